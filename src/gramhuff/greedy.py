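"""Linear-time greedy approximate encoder.

At each input position the coder considers every codebook gram starting
there (lengths 1..m, clamped at the end of the input) and takes the one
with the highest symbols-per-bit ratio |S| / |codeword(S)| — the classical
density rule of the fractional-knapsack heuristic. The comparison is
strictly greater-than, so ties keep the earlier (shorter) candidate; the
chosen codeword is emitted and the position advances by |S|.

The candidate scan is a single TRIE walk, which enumerates exactly the
codebook grams at the position in increasing length — grams pruned from
the codebook are skipped rather than treated as errors.
"""

from __future__ import annotations

from typing import List, Optional, Union

from .errors import UnencodableSymbolError
from .huffman import Codebook
from .optimal import CodeTrie, build_trie, _check_singles
from .types import EncodedBits, SymbolSequence, as_symbols

__all__ = ["encode_greedy"]


def encode_greedy(
    seq: Union[str, SymbolSequence], book: Codebook, m: Optional[int] = None
) -> EncodedBits:
    """Encode ``seq`` by the greedy best-ratio rule; never beats the optimal parse."""
    symbols = as_symbols(seq)
    n = len(symbols)
    if n == 0:
        return EncodedBits(bits="", parse=())
    _check_singles(symbols, book)
    if m is None:
        m = book.max_gram_length
    trie: CodeTrie = build_trie(book)

    out: List[str] = []
    grams: List[str] = []
    i = 0
    while i < n:
        best_ratio = 0.0
        best_end = i
        best_code: Optional[str] = None
        for j, codeword in trie.matches(symbols, i, m):
            t = (j - i) / len(codeword)
            if t > best_ratio:
                best_ratio = t
                best_end = j
                best_code = codeword
        if best_code is None:  # pragma: no cover - excluded by _check_singles
            raise UnencodableSymbolError(f"unencodable symbol {symbols[i]!r}")
        out.append(best_code)
        grams.append(symbols[i:best_end])
        i = best_end
    return EncodedBits(bits="".join(out), parse=tuple(grams))
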