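"""Optimal minimum-bit parsing of a sequence into codebook grams.

Every way of segmenting the input into grams that carry codewords is a
0 -> n path in a DAG over input positions, where an edge i -> j exists when
the gram I[i:j] (half-open, 0-based) is in the codebook and costs the
length of its codeword. The optimal encoding is the shortest such path.

Positions processed in ascending order are a topological order of that DAG,
so a single forward pass computes the per-position best length f and a
backpointer; the stage-by-stage formulation over a multistage graph visits
the same edges repeatedly and produces identical results. Candidate grams
at a position are enumerated in one walk of a TRIE built over the
codebook's grams.

Tie policy: strict-improvement relaxation with predecessors scanned in
ascending position order, i.e. on equal total length the parse through the
earliest predecessor wins ("choose the first possibility").
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Dict, Iterator, List, Optional, Tuple, Union

from .errors import UnencodableSymbolError
from .huffman import Codebook
from .types import EncodedBits, SymbolSequence, as_symbols

__all__ = ["CodeTrie", "TrieNode", "ParseTable", "build_trie", "parse_optimal", "encode_optimal"]

_INF = float("inf")


class TrieNode:
    __slots__ = ("children", "codeword")

    def __init__(self) -> None:
        self.children: Dict[str, "TrieNode"] = {}
        self.codeword: Optional[str] = None


class CodeTrie:
    """Symbol-indexed prefix tree over the codebook's grams.

    A node carries a codeword iff the gram spelled by its root path is in
    the codebook; intermediate nodes exist for proper prefixes of longer
    grams.
    """

    def __init__(self) -> None:
        self.root = TrieNode()
        self._size = 0

    def insert(self, gram: str, codeword: str) -> None:
        node = self.root
        for ch in gram:
            node = node.children.setdefault(ch, TrieNode())
        if node.codeword is None:
            self._size += 1
        node.codeword = codeword

    def __len__(self) -> int:
        """Number of marked (codeword-carrying) nodes."""
        return self._size

    def lookup(self, gram: str) -> Optional[str]:
        node = self.root
        for ch in gram:
            node = node.children.get(ch)
            if node is None:
                return None
        return node.codeword

    def matches(self, symbols: str, start: int, max_len: int) -> Iterator[Tuple[int, str]]:
        """Yield (end, codeword) for every codebook gram symbols[start:end].

        Matches are produced in order of increasing gram length; the walk
        stops at the first symbol with no trie child, which bounds the work
        per position by the depth of the trie.
        """
        node = self.root
        limit = min(start + max_len, len(symbols))
        for idx in range(start, limit):
            node = node.children.get(symbols[idx])
            if node is None:
                return
            if node.codeword is not None:
                yield idx + 1, node.codeword


def build_trie(book: Codebook) -> CodeTrie:
    trie = CodeTrie()
    for gram, codeword in book.items():
        trie.insert(gram, codeword)
    return trie


@dataclass
class ParseTable:
    """Per-position dynamic-programming state of the optimal parse.

    ``f[j]`` is the fewest bits needed to encode the first j symbols
    (infinity if position j is unreachable); ``back[j]`` is the predecessor
    position of the winning gram ending at j.
    """

    f: List[float]
    back: List[Optional[int]]

    @property
    def n(self) -> int:
        return len(self.f) - 1


def _check_singles(symbols: str, book: Codebook) -> None:
    missing = set(symbols) - book.single_symbols()
    if missing:
        raise UnencodableSymbolError(
            f"unencodable symbol(s): {sorted(missing)!r} not in codebook"
        )


def parse_optimal(
    seq: Union[str, SymbolSequence],
    book: Codebook,
    m: Optional[int] = None,
    trie: Optional[CodeTrie] = None,
) -> ParseTable:
    """Run the forward shortest-path pass and return the full parse table."""
    symbols = as_symbols(seq)
    n = len(symbols)
    _check_singles(symbols, book)
    if m is None:
        m = book.max_gram_length
    if trie is None:
        trie = build_trie(book)

    f: List[float] = [_INF] * (n + 1)
    back: List[Optional[int]] = [None] * (n + 1)
    f[0] = 0.0
    for i in range(n):
        fi = f[i]
        if fi == _INF:
            continue
        for j, codeword in trie.matches(symbols, i, m):
            cost = fi + len(codeword)
            if cost < f[j]:
                f[j] = cost
                back[j] = i
    return ParseTable(f=f, back=back)


def encode_optimal(
    seq: Union[str, SymbolSequence], book: Codebook, m: Optional[int] = None
) -> EncodedBits:
    """Encode ``seq`` with the globally minimum number of bits.

    Grams of length >= 2 absent from (e.g. pruned out of) the codebook
    simply contribute no edge; feasibility is guaranteed as long as every
    single symbol of the input carries a codeword, which is checked up
    front and reported as ``UnencodableSymbolError`` otherwise.
    """
    symbols = as_symbols(seq)
    n = len(symbols)
    if n == 0:
        return EncodedBits(bits="", parse=())
    table = parse_optimal(symbols, book, m=m)

    grams: List[str] = []
    j = n
    while j > 0:
        i = table.back[j]
        assert i is not None, "unreachable end position despite full single-symbol cover"
        grams.append(symbols[i:j])
        j = i
    grams.reverse()
    bits = "".join(book[g] for g in grams)
    return EncodedBits(bits=bits, parse=tuple(grams))
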