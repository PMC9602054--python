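"""Experiment harness: the bits-per-symbol metric and pattern/test runs.

The headline figure throughout is *bits per symbol*: compressed payload
bits divided by the number of input symbols, excluding any codebook
transmission cost (both sides are assumed to share the codewords). A run
estimates gram frequencies on the *pattern* set, builds the codebook, then
encodes the *test* set — the same train/evaluate discipline as any
out-of-sample benchmark.
"""

from __future__ import annotations

import zlib
from dataclasses import dataclass
from typing import Optional, Union

from .decoding import build_decode_tree, decode
from .errors import AlphabetMismatchError
from .frequencies import estimate_frequencies, prune_frequencies
from .greedy import encode_greedy
from .huffman import codebook_from_frequencies, first_order_entropy, symbol_distribution
from .optimal import encode_optimal
from .synthetic import split_pattern_test
from .types import EncodedBits, SymbolSequence, as_symbols

__all__ = ["bits_per_symbol", "ExperimentReport", "run_experiment", "run_split_experiment"]


def bits_per_symbol(bits: Union[EncodedBits, str, int], n: int) -> float:
    """Compressed payload bits divided by the number of input symbols."""
    if n < 1:
        raise ValueError("n must be >= 1")
    count = bits if isinstance(bits, int) else len(bits)
    return count / n


@dataclass
class ExperimentReport:
    m: int
    alpha: float
    keep_fraction: float
    coder: str
    n_pattern: int
    n_test: int
    codebook_size: int
    bit_count: int
    bits_per_symbol: float
    pattern_entropy: float
    deflate_bits_per_symbol: Optional[float] = None

    def as_tsv(self) -> str:
        header = [
            "m", "alpha", "keep_fraction", "coder", "n_pattern", "n_test",
            "codebook_size", "bit_count", "bits_per_symbol", "pattern_entropy",
            "deflate_bits_per_symbol",
        ]
        values = [
            self.m, self.alpha, self.keep_fraction, self.coder, self.n_pattern,
            self.n_test, self.codebook_size, self.bit_count,
            f"{self.bits_per_symbol:.3f}", f"{self.pattern_entropy:.3f}",
            "NA" if self.deflate_bits_per_symbol is None
            else f"{self.deflate_bits_per_symbol:.3f}",
        ]
        return "\t".join(header) + "\n" + "\t".join(map(str, values)) + "\n"


_CODERS = {"optimal": encode_optimal, "greedy": encode_greedy}


def run_experiment(
    pattern: Union[str, SymbolSequence],
    test: Union[str, SymbolSequence],
    *,
    m: int,
    alpha: float = 1.0,
    keep_fraction: float = 1.0,
    coder: str = "greedy",
    deflate_baseline: bool = False,
    verify_roundtrip: bool = True,
) -> ExperimentReport:
    """Train on ``pattern``, encode ``test``, report compression statistics.

    Raises ``AlphabetMismatchError`` if the test data contains symbols the
    pattern never produced (those would have no codeword at any m).
    """
    if coder not in _CODERS:
        raise ValueError(f"unknown coder {coder!r}")
    pattern_s = as_symbols(pattern)
    test_s = as_symbols(test)
    missing = set(test_s) - set(pattern_s)
    if missing:
        raise AlphabetMismatchError(
            f"alphabet mismatch: test symbols {sorted(missing)!r} absent from pattern"
        )

    table = estimate_frequencies(pattern_s, m=m, alpha=alpha)
    if keep_fraction < 1.0:
        table = prune_frequencies(table, keep_fraction)
    book = codebook_from_frequencies(table)
    encoded = _CODERS[coder](test_s, book, m=m)
    if verify_roundtrip:
        tree = build_decode_tree(book)
        if str(decode(encoded, tree)) != test_s:
            raise AssertionError("roundtrip failure: decoded test data differs")

    deflate_bps = None
    if deflate_baseline:
        try:
            raw = test_s.encode("latin-1")
        except UnicodeEncodeError:
            raw = test_s.encode("utf-8")
        deflate_bps = 8 * len(zlib.compress(raw, 9)) / len(test_s)

    return ExperimentReport(
        m=m,
        alpha=alpha,
        keep_fraction=keep_fraction,
        coder=coder,
        n_pattern=len(pattern_s),
        n_test=len(test_s),
        codebook_size=len(book),
        bit_count=len(encoded.bits),
        bits_per_symbol=bits_per_symbol(encoded, len(test_s)),
        pattern_entropy=first_order_entropy(symbol_distribution(pattern_s).values()),
        deflate_bits_per_symbol=deflate_bps,
    )


def run_split_experiment(
    corpus: Union[str, SymbolSequence],
    pattern_fraction: float = 0.25,
    **kwargs,
) -> ExperimentReport:
    """Split a corpus into a contiguous pattern prefix and test remainder, then run."""
    pattern, test = split_pattern_test(corpus, pattern_fraction)
    return run_experiment(pattern, test, **kwargs)
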