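"""Alpha-weighted m-gram frequency estimation and table pruning.

The codec assigns codewords not to single symbols but to *grams*: contiguous
runs of 1..m symbols. Their statistics are estimated from a *pattern*
sequence by sliding a window of every length i = 1..m over it and adding
``i**alpha`` per occurrence. With ``alpha = 0`` this is a plain occurrence
count; ``alpha > 0`` boosts long grams so that they win shorter codewords in
the subsequent Huffman construction.

Insertion order of the resulting table is semantically meaningful: the
canonical Huffman tie policy (see :mod:`gramhuff.huffman`) breaks weight
ties by first-seen order, which is what makes codebooks reproducible from a
transmitted frequency table alone.
"""

from __future__ import annotations

import math
from typing import Dict, Iterator, Mapping, Tuple, Union

from .errors import EmptyInputError
from .types import SymbolSequence, as_symbols

__all__ = ["FrequencyTable", "estimate_frequencies", "prune_frequencies"]

Number = Union[int, float]


class FrequencyTable(Mapping[str, Number]):
    """Ordered map from grams to alpha-weighted occurrence counts.

    Parameters
    ----------
    counts:
        Gram -> weighted count, in insertion (first-seen) order.
    m:
        Maximum gram length the table was built for.
    alpha:
        The exponential length-weighting factor used (>= 0).
    """

    def __init__(self, counts: Mapping[str, Number], m: int, alpha: float):
        self._counts: Dict[str, Number] = dict(counts)
        self.m = int(m)
        self.alpha = alpha

    # Mapping interface -------------------------------------------------
    def __getitem__(self, gram: str) -> Number:
        return self._counts[gram]

    def __iter__(self) -> Iterator[str]:
        return iter(self._counts)

    def __len__(self) -> int:
        return len(self._counts)

    # Convenience -------------------------------------------------------
    def grams(self) -> Tuple[str, ...]:
        return tuple(self._counts)

    def items_of_length(self, i: int) -> list[tuple[str, Number]]:
        return [(g, c) for g, c in self._counts.items() if len(g) == i]

    def total(self) -> Number:
        return sum(self._counts.values())

    def __repr__(self) -> str:
        return f"FrequencyTable({len(self)} grams, m={self.m}, alpha={self.alpha})"

    def __eq__(self, other) -> bool:
        if not isinstance(other, FrequencyTable):
            return NotImplemented
        return (
            list(self._counts.items()) == list(other._counts.items())
            and self.m == other.m
            and self.alpha == other.alpha
        )


def _increment(i: int, alpha: float) -> Number:
    """i**alpha, kept as an exact integer whenever alpha is a whole number."""
    if float(alpha).is_integer():
        return i ** int(alpha)
    return float(i) ** alpha


def estimate_frequencies(
    pattern: Union[str, SymbolSequence], m: int, alpha: float = 1.0
) -> FrequencyTable:
    """Slide windows of every length 1..m over ``pattern``, weighting by i**alpha.

    Grams enter the table in the scan order: outer loop over the window
    length i, inner loop over the start position j. Each occurrence of a
    length-i gram contributes ``i**alpha`` to its count, so with alpha = 0
    the count of a length-i gram sums to n - i + 1 over all grams of that
    length.

    Raises
    ------
    EmptyInputError
        If the pattern is empty.
    ValueError
        If ``m`` exceeds the pattern length, ``m < 1`` or ``alpha < 0``.
    """
    symbols = as_symbols(pattern)
    n = len(symbols)
    if n == 0:
        raise EmptyInputError("empty input")
    if m < 1:
        raise ValueError("m must be >= 1")
    if m > n:
        raise ValueError("m exceeds data size")
    if alpha < 0:
        raise ValueError("alpha must be >= 0")

    counts: Dict[str, Number] = {}
    for i in range(1, m + 1):
        w = _increment(i, alpha)
        for j in range(n - i + 1):
            gram = symbols[j : j + i]
            counts[gram] = counts.get(gram, 0) + w
    return FrequencyTable(counts, m=m, alpha=alpha)


def prune_frequencies(table: FrequencyTable, keep_fraction: float) -> FrequencyTable:
    """Keep all single-symbol grams plus the most frequent longer grams.

    Among grams of length >= 2, the ``ceil(keep_fraction * count)`` with the
    highest counts survive; count ties are broken in favour of the
    earlier-inserted gram. Length-1 grams are always retained — every symbol
    of the alphabet must stay encodable. Relative insertion order of the
    survivors is preserved, as are their counts.
    """
    if not 0.0 <= keep_fraction <= 1.0:
        raise ValueError("keep_fraction must lie in [0, 1]")
    if len(table) == 0:
        raise EmptyInputError("empty table")

    multi = [g for g in table if len(g) >= 2]
    n_keep = math.ceil(keep_fraction * len(multi))
    # Stable sort by descending count: earlier-inserted grams win ties.
    survivors = set(sorted(multi, key=lambda g: -table[g])[:n_keep])
    kept = {g: c for g, c in table.items() if len(g) == 1 or g in survivors}
    return FrequencyTable(kept, m=table.m, alpha=table.alpha)
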