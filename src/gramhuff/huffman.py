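"""Huffman code trees over gram frequency tables, and code statistics.

The construction is the classical one — repeatedly merge the two
lowest-weight trees of the forest — applied to a forest whose leaves are
grams of length 1..m rather than single symbols. Because Huffman coding
leaves the bit assignment free wherever weights tie, this module pins a
*canonical tie policy* so that a codebook is a pure function of the
frequency table (and can therefore be rebuilt identically from a
transmitted table):

* every node carries a creation index — leaves first, in frequency-table
  insertion order, then merged nodes in merge order;
* merge selection orders the forest by (weight, creation index);
* of the two nodes merged, the one that sorts first becomes the '0'/left
  child.
"""

from __future__ import annotations

import heapq
import math
from dataclasses import dataclass, field
from typing import Dict, Iterable, Iterator, Mapping, Optional, Tuple, Union

from .errors import CodecError, EmptyInputError
from .frequencies import FrequencyTable
from .types import SymbolSequence, as_symbols

__all__ = [
    "HuffmanNode",
    "HuffmanTree",
    "Codebook",
    "build_tree",
    "extract_codewords",
    "codebook_from_frequencies",
    "first_order_entropy",
    "symbol_distribution",
    "average_code_length",
    "total_code_bits",
]

Number = Union[int, float]


@dataclass
class HuffmanNode:
    weight: Number
    index: int                       # creation index; total order for tie-breaks
    gram: Optional[str] = None       # payload on leaves only
    left: Optional["HuffmanNode"] = None
    right: Optional["HuffmanNode"] = None

    @property
    def is_leaf(self) -> bool:
        return self.gram is not None


@dataclass
class HuffmanTree:
    root: HuffmanNode
    leaves: Tuple[HuffmanNode, ...] = field(default_factory=tuple)

    def leaf_depths(self) -> Dict[str, int]:
        """Gram -> depth of its leaf (0 for a root-as-leaf tree)."""
        depths: Dict[str, int] = {}

        def walk(node: HuffmanNode, d: int) -> None:
            if node.is_leaf:
                depths[node.gram] = d
            else:
                walk(node.left, d + 1)
                walk(node.right, d + 1)

        walk(self.root, 0)
        return depths


class Codebook(Mapping[str, str]):
    """Prefix-free map from grams to binary codewords ('0'/'1' strings)."""

    def __init__(
        self,
        codes: Mapping[str, str],
        m: Optional[int] = None,
        alpha: Optional[float] = None,
        granularity: Optional[str] = None,
    ):
        self._codes: Dict[str, str] = dict(codes)
        self.m = m if m is not None else (max(map(len, self._codes)) if self._codes else 0)
        self.alpha = alpha
        self.granularity = granularity

    def __getitem__(self, gram: str) -> str:
        return self._codes[gram]

    def __iter__(self) -> Iterator[str]:
        return iter(self._codes)

    def __len__(self) -> int:
        return len(self._codes)

    @property
    def max_gram_length(self) -> int:
        return max(map(len, self._codes)) if self._codes else 0

    def single_symbols(self) -> frozenset:
        return frozenset(g for g in self._codes if len(g) == 1)

    def is_prefix_free(self) -> bool:
        codes = sorted(self._codes.values())
        return all(not b.startswith(a) for a, b in zip(codes, codes[1:]))

    def kraft_sum(self) -> float:
        return sum(2.0 ** -len(c) for c in self._codes.values())

    def __repr__(self) -> str:
        return f"Codebook({len(self)} grams, m={self.m}, alpha={self.alpha})"


def build_tree(table: Union[FrequencyTable, Mapping[str, Number]]) -> HuffmanTree:
    """Build the Huffman tree for a frequency table under the canonical tie policy.

    A single-entry table yields a root-as-leaf tree (depth 0); codeword
    assignment for that degenerate case is handled in
    :func:`extract_codewords`.
    """
    items = list(table.items())
    if not items:
        raise EmptyInputError("empty table")

    leaves = tuple(
        HuffmanNode(weight=w, index=i, gram=g) for i, (g, w) in enumerate(items)
    )
    counter = len(leaves)
    # Heap entries sort by (weight, creation index): the first node popped in
    # each merge is the preferred one and becomes the '0'/left child.
    heap: list[tuple[Number, int, HuffmanNode]] = [
        (node.weight, node.index, node) for node in leaves
    ]
    heapq.heapify(heap)
    while len(heap) > 1:
        _, _, left = heapq.heappop(heap)
        _, _, right = heapq.heappop(heap)
        merged = HuffmanNode(
            weight=left.weight + right.weight, index=counter, left=left, right=right
        )
        counter += 1
        heapq.heappush(heap, (merged.weight, merged.index, merged))
    return HuffmanTree(root=heap[0][2], leaves=leaves)


def extract_codewords(tree: HuffmanTree) -> Codebook:
    """Read codewords off the tree: '0' into the left subtree, '1' into the right.

    A root-as-leaf tree (single gram) gets the 1-bit codeword "0" so that
    degenerate inputs remain encodable.
    """
    root = tree.root
    if root.is_leaf:
        return Codebook({root.gram: "0"})
    codes: Dict[str, str] = {}

    def walk(node: HuffmanNode, prefix: str) -> None:
        if node.is_leaf:
            codes[node.gram] = prefix
        else:
            walk(node.left, prefix + "0")
            walk(node.right, prefix + "1")

    walk(root, "")
    # Report codewords in the frequency table's insertion order.
    ordered = {leaf.gram: codes[leaf.gram] for leaf in tree.leaves}
    return Codebook(ordered)


def codebook_from_frequencies(
    table: Union[FrequencyTable, Mapping[str, Number]]
) -> Codebook:
    """Frequency table -> canonical codebook, carrying m/alpha metadata along."""
    book = extract_codewords(build_tree(table))
    if isinstance(table, FrequencyTable):
        book.m = table.m
        book.alpha = table.alpha
    return book


def first_order_entropy(probs: Iterable[float]) -> float:
    """Shannon entropy -sum(p * log2 p) in bits per symbol.

    ``probs`` must be a proper probability vector: strictly positive entries
    summing to 1 (within floating tolerance).
    """
    p = [float(x) for x in probs]
    if not p or any(x <= 0.0 for x in p):
        raise ValueError("probabilities must be strictly positive")
    if abs(sum(p) - 1.0) > 1e-9:
        raise ValueError("probabilities must sum to 1")
    return -sum(x * math.log2(x) for x in p)


def symbol_distribution(seq: Union[str, SymbolSequence]) -> Dict[str, float]:
    """Empirical single-symbol probabilities, in first-seen order."""
    symbols = as_symbols(seq)
    if not symbols:
        raise EmptyInputError("empty input")
    counts: Dict[str, int] = {}
    for ch in symbols:
        counts[ch] = counts.get(ch, 0) + 1
    n = len(symbols)
    return {s: c / n for s, c in counts.items()}


def total_code_bits(
    book: Mapping[str, str], table: Union[FrequencyTable, Mapping[str, Number]]
) -> Number:
    """Weighted bit total: sum over grams of count * codeword length."""
    try:
        return sum(c * len(book[g]) for g, c in table.items())
    except KeyError as exc:  # pragma: no cover - defensive
        raise CodecError(f"missing codeword for gram {exc.args[0]!r}") from exc


def average_code_length(
    book: Mapping[str, str], table: Union[FrequencyTable, Mapping[str, Number]]
) -> float:
    """Average codeword length in bits per table entry occurrence.

    For a table restricted to single symbols this is the classical
    bits-per-symbol of symbol-by-symbol Huffman coding.
    """
    total_count = sum(table.values())
    if total_count <= 0:
        raise ValueError("table counts must be positive")
    return total_code_bits(book, table) / total_count
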