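"""Prefix-tree decoding of encoded bitstrings.

Because the codebook is prefix-free, a concatenation of codewords decodes
unambiguously — and identically no matter which parser (optimal or greedy)
produced it: read bits, walk the binary tree ('0' left, '1' right), emit
the gram at each leaf reached and restart at the root.
"""

from __future__ import annotations

from typing import List, Optional, Union

from .errors import CorruptStreamError, InvalidCodebookError, TruncatedStreamError
from .huffman import Codebook
from .types import EncodedBits, SymbolSequence

__all__ = ["DecodeNode", "DecodeTree", "build_decode_tree", "decode"]


class DecodeNode:
    __slots__ = ("zero", "one", "gram")

    def __init__(self) -> None:
        self.zero: Optional["DecodeNode"] = None
        self.one: Optional["DecodeNode"] = None
        self.gram: Optional[str] = None


class DecodeTree:
    """Bit-indexed binary tree whose leaves carry grams."""

    def __init__(self) -> None:
        self.root = DecodeNode()
        self.leaf_count = 0


def build_decode_tree(book: Union[Codebook, dict]) -> DecodeTree:
    """Invert a prefix-free codebook into a decode tree.

    Raises ``InvalidCodebookError`` if any codeword is empty, is a prefix
    of another, or has another codeword as a prefix.
    """
    tree = DecodeTree()
    for gram, codeword in book.items():
        if not codeword:
            raise InvalidCodebookError(f"invalid codebook: empty codeword for {gram!r}")
        node = tree.root
        for bit in codeword:
            if node.gram is not None:
                raise InvalidCodebookError(
                    f"invalid codebook: {book[node.gram]!r} is a prefix of {codeword!r}"
                )
            if bit == "0":
                if node.zero is None:
                    node.zero = DecodeNode()
                node = node.zero
            elif bit == "1":
                if node.one is None:
                    node.one = DecodeNode()
                node = node.one
            else:
                raise InvalidCodebookError(f"invalid codebook: bad bit {bit!r}")
        if node.gram is not None or node.zero is not None or node.one is not None:
            raise InvalidCodebookError(
                f"invalid codebook: codeword {codeword!r} conflicts with another entry"
            )
        node.gram = gram
        tree.leaf_count += 1
    return tree


def decode(bits: Union[str, EncodedBits], tree: DecodeTree) -> SymbolSequence:
    """Decode a concatenation of codewords back into the symbol sequence.

    Consumes every bit; raises ``TruncatedStreamError`` if the stream ends
    mid-codeword and ``CorruptStreamError`` if it walks off the tree.
    """
    if isinstance(bits, EncodedBits):
        bits = bits.bits
    out: List[str] = []
    root = tree.root
    node = root
    for bit in bits:
        node = node.zero if bit == "0" else node.one
        if node is None:
            raise CorruptStreamError("corrupt stream: bit pattern matches no codeword")
        if node.gram is not None:
            out.append(node.gram)
            node = root
    if node is not root:
        raise TruncatedStreamError("truncated stream: bits end mid-codeword")
    return SymbolSequence("".join(out))
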