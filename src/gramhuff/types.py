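"""Shared value types: symbol sequences and encoded bit blocks.

Symbols are single Python characters throughout the package. A "sequence"
is therefore just a string; grams are substrings. Byte-granularity data is
mapped onto characters via Latin-1 so that arbitrary binary streams fit the
same representation, and bit granularity uses the characters '0'/'1'.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Union

__all__ = ["SymbolSequence", "EncodedBits", "as_symbols"]


class SymbolSequence:
    """An immutable stream of symbols over a finite alphabet.

    Parameters
    ----------
    symbols:
        The symbol stream, one character per symbol.
    alphabet:
        Optional explicit alphabet. Defaults to the set of distinct symbols
        actually present. Every symbol must be a member.
    """

    __slots__ = ("symbols", "alphabet")

    def __init__(self, symbols: Union[str, Iterable[str]], alphabet: Iterable[str] | None = None):
        text = symbols if isinstance(symbols, str) else "".join(symbols)
        self.symbols = text
        self.alphabet = frozenset(text) if alphabet is None else frozenset(alphabet)
        if not self.alphabet.issuperset(text):
            extra = sorted(set(text) - self.alphabet)
            raise ValueError(f"symbols outside the declared alphabet: {extra!r}")

    @property
    def n(self) -> int:
        return len(self.symbols)

    def __len__(self) -> int:
        return len(self.symbols)

    def __str__(self) -> str:
        return self.symbols

    def __iter__(self):
        return iter(self.symbols)

    def __eq__(self, other) -> bool:
        if isinstance(other, SymbolSequence):
            return self.symbols == other.symbols
        if isinstance(other, str):
            return self.symbols == other
        return NotImplemented

    def __hash__(self) -> int:
        return hash(self.symbols)

    def __repr__(self) -> str:
        head = self.symbols[:40] + ("..." if len(self.symbols) > 40 else "")
        return f"SymbolSequence({head!r}, n={len(self)}, |A|={len(self.alphabet)})"


def as_symbols(seq: Union[str, SymbolSequence]) -> str:
    """Normalise a str / SymbolSequence argument to a plain string."""
    if isinstance(seq, SymbolSequence):
        return seq.symbols
    if isinstance(seq, str):
        return seq
    return "".join(seq)


@dataclass(frozen=True)
class EncodedBits:
    """An encoded payload: the output bitstring plus the parse that made it.

    ``bits`` is the concatenation of the codewords of the grams in ``parse``;
    the concatenation of the grams themselves is the original input.
    """

    bits: str
    parse: tuple[str, ...] = field(default_factory=tuple)

    def __len__(self) -> int:
        return len(self.bits)

    @property
    def bit_count(self) -> int:
        return len(self.bits)
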