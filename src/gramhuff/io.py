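"""File formats: FASTA/text/binary readers, codebook files, encoded container.

Symbol granularities
--------------------
``byte``
    one symbol per byte; bytes are mapped to characters via Latin-1 so any
    binary stream fits the in-memory string representation.
``char``
    one symbol per text character (UTF-8).
``bit``
    one symbol per bit, most-significant bit first within each byte; the
    symbols are the characters '0' and '1'.

Codebook files
--------------
Line-oriented text with ``#key<TAB>value`` header records (m, alpha,
granularity, mode) followed by one record per gram. In ``explicit`` mode a
record is ``gram<TAB>codeword``; in ``frequencies`` mode it is
``gram<TAB>count`` in insertion order, from which the canonical Huffman
policy rebuilds exactly the same codewords. Grams are backslash-escaped.

Container
---------
A small binary framing: magic ``GHUF``, version, granularity, codebook
mode, m, alpha, an embedded codebook text block (possibly empty for
"external" mode), the exact payload bit count, and the payload zero-padded
to a byte boundary.
"""

from __future__ import annotations

import struct
from dataclasses import dataclass
from pathlib import Path
from typing import Optional, Tuple, Union

from Bio import SeqIO

from ._escape import escape_gram, unescape_gram
from .errors import (
    CodecError,
    ContainerFormatError,
    EmptyInputError,
    TruncatedStreamError,
)
from .frequencies import FrequencyTable
from .huffman import Codebook, codebook_from_frequencies
from .types import SymbolSequence, as_symbols

__all__ = [
    "GRANULARITIES",
    "read_fasta",
    "read_symbols",
    "write_symbols",
    "pack_bits",
    "unpack_bits",
    "codebook_to_text",
    "codebook_from_text",
    "write_codebook",
    "read_codebook",
    "write_frequency_table",
    "read_frequency_table",
    "EncodedBlock",
    "write_block",
    "read_block",
]

GRANULARITIES = ("byte", "char", "bit")
_GRAN_CODE = {g: i for i, g in enumerate(GRANULARITIES)}
_MAGIC = b"GHUF"
_VERSION = 1
_MODES = ("external", "explicit", "frequencies")
_MODE_CODE = {m: i for i, m in enumerate(_MODES)}
# magic, version, granularity, mode, m, alpha, codebook byte length, payload bit count
_HEADER = struct.Struct("<4sBBBId I Q".replace(" ", ""))


# --------------------------------------------------------------------------
# Sequence readers / writers
# --------------------------------------------------------------------------

def read_fasta(path: Union[str, Path]) -> SymbolSequence:
    """Concatenate the sequence lines of all FASTA records, uppercased."""
    text = Path(path).read_text()
    if not text.strip():
        raise EmptyInputError(f"empty input: {path}")
    if not text.lstrip().startswith(">"):
        raise CodecError(f"not FASTA (no '>' header): {path}")
    records = list(SeqIO.parse(str(path), "fasta"))
    seq = "".join(str(rec.seq) for rec in records).upper()
    if not seq:
        raise EmptyInputError(f"FASTA contains no sequence data: {path}")
    return SymbolSequence(seq)


def read_symbols(path: Union[str, Path], granularity: str = "char") -> SymbolSequence:
    """Read a file as a symbol stream at the requested granularity."""
    if granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {granularity!r}")
    data = Path(path).read_bytes()
    if granularity == "byte":
        return SymbolSequence(data.decode("latin-1"))
    if granularity == "char":
        return SymbolSequence(data.decode("utf-8"))
    bits = "".join(format(byte, "08b") for byte in data)  # MSB first
    return SymbolSequence(bits, alphabet="01")


def write_symbols(
    seq: Union[str, SymbolSequence], path: Union[str, Path], granularity: str = "char"
) -> None:
    """Inverse of :func:`read_symbols` for each granularity."""
    symbols = as_symbols(seq)
    if granularity == "byte":
        Path(path).write_bytes(symbols.encode("latin-1"))
    elif granularity == "char":
        Path(path).write_text(symbols, encoding="utf-8")
    elif granularity == "bit":
        if len(symbols) % 8:
            raise CodecError("bit-granularity output is not a whole number of bytes")
        Path(path).write_bytes(pack_bits(symbols))
    else:
        raise ValueError(f"unknown granularity {granularity!r}")


# --------------------------------------------------------------------------
# Bit packing
# --------------------------------------------------------------------------

def pack_bits(bits: str) -> bytes:
    """Pack a '0'/'1' string into bytes, MSB first, zero-padded at the end."""
    out = bytearray()
    for i in range(0, len(bits), 8):
        chunk = bits[i : i + 8]
        out.append(int(chunk.ljust(8, "0"), 2))
    return bytes(out)


def unpack_bits(data: bytes, bit_count: int) -> str:
    """Inverse of :func:`pack_bits`, keeping exactly ``bit_count`` bits."""
    if bit_count > 8 * len(data):
        raise TruncatedStreamError("truncated: fewer payload bytes than bit count")
    return "".join(format(byte, "08b") for byte in data)[:bit_count]


# --------------------------------------------------------------------------
# Codebook / frequency-table text format
# --------------------------------------------------------------------------

def _format_number(x) -> str:
    if isinstance(x, int):
        return str(x)
    if float(x).is_integer():
        return str(int(x))
    return repr(float(x))


def _parse_number(s: str):
    try:
        return int(s)
    except ValueError:
        return float(s)


def codebook_to_text(
    book: Optional[Codebook] = None,
    table: Optional[FrequencyTable] = None,
    mode: str = "explicit",
    granularity: Optional[str] = None,
) -> str:
    """Serialise a codebook (or its frequency table) to the text format."""
    if mode not in ("explicit", "frequencies"):
        raise ValueError(f"unknown codebook mode {mode!r}")
    if mode == "frequencies":
        if table is None:
            raise ValueError("frequency mode requires the frequency table")
        m, alpha = table.m, table.alpha
        rows = [f"{escape_gram(g)}\t{_format_number(c)}" for g, c in table.items()]
    else:
        if book is None:
            raise ValueError("explicit mode requires the codebook")
        m, alpha = book.m, book.alpha
        rows = [f"{escape_gram(g)}\t{c}" for g, c in book.items()]
        granularity = granularity or book.granularity
    header = [
        "#gramhuff-codebook\t1",
        f"#mode\t{mode}",
        f"#m\t{m}",
        f"#alpha\t{_format_number(alpha) if alpha is not None else ''}",
        f"#granularity\t{granularity or ''}",
    ]
    return "\n".join(header + rows) + "\n"


def codebook_from_text(text: str) -> Codebook:
    """Parse the codebook text format; rebuilds codewords in frequency mode."""
    meta = {}
    rows: list[Tuple[str, str]] = []
    for lineno, line in enumerate(text.splitlines(), 1):
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            meta[key] = value
            continue
        gram, sep, value = line.partition("\t")
        if not sep:
            raise ContainerFormatError(f"bad codebook record on line {lineno}: {line!r}")
        rows.append((unescape_gram(gram), value))
    if meta.get("gramhuff-codebook") != "1":
        raise ContainerFormatError("not a gramhuff codebook file")
    mode = meta.get("mode", "explicit")
    m = int(meta["m"]) if meta.get("m") else None
    alpha = _parse_number(meta["alpha"]) if meta.get("alpha") else None
    granularity = meta.get("granularity") or None
    if mode == "frequencies":
        table = FrequencyTable({g: _parse_number(v) for g, v in rows}, m=m or 1, alpha=alpha)
        book = codebook_from_frequencies(table)
    elif mode == "explicit":
        book = Codebook(dict(rows))
    else:
        raise ContainerFormatError(f"unknown codebook mode {mode!r}")
    book.m = m if m is not None else book.max_gram_length
    book.alpha = alpha
    book.granularity = granularity
    return book


def write_codebook(
    path: Union[str, Path],
    book: Optional[Codebook] = None,
    table: Optional[FrequencyTable] = None,
    mode: str = "explicit",
    granularity: Optional[str] = None,
) -> None:
    Path(path).write_text(
        codebook_to_text(book=book, table=table, mode=mode, granularity=granularity),
        encoding="utf-8",
    )


def read_codebook(path: Union[str, Path]) -> Codebook:
    return codebook_from_text(Path(path).read_text(encoding="utf-8"))


def write_frequency_table(table: FrequencyTable, path: Union[str, Path]) -> None:
    """TSV: header records m and alpha; rows are gram, length, weighted count."""
    lines = [
        "#gramhuff-frequencies\t1",
        f"#m\t{table.m}",
        f"#alpha\t{_format_number(table.alpha)}",
    ]
    for gram, count in table.items():
        lines.append(f"{escape_gram(gram)}\t{len(gram)}\t{_format_number(count)}")
    Path(path).write_text("\n".join(lines) + "\n", encoding="utf-8")


def read_frequency_table(path: Union[str, Path]) -> FrequencyTable:
    meta = {}
    counts = {}
    for lineno, line in enumerate(Path(path).read_text(encoding="utf-8").splitlines(), 1):
        if not line:
            continue
        if line.startswith("#"):
            key, _, value = line[1:].partition("\t")
            meta[key] = value
            continue
        parts = line.split("\t")
        if len(parts) != 3:
            raise ContainerFormatError(f"bad frequency record on line {lineno}: {line!r}")
        gram = unescape_gram(parts[0])
        if len(gram) != int(parts[1]):
            raise ContainerFormatError(f"length field mismatch on line {lineno}")
        counts[gram] = _parse_number(parts[2])
    if meta.get("gramhuff-frequencies") != "1":
        raise ContainerFormatError("not a gramhuff frequency file")
    return FrequencyTable(counts, m=int(meta["m"]), alpha=_parse_number(meta["alpha"]))


# --------------------------------------------------------------------------
# Encoded container
# --------------------------------------------------------------------------

@dataclass
class EncodedBlock:
    """An encoded payload plus everything needed to decode it.

    ``codebook_mode`` selects what is embedded: an explicit codeword table,
    an insertion-ordered frequency table (canonically rebuilt on read), or
    nothing ("external": both sides already share the codewords, so none
    are stored in the output file).
    """

    bits: str
    granularity: str = "char"
    m: int = 1
    alpha: Optional[float] = None
    codebook_mode: str = "explicit"
    codebook: Optional[Codebook] = None
    table: Optional[FrequencyTable] = None

    @property
    def payload_bit_count(self) -> int:
        return len(self.bits)


def write_block(block: EncodedBlock, path: Union[str, Path]) -> None:
    if block.granularity not in GRANULARITIES:
        raise ValueError(f"unknown granularity {block.granularity!r}")
    if block.codebook_mode not in _MODES:
        raise ValueError(f"unknown codebook mode {block.codebook_mode!r}")
    if block.codebook_mode == "external":
        cb_bytes = b""
    else:
        cb_bytes = codebook_to_text(
            book=block.codebook,
            table=block.table,
            mode=block.codebook_mode,
            granularity=block.granularity,
        ).encode("utf-8")
    payload = pack_bits(block.bits)
    header = _HEADER.pack(
        _MAGIC,
        _VERSION,
        _GRAN_CODE[block.granularity],
        _MODE_CODE[block.codebook_mode],
        block.m,
        block.alpha if block.alpha is not None else float("nan"),
        len(cb_bytes),
        len(block.bits),
    )
    Path(path).write_bytes(header + cb_bytes + payload)


def read_block(path: Union[str, Path]) -> EncodedBlock:
    data = Path(path).read_bytes()
    if len(data) < _HEADER.size:
        raise TruncatedStreamError("truncated container: incomplete header")
    magic, version, gran_code, mode_code, m, alpha, cb_len, bit_count = _HEADER.unpack(
        data[: _HEADER.size]
    )
    if magic != _MAGIC:
        raise ContainerFormatError("bad magic: not a gramhuff container")
    if version != _VERSION:
        raise ContainerFormatError(f"unsupported container version {version}")
    try:
        granularity = GRANULARITIES[gran_code]
        mode = _MODES[mode_code]
    except IndexError as exc:
        raise ContainerFormatError("bad granularity/mode code") from exc
    body = data[_HEADER.size :]
    if len(body) < cb_len:
        raise TruncatedStreamError("truncated container: incomplete codebook block")
    cb_bytes, payload = body[:cb_len], body[cb_len:]
    expected = (bit_count + 7) // 8
    if len(payload) < expected:
        raise TruncatedStreamError("truncated container: incomplete payload")
    if len(payload) > expected:
        raise ContainerFormatError("payload bit count inconsistent with payload size")
    bits = unpack_bits(payload, bit_count)
    codebook = None
    table = None
    if mode != "external":
        codebook = codebook_from_text(cb_bytes.decode("utf-8"))
    alpha_val = None if alpha != alpha else alpha  # NaN marks "not recorded"
    return EncodedBlock(
        bits=bits,
        granularity=granularity,
        m=m,
        alpha=alpha_val,
        codebook_mode=mode,
        codebook=codebook,
        table=table,
    )
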