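"""Backslash escaping of grams for the line-oriented text formats.

Tab, newline, carriage return and backslash would break a TSV record, and
control characters would make files unreadable; everything else (including
Latin-1 mapped bytes >= 0x80) is written verbatim.
"""

from __future__ import annotations

from .errors import ContainerFormatError

_FORWARD = {"\\": "\\\\", "\t": "\\t", "\n": "\\n", "\r": "\\r"}
_BACKWARD = {"\\": "\\", "t": "\t", "n": "\n", "r": "\r"}


def escape_gram(gram: str) -> str:
    out = []
    for ch in gram:
        if ch in _FORWARD:
            out.append(_FORWARD[ch])
        elif ord(ch) < 0x20 or ord(ch) == 0x7F:
            out.append(f"\\x{ord(ch):02x}")
        else:
            out.append(ch)
    return "".join(out)


def unescape_gram(text: str) -> str:
    out = []
    i = 0
    while i < len(text):
        ch = text[i]
        if ch != "\\":
            out.append(ch)
            i += 1
            continue
        if i + 1 >= len(text):
            raise ContainerFormatError(f"dangling escape in gram field: {text!r}")
        nxt = text[i + 1]
        if nxt == "x":
            if i + 4 > len(text):
                raise ContainerFormatError(f"bad \\x escape in gram field: {text!r}")
            out.append(chr(int(text[i + 2 : i + 4], 16)))
            i += 4
        elif nxt in _BACKWARD:
            out.append(_BACKWARD[nxt])
            i += 2
        else:
            raise ContainerFormatError(f"unknown escape \\{nxt} in gram field: {text!r}")
    return "".join(out)
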