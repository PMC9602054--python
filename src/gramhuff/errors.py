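"""Exception hierarchy for the gramhuff codec.

Everything the library raises on bad data derives from :class:`CodecError`,
so callers (and the CLI) can distinguish data problems from programming
errors with a single ``except`` clause.
"""


class CodecError(Exception):
    """Base class for all data-dependent codec failures."""


class EmptyInputError(CodecError):
    """An operation received an empty sequence or table."""


class UnencodableSymbolError(CodecError):
    """The input contains a symbol with no codeword in the codebook."""


class InvalidCodebookError(CodecError):
    """The codebook is not prefix-free or otherwise malformed."""


class TruncatedStreamError(CodecError):
    """An encoded bit stream or container file ended mid-record."""


class CorruptStreamError(CodecError):
    """An encoded bit stream walked off the decode tree."""


class ContainerFormatError(CodecError):
    """An encoded container file has a bad magic tag, version or header."""


class AlphabetMismatchError(CodecError):
    """Test data contains symbols absent from the pattern alphabet."""
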