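"""Exception taxonomy shared by all cipoc modules."""


class CipocError(Exception):
    """Base class for all cipoc errors."""


class UsageError(CipocError, ValueError):
    """A caller violated an operation's contract (bad argument, bad state)."""


class ParseError(CipocError, ValueError):
    """A structure file could not be parsed; message carries line/record context."""


class UnsupportedFormatError(ParseError):
    """A recognized but unsupported dialect (e.g. SDF V3000)."""


class GeometryError(CipocError, ValueError):
    """A geometric construction is degenerate (collinear axis, zero-length vector)."""


class ValidationError(CipocError, ValueError):
    """Input data is internally inconsistent (e.g. negative distortion energy)."""
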