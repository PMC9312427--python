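"""Exception hierarchy.

All data-dependent failures raise :class:`SkylineCheckError` subclasses so the
CLI can distinguish bad input (exit 1) from bad usage (exit 2).
"""


class SkylineCheckError(Exception):
    """Base class for all input/data errors raised by skylinecheck."""


class NewickParseError(SkylineCheckError):
    """Malformed newick input (syntax error or missing branch length)."""


class TreeStructureError(SkylineCheckError):
    """Tree violates structural requirements (polytomy, too few tips, ...)."""


class NotUltrametricError(SkylineCheckError):
    """Root-to-tip path lengths disagree beyond the allowed tolerance."""


class SkylineFormatError(SkylineCheckError):
    """Skyline reconstruction table cannot be parsed or is inconsistent."""


class DegenerateTreeError(SkylineCheckError):
    """Tree carries no usable time information (all intervals zero)."""
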