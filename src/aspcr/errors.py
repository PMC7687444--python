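"""Exception hierarchy shared across the toolkit."""


class AspcrError(Exception):
    """Base class for all toolkit errors."""


class AlphabetError(AspcrError, ValueError):
    """A sequence contains a character outside the IUPAC-DNA alphabet."""


class AlignmentShapeError(AspcrError, ValueError):
    """Records in an alignment do not share a common length."""


class LabellingError(AspcrError, KeyError):
    """A record id has no species label, or a species is unknown."""

    def __str__(self) -> str:  # KeyError quotes its message; undo that
        return super(KeyError, self).__str__()


class ConfigurationError(AspcrError, ValueError):
    """Parameters are inconsistent with the requested operation."""


class GeometryError(AspcrError, ValueError):
    """A primer footprint or amplicon layout is impossible."""


class GapError(AspcrError, ValueError):
    """A gap character falls where an ungapped sequence is required."""


class SaturationError(AspcrError, ArithmeticError):
    """A distance correction is undefined (log argument <= 0)."""
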