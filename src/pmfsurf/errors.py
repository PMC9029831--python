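"""Exception hierarchy."""


class PmfsurfError(Exception):
    """Base class for all package errors."""


class FormatError(PmfsurfError):
    """Malformed input file (missing column, bad header, ...)."""


class EmptyInputError(PmfsurfError):
    """An input file or selection contained no usable rows."""


class UnitError(PmfsurfError):
    """Dimensionally incompatible or unknown unit tags."""


class DomainError(PmfsurfError):
    """A grid or region lies outside the domain it must be contained in."""


class ConsistencyError(PmfsurfError):
    """An internal invariant was violated (e.g. non-constant reference row)."""


class GeometryError(PmfsurfError):
    """Degenerate or out-of-range molecular geometry."""


class EmptyDistributionError(PmfsurfError):
    """A histogram was requested over an empty sample selection."""


class AmbiguityError(PmfsurfError):
    """Periodic unwrapping is ambiguous (jump of half a box or more)."""


class DegeneratePairError(PmfsurfError):
    """A pairwise operation was given the same state twice."""
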