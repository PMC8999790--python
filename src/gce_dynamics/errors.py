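"""Exception hierarchy shared by all analysis stages."""


class GCEDynamicsError(Exception):
    """Base class for all package-specific errors."""


class ParseError(GCEDynamicsError):
    """A structure or trajectory file could not be parsed."""


class EmptyInputError(GCEDynamicsError):
    """An input contained no usable records or points."""


class StructuralMismatchError(GCEDynamicsError):
    """Two structures or frames disagree on atom count or labels."""


class SelectionError(GCEDynamicsError, KeyError):
    """A requested residue or atom is absent from the structure."""

    def __str__(self) -> str:  # KeyError quotes its message otherwise
        return Exception.__str__(self)


class ConfigurationError(GCEDynamicsError):
    """A run configuration is inconsistent or incomplete."""


class ConditioningError(GCEDynamicsError):
    """A numerical problem is degenerate (too few or collinear points)."""


class DegenerateDataError(GCEDynamicsError):
    """A dataset carries no signal the requested fit could use."""
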