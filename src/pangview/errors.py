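"""Exception hierarchy shared across the package.

All domain-specific failures derive from :class:`PangviewError` so callers
(and the CLI) can distinguish user-facing problems from genuine bugs.
"""


class PangviewError(Exception):
    """Base class for all pangview errors."""


class GFAParseError(PangviewError):
    """Malformed GFA input; carries the 1-based line number when known."""

    def __init__(self, message: str, line_number: int | None = None):
        self.line_number = line_number
        if line_number is not None:
            message = f"line {line_number}: {message}"
        super().__init__(message)


class DuplicateSegmentError(GFAParseError):
    """Two S lines declare the same segment id."""


class GraphReferenceError(PangviewError):
    """A path step or edge refers to a segment that does not exist."""


class GraphValidationError(PangviewError):
    """Strict-mode load found invariant violations."""


class GFF3ParseError(PangviewError):
    """Malformed GFF3 input."""


class BindingError(PangviewError):
    """Annotation seqids could not be resolved to graph paths."""


class FeatureRangeError(PangviewError):
    """A feature extends beyond the length of its bound path."""


class RegionParseError(PangviewError):
    """A region string did not match ``PATH:start-end``."""


class LookupError_(PangviewError, KeyError):
    """Unknown path, node or gene identifier."""


class RangeError(PangviewError):
    """A coordinate lies outside its valid range."""


class DomainError(PangviewError):
    """An argument is outside the operation's domain (e.g. negative length)."""


class AbsenceError(PangviewError):
    """A genome required to traverse a region does not appear in it."""


class DegenerateGroupingError(PangviewError):
    """Phenotype grouping left one side empty."""


class PlacementError(PangviewError):
    """Variant sampling could not place all variants without overlap."""


class ConfigurationError(PangviewError):
    """A simulation was asked for something its truth model does not define."""


class LayoutError(PangviewError):
    """Tube-map layout cannot be computed (e.g. empty subgraph)."""
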