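"""Exception hierarchy.

Errors are grouped by where in a pipeline they arise so the CLI can map
them onto stable exit codes: configuration (2), input data (3), numerics (4).
"""


class BilayerlabError(Exception):
    """Base class for all package errors."""


class ConfigError(BilayerlabError):
    """Invalid or contradictory run configuration."""


class FormatError(BilayerlabError):
    """Unreadable or unsupported input file."""


class SelectionError(BilayerlabError):
    """A particle selection matched nothing or could not be parsed."""


class ParameterError(BilayerlabError):
    """A parameter value is out of its valid range."""


class GeometryError(BilayerlabError):
    """Degenerate geometry (coincident endpoints, hole larger than image...)."""


class AmbiguousLeafletError(BilayerlabError):
    """Headgroup z values do not separate into two leaflets."""


class FitError(BilayerlabError):
    """A least-squares problem is rank deficient or under-determined."""


class LeafletOrderError(BilayerlabError):
    """Upper/lower leaflet surfaces cross (negative thickness)."""


class AggregationError(BilayerlabError):
    """Empty window or region in a time/space aggregation."""


class NoStepError(BilayerlabError):
    """No detectable step in an AFM profile or image."""
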