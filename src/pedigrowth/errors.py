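"""Exception hierarchy.

All pedigrowth errors derive from :class:`GrowthError` (a ``ValueError``),
so callers can catch either the package root or the specific class.
"""


class GrowthError(ValueError):
    """Base class for all pedigrowth errors."""


class DomainError(GrowthError):
    """An input value is outside the mathematical domain of an operation."""


class UsageError(GrowthError):
    """Inputs are structurally wrong or insufficient for the request."""


class ConsistencyError(GrowthError):
    """Redundant inputs disagree with each other."""


class ChartLoadError(GrowthError):
    """A growth-reference table failed validation while loading."""


class ChartRangeError(GrowthError):
    """An age falls outside a chart's knot range; no extrapolation is done."""


class ModelFitError(GrowthError):
    """A regression design is singular or otherwise unfit-able."""
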