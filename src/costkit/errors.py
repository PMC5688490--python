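"""Exception hierarchy.

Every error raised by costkit derives from :class:`CostKitError`, so callers
can catch one type. Validation failures always name the offending table and
row; nothing is silently clamped or defaulted.
"""


class CostKitError(Exception):
    """Base class for all costkit errors."""


class ScenarioValidationError(CostKitError, ValueError):
    """A configuration table or cross-reference failed validation."""


class DomainError(CostKitError, ValueError):
    """An input to a costing operation is outside its mathematical domain."""


class EstimationError(CostKitError, ValueError):
    """The econometric fit cannot proceed (singular design, too few rows)."""


class UndefinedRatioError(CostKitError, ZeroDivisionError):
    """A cost-effectiveness ratio with a zero effect denominator."""


class ComparisonError(CostKitError, ValueError):
    """Two scenarios are not comparable (mismatched years or interventions)."""
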