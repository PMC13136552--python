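"""Exception types raised across the pipeline."""


class BranchCarbonError(ValueError):
    """Base class for all package-specific errors."""


class InvalidConfigError(BranchCarbonError):
    """A scenario or pipeline configuration violates an invariant."""


class FitError(BranchCarbonError):
    """A light-response curve cannot be fitted (too few or degenerate data)."""


class GapError(BranchCarbonError):
    """A time series does not cover the span required by a computation."""


class AlignmentError(BranchCarbonError):
    """Series that must share a common date index do not."""


class TableFormatError(BranchCarbonError):
    """A delimited input table is malformed (missing columns, bad rows)."""
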