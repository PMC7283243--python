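"""Exception hierarchy shared across the package."""

__all__ = [
    "TnfkinError",
    "SchemaError",
    "DataError",
    "FitError",
    "FlatTraceError",
    "IdentifiabilityWarning",
]


class TnfkinError(Exception):
    """Base class for package errors."""


class SchemaError(TnfkinError):
    """Input file does not conform to the expected schema."""


class DataError(TnfkinError):
    """Input values are malformed (non-monotone time, negative conc, ...)."""


class FitError(TnfkinError):
    """Nonlinear fit failed to converge or hit a parameter boundary."""


class FlatTraceError(FitError):
    """Trace carries no resolvable amplitude; a decay rate cannot be fitted."""


class IdentifiabilityWarning(UserWarning):
    """Fit succeeded but parameters are poorly identifiable from the design."""
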