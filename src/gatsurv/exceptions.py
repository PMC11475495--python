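"""Exception hierarchy for gatsurv."""


class GatsurvError(Exception):
    """Base class for all package errors."""


class ConfigurationError(GatsurvError, ValueError):
    """An infeasible or out-of-range configuration value."""


class ParseError(GatsurvError, ValueError):
    """A dataset file failed validation; the message names the offending row/column."""


class DegenerateTableError(GatsurvError, ValueError):
    """A contingency table with a zero row or column margin (expected counts undefined)."""


class UndefinedCorrelationError(GatsurvError, ValueError):
    """Pearson correlation requested for a constant vector."""


class ConvergenceError(GatsurvError, RuntimeError):
    """An iterative fit failed to reach its tolerance."""


class NumericalError(GatsurvError, RuntimeError):
    """Non-finite values appeared during model evaluation or training."""
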