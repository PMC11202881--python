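"""Exception hierarchy shared across the package."""


class QTrustError(Exception):
    """Base class for package-specific errors."""


class SchemaError(QTrustError, ValueError):
    """A tabular input is missing a required column or field."""


class ValidationError(QTrustError, ValueError):
    """A record or matrix violates one of its structural invariants."""


class EstimationError(QTrustError, ValueError):
    """An empirical quantity is undefined on the supplied data
    (e.g. a conditional probability with an empty conditioning cell)."""


class ParameterError(QTrustError, ValueError):
    """A model parameter bundle violates its feasibility constraints."""


class InfeasibleInterferenceError(QTrustError, ValueError):
    """Observed probabilities cannot be produced by any interference phase
    (|cos theta| would exceed 1)."""


class NumericalFailureError(QTrustError, RuntimeError):
    """A propagated state left its admissible set beyond tolerance."""
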