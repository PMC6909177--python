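"""Exception and warning hierarchy shared across the package."""


class SrsPreError(Exception):
    """Base class for all srspre errors."""


class ValidationError(SrsPreError):
    """A record or value violates a domain invariant."""


class CohortParseError(SrsPreError):
    """A cohort file row or cell could not be parsed."""


class ScalingError(SrsPreError):
    """A dose-rescaling query is inconsistent (e.g. dose above plan maximum,
    or mapped isodose percent outside the tabulated curve)."""


class FitError(SrsPreError):
    """A regression stage cannot be run (too few points, degenerate design,
    non-positive volumes) or did not converge."""


class ModelDomainError(SrsPreError):
    """The fitted surface is invalid at the queried prescription dose
    (non-positive dose multiplier n*PD + d)."""


class ExtrapolationWarning(UserWarning):
    """A query lies outside the PD or PTV range the model was fitted on.

    The value is still returned: pre-planning is advisory, but silent
    extrapolation would hide model misuse.
    """


class NegativePredictionWarning(UserWarning):
    """A predicted V12 came out negative.

    Negative predictions are returned unclamped: they preserve invertibility
    and flag an out-of-domain query (typically GTV larger than the whole
    predicted 12 Gy volume).
    """
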