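"""Forward and inverse queries on a fitted TV12 surface, and printed-protocol
prescription-dose lookup.

The fitted surface is

    TV12(PTV, PD) = (n*PD + d) * PTV^(a*PD^c)     [cc, Gy]

and the normal-brain metric follows as V12 = TV12 - GTV.  Because the
surface is strictly monotone in both PTV and PD over its validity domain,
the pre-planning questions "how much margin can I afford?" and "how high can
I prescribe?" have unique answers: the PTV inverse is closed form and the PD
inverse is a bracketed scalar root find.

Queries outside the fitted PD/PTV ranges are answered but flagged with
:class:`~srspre.errors.ExtrapolationWarning`; negative V12 predictions are
returned unclamped with :class:`~srspre.errors.NegativePredictionWarning`.
"""

from __future__ import annotations

import enum
import warnings
from dataclasses import dataclass

from scipy import optimize

from .errors import (
    ExtrapolationWarning,
    ModelDomainError,
    NegativePredictionWarning,
    ValidationError,
)
from .fitting import ModelParams
from .records import PlanType

#: Absolute tolerance (Gy) of the PD inverse root find.
PD_ROOT_TOL = 1e-6


@dataclass(frozen=True)
class PrePlanQuery:
    """A pre-planning question: lesion geometry plus either a candidate PD or
    a V12 goal driving an inverse search."""

    plan_type: PlanType
    gtv: float
    ptv: float
    pd: float | None = None
    v12_goal: float | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan_type", PlanType(self.plan_type))
        if self.gtv < 0 or self.ptv <= 0:
            raise ValidationError("gtv must be >= 0 and ptv > 0")
        if self.gtv > self.ptv:
            raise ValidationError("gtv <= ptv violated")


def _dose_multiplier(model: ModelParams, pd: float) -> float:
    mult = model.n * pd + model.d
    if mult <= 0:
        raise ModelDomainError(
            f"dose multiplier n*pd + d = {mult:.4g} <= 0 at pd = {pd} Gy; the "
            f"surface is invalid below ~{-model.d / model.n:.2f} Gy"
        )
    return mult


def _warn_domain(model: ModelParams, ptv: float | None, pd: float | None) -> None:
    if pd is not None and not (model.pd_domain[0] <= pd <= model.pd_domain[1]):
        warnings.warn(
            f"pd = {pd} Gy outside fitted range {model.pd_domain}",
            ExtrapolationWarning,
            stacklevel=3,
        )
    if ptv is not None and not (model.ptv_domain[0] <= ptv <= model.ptv_domain[1]):
        warnings.warn(
            f"ptv = {ptv} cc outside fitted range {model.ptv_domain}",
            ExtrapolationWarning,
            stacklevel=3,
        )


def predict_tv12(model: ModelParams, ptv: float, pd: float) -> float:
    """Predicted total 12 Gy volume (cc) at a given PTV (cc) and PD (Gy)."""
    if ptv <= 0:
        raise ValidationError("ptv must be > 0")
    if pd <= 0:
        raise ValidationError("pd must be > 0")
    mult = _dose_multiplier(model, pd)
    _warn_domain(model, ptv, pd)
    return mult * ptv ** (model.a * pd**model.c)


def predict_v12(model: ModelParams, ptv: float, pd: float, gtv: float) -> float:
    """Predicted normal-brain 12 Gy volume, TV12 - GTV (cc).

    Valid when the 12 Gy surface stays within brain parenchyma; when it
    exits the parenchyma the unclipped TV12 overestimates the true V12.
    """
    if gtv < 0:
        raise ValidationError("gtv must be >= 0")
    v12 = predict_tv12(model, ptv, pd) - gtv
    if v12 < 0:
        warnings.warn(
            f"predicted v12 = {v12:.4g} cc is negative (gtv exceeds the "
            "predicted 12 Gy volume): out-of-domain query",
            NegativePredictionWarning,
            stacklevel=2,
        )
    return v12


def max_ptv_for_goal(
    model: ModelParams, pd: float, gtv: float, v12_goal: float
) -> float:
    """Largest PTV (cc) whose predicted V12 still equals the goal.

    Closed-form inversion of the surface:
    ptv = ((v12_goal + gtv) / (n*pd + d))^(1 / (a*pd^c)).
    """
    if v12_goal + gtv <= 0:
        raise ValidationError("v12_goal + gtv must be > 0")
    mult = _dose_multiplier(model, pd)
    exponent = model.a * pd**model.c
    if exponent <= 0:
        raise ModelDomainError(f"surface exponent a*pd^c <= 0 at pd = {pd} Gy")
    ptv = ((v12_goal + gtv) / mult) ** (1.0 / exponent)
    _warn_domain(model, ptv, pd)
    return ptv


@dataclass(frozen=True)
class PdSolution:
    """Result of the PD inverse search.

    ``pd`` is the dose meeting the V12 goal, or ``None`` when the goal is
    unattainable in the searched range; the boundary predictions are carried
    either way so the caller can see how far off the goal is.
    """

    pd: float | None
    attainable: bool
    v12_at_min: float
    v12_at_max: float
    pd_range: tuple[float, float]


def max_pd_for_goal(
    model: ModelParams,
    ptv: float,
    gtv: float,
    v12_goal: float,
    pd_range: tuple[float, float] | None = None,
) -> PdSolution:
    """Highest PD (Gy) whose predicted V12 equals the goal, within a range.

    Predicted V12 is strictly increasing in PD over the validity domain, so
    the root is unique when bracketed.  Defaults to the model's fitted PD
    range.  An out-of-bracket goal yields an explicit no-solution result, not
    an exception.
    """
    lo, hi = pd_range if pd_range is not None else model.pd_domain
    if not (0 < lo < hi):
        raise ValidationError("pd_range must satisfy 0 < lo < hi")

    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        f_lo = predict_v12(model, ptv, lo, gtv) - v12_goal
        f_hi = predict_v12(model, ptv, hi, gtv) - v12_goal
    v_lo, v_hi = f_lo + v12_goal, f_hi + v12_goal

    if abs(f_lo) <= 1e-12:
        root = lo
    elif abs(f_hi) <= 1e-12:
        root = hi
    elif f_lo > 0 or f_hi < 0:
        return PdSolution(
            pd=None, attainable=False, v12_at_min=v_lo, v12_at_max=v_hi,
            pd_range=(lo, hi),
        )
    else:
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            root = float(
                optimize.brentq(
                    lambda pd: predict_v12(model, ptv, pd, gtv) - v12_goal,
                    lo,
                    hi,
                    xtol=PD_ROOT_TOL,
                )
            )
    return PdSolution(
        pd=root, attainable=True, v12_at_min=v_lo, v12_at_max=v_hi,
        pd_range=(lo, hi),
    )


# ---------------------------------------------------------------------------
# Printed protocol dose guidelines
# ---------------------------------------------------------------------------


class Protocol(str, enum.Enum):
    """Cooperative-group SRS dose guidelines keyed to maximal lesion diameter."""

    RTOG_9005 = "RTOG_9005"
    RTOG_1270 = "RTOG_1270"


#: Local prescribing convention: SRS is not offered for targets whose maximal
#: diameter exceeds this value (mm).
LOCAL_MAX_DIAMETER_MM = 20.0


@dataclass(frozen=True)
class GuidelineDose:
    """Protocol lookup result.

    ``dose`` is ``None`` (and ``eligible`` False) beyond the last printed
    diameter bracket.  ``within_local_convention`` additionally marks whether
    a conservative clinic treating only <= 20 mm targets would accept the case.
    """

    dose: float | None
    eligible: bool
    within_local_convention: bool


def rtog_dose_guideline(
    max_diameter: float, protocol: Protocol | str
) -> GuidelineDose:
    """Guideline prescription dose (Gy) for a lesion of maximal diameter (mm).

    RTOG 90-05 (recurrent, previously irradiated metastases): 24 Gy for
    <= 20 mm, 18 Gy for 21-30 mm, 15 Gy for 31-40 mm.  The printed integer
    brackets leave (20, 21) mm unassigned; such diameters fall in the 18 Gy
    bracket here.  RTOG 1270 (unresected metastases): 24 Gy for < 10 mm,
    22 Gy for 10-19.99 mm, 20 Gy for 20-29.99 mm; >= 30 mm is not eligible.
    """
    if max_diameter <= 0:
        raise ValidationError("max_diameter must be > 0")
    protocol = Protocol(protocol)
    if protocol is Protocol.RTOG_9005:
        if max_diameter <= 20.0:
            dose = 24.0
        elif max_diameter <= 30.0:
            dose = 18.0
        elif max_diameter <= 40.0:
            dose = 15.0
        else:
            dose = None
    else:  # RTOG_1270
        if max_diameter < 10.0:
            dose = 24.0
        elif max_diameter < 20.0:
            dose = 22.0
        elif max_diameter < 30.0:
            dose = 20.0
        else:
            dose = None
    return GuidelineDose(
        dose=dose,
        eligible=dose is not None,
        within_local_convention=max_diameter <= LOCAL_MAX_DIAMETER_MM,
    )


def advise(
    model: ModelParams,
    query: PrePlanQuery,
    v12_goal: float = 3.3,
    pd_range: tuple[float, float] | None = None,
) -> dict:
    """Answer a pre-planning query as a machine-readable report.

    For a query with a candidate PD the report carries the predicted TV12 and
    V12 and whether the V12 goal is met; either way it carries the largest
    admissible PTV at each bound of the PD range and, when a PD is given, the
    highest PD meeting the goal at the queried PTV.
    """
    goal = query.v12_goal if query.v12_goal is not None else v12_goal
    lo, hi = pd_range if pd_range is not None else model.pd_domain
    report: dict = {
        "plan_type": model.plan_type.value,
        "gtv_cc": query.gtv,
        "ptv_cc": query.ptv,
        "v12_goal_cc": goal,
    }
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        if query.pd is not None:
            tv12 = predict_tv12(model, query.ptv, query.pd)
            v12 = tv12 - query.gtv
            report.update(
                pd_gy=query.pd,
                predicted_tv12_cc=tv12,
                predicted_v12_cc=v12,
                v12_goal_met=v12 < goal,
            )
        sol = max_pd_for_goal(model, query.ptv, query.gtv, goal, (lo, hi))
        report["max_pd_for_goal_gy"] = sol.pd
        report["goal_attainable_in_pd_range"] = sol.attainable
        report["max_ptv_at_pd_range"] = {
            str(pd): max_ptv_for_goal(model, pd, query.gtv, goal) for pd in (lo, hi)
        }
    return report
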