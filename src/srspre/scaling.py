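"""Prescription-dose rescaling of plan dosimetry.

Changing only the prescription dose (PD) of a plan rescales the absolute
dose everywhere by the same factor and leaves the *relative* dose
distribution untouched.  Consequently COV, PIDL, CI and every isodose line
are unchanged, and the 12 Gy volume at any new PD can be read directly off
the plan's isodose-volume curve at the isodose percent onto which 12 Gy
maps.  This lets one clinical plan stand in for a whole family of plans at
different prescriptions without recomputing dose.

Two percent conventions appear in clinical practice and both are provided
explicitly: percent of the plan *maximum* dose (what a DVH indexed by PTVMD
uses) and percent of the *prescription* dose.  With the prescription isodose
line at PIDL percent of maximum, a dose D maps to

    percent of max = 100 * D * (PIDL/100) / PD
    percent of PD  = 100 * D / PD
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Literal, Sequence

from .errors import ScalingError
from .records import IsodoseVolumeCurve, PlanRecord, PlanType

EvalMode = Literal["interp", "bin1pct"]


@dataclass(frozen=True)
class RescaledPlan:
    """A plan re-prescribed at ``new_pd`` with TV12 read off its curve.

    CI, COV and PIDL are those of the base plan by construction (relative
    dose invariance).  Exposes the same field names as
    :class:`~srspre.records.PlanRecord` so rescaled cohorts feed directly
    into the fitting and comparison stages.
    """

    base: PlanRecord
    new_pd: float
    tv12_at_new_pd: float

    def __post_init__(self) -> None:
        if self.new_pd <= 0:
            raise ScalingError("new_pd must be > 0")
        if self.tv12_at_new_pd < 0:
            raise ScalingError("tv12_at_new_pd must be >= 0")

    @property
    def plan_id(self) -> str:
        return self.base.plan_id

    @property
    def plan_type(self) -> PlanType:
        return self.base.plan_type

    @property
    def pd(self) -> float:
        return self.new_pd

    @property
    def ptv(self) -> float:
        return self.base.ptv

    @property
    def gtv(self) -> float:
        return self.base.gtv

    @property
    def tv12(self) -> float:
        return self.tv12_at_new_pd

    @property
    def ci(self) -> float | None:
        return self.base.ci

    @property
    def cov(self) -> float | None:
        return self.base.cov

    @property
    def pidl(self) -> float | None:
        return self.base.pidl


def isodose_percent_for_dose(dose: float, pd: float, pidl: float) -> float:
    """Dose expressed as percent of the plan maximum, given PD at pidl% of max.

    With the prescription isodose line fixed at 80%, 12 Gy maps to 64, 53.3,
    45.7 and 40% of maximum for PD = 15, 18, 21 and 24 Gy.
    """
    if dose <= 0 or pd <= 0:
        raise ScalingError("dose and pd must be > 0")
    if not (0.0 < pidl <= 100.0):
        raise ScalingError("pidl must be in (0, 100]")
    percent = 100.0 * dose * (pidl / 100.0) / pd
    if percent > 100.0:
        raise ScalingError(
            f"dose {dose} Gy exceeds the plan maximum ({pd / (pidl / 100.0):.3f} Gy)"
        )
    return percent


def isodose_percent_of_pd(dose: float, pd: float) -> float:
    """Dose expressed as percent of the prescription dose
    (e.g. 12 Gy is the 50% line at PD = 24 Gy and the 80% line at 15 Gy)."""
    if dose <= 0 or pd <= 0:
        raise ScalingError("dose and pd must be > 0")
    return 100.0 * dose / pd


def tv_at_dose(
    curve: IsodoseVolumeCurve,
    dose: float,
    pd: float,
    pidl: float,
    mode: EvalMode = "interp",
) -> float:
    """Enclosed volume (cc) at ``dose`` Gy for a plan prescribed ``pd`` Gy.

    ``mode="interp"`` interpolates the curve linearly at the exact mapped
    percent.  ``mode="bin1pct"`` first rounds the dose to the nearest 1% of
    PD, emulating a planning system whose DVH reports dose in 1%-of-PD steps.
    """
    if mode == "bin1pct":
        pct_of_pd = round(isodose_percent_of_pd(dose, pd))
        percent = pct_of_pd * pidl / 100.0
        if percent > 100.0:
            raise ScalingError("binned dose exceeds the plan maximum")
    elif mode == "interp":
        percent = isodose_percent_for_dose(dose, pd, pidl)
    else:
        raise ValueError(f"unknown mode {mode!r}")
    try:
        return curve.volume_at(percent)
    except Exception as exc:
        raise ScalingError(str(exc)) from None


def rescale_plan(
    plan: PlanRecord,
    new_pd: float,
    dose: float = 12.0,
    mode: EvalMode = "interp",
) -> RescaledPlan:
    """Re-prescribe one plan at ``new_pd`` and read TV12 off its curve."""
    if plan.curve is None:
        raise ScalingError(f"plan {plan.plan_id}: no isodose-volume curve")
    if plan.pidl is None:
        raise ScalingError(f"plan {plan.plan_id}: pidl is absent")
    tv = tv_at_dose(plan.curve, dose, new_pd, plan.pidl, mode=mode)
    return RescaledPlan(base=plan, new_pd=new_pd, tv12_at_new_pd=tv)


def expand_cohort(
    plans: Iterable[PlanRecord],
    pd_list: Sequence[float],
    mode: EvalMode = "interp",
) -> list[RescaledPlan]:
    """Expand a cohort over several prescription doses.

    Every plan must carry an isodose-volume curve and a PIDL.  The result has
    ``len(plans) * len(pd_list)`` records; CI, COV and PIDL of each rescaled
    record are those of its base plan, and TV12 is read at 12 Gy.
    """
    out: list[RescaledPlan] = []
    for plan in plans:
        for new_pd in pd_list:
            out.append(rescale_plan(plan, new_pd, mode=mode))
    return out
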