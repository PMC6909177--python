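"""Paired CAT-vs-DCAT plan comparison.

For each lesion planned both ways, the conformity and low-dose-spread changes
are the percent differences of the DCAT re-plan relative to the CAT plan:

    dCI   = 100 * (CI_DCAT   - CI_CAT)   / CI_CAT
    dTV12 = 100 * (TV12_DCAT - TV12_CAT) / TV12_CAT

DCAT usually wins on conformity (dCI < 0) but loses on low-dose spread
(dTV12 > 0) because the mMLC penumbra is wider than a cone's, and the effect
grows with PD.  The per-PD summary (max/min/median and sign counts of dTV12)
and the fitted-surface crossover PTV quantify exactly this trade-off.
"""

from __future__ import annotations

import math
import statistics
from collections import defaultdict
from dataclasses import dataclass
from typing import Iterable, Sequence

from scipy import optimize

from .errors import ValidationError
from .fitting import ModelParams
from .predict import predict_tv12
from .records import PlanType


@dataclass(frozen=True)
class ComparisonRecord:
    """Percent CI and TV12 differences for one CAT/DCAT pair (same plan, PD)."""

    plan_id: str
    ptv: float
    pd: float
    delta_ci: float
    delta_tv12: float

    def __post_init__(self) -> None:
        if not (math.isfinite(self.delta_ci) and math.isfinite(self.delta_tv12)):
            raise ValidationError(f"plan {self.plan_id}: delta values must be finite")


@dataclass(frozen=True)
class ComparisonSummary:
    """Distribution of dTV12 at one PD: extremes, median, and sign counts."""

    pd: float
    n_pairs: int
    max_delta_tv12: float
    min_delta_tv12: float
    median_delta_tv12: float
    count_increasing: int
    count_decreasing: int
    count_unchanged: int


def delta_ci(ci_cat: float, ci_dcat: float) -> float:
    """Percent CI difference of the DCAT re-plan relative to the CAT plan."""
    if ci_cat <= 0:
        raise ValidationError("ci_cat must be > 0")
    return 100.0 * (ci_dcat - ci_cat) / ci_cat


def delta_tv12(tv12_cat: float, tv12_dcat: float) -> float:
    """Percent TV12 difference of the DCAT re-plan relative to the CAT plan."""
    if tv12_cat <= 0:
        raise ValidationError("tv12_cat must be > 0")
    return 100.0 * (tv12_dcat - tv12_cat) / tv12_cat


def pair_cohort(
    records: Iterable,
) -> tuple[list[ComparisonRecord], list[tuple[str, float]]]:
    """Pair records sharing (plan_id, pd) across the two plan types.

    Accepts plan records or rescaled plans.  Returns the comparison records
    (ordered by plan_id then pd) and the (plan_id, pd) keys that could not be
    paired — unpaired records are reported, never silently dropped.
    """
    by_key: dict[tuple[str, float], dict[PlanType, object]] = defaultdict(dict)
    for rec in records:
        key = (rec.plan_id, float(rec.pd))
        pt = PlanType(rec.plan_type)
        if pt in by_key[key]:
            raise ValidationError(
                f"duplicate {pt.value} record for plan {rec.plan_id} at "
                f"pd = {rec.pd} Gy"
            )
        by_key[key][pt] = rec

    pairs: list[ComparisonRecord] = []
    unpaired: list[tuple[str, float]] = []
    for key in sorted(by_key):
        group = by_key[key]
        if len(group) != 2:
            unpaired.append(key)
            continue
        cat, dcat = group[PlanType.CAT], group[PlanType.DCAT]
        for rec in (cat, dcat):
            if rec.tv12 is None or rec.ci is None:
                raise ValidationError(
                    f"plan {rec.plan_id} at pd = {rec.pd} Gy: tv12 and ci "
                    "required for comparison"
                )
        pairs.append(
            ComparisonRecord(
                plan_id=key[0],
                ptv=cat.ptv,
                pd=key[1],
                delta_ci=delta_ci(cat.ci, dcat.ci),
                delta_tv12=delta_tv12(cat.tv12, dcat.tv12),
            )
        )
    return pairs, unpaired


def summarize(pairs: Sequence[ComparisonRecord], pd: float) -> ComparisonSummary:
    """Summarize dTV12 over all pairs at one PD.

    Median of an even-length list is the mean of the middle two; zero deltas
    count as unchanged.
    """
    deltas = [p.delta_tv12 for p in pairs if p.pd == pd]
    if not deltas:
        raise ValidationError(f"no pairs at pd = {pd} Gy")
    return ComparisonSummary(
        pd=pd,
        n_pairs=len(deltas),
        max_delta_tv12=max(deltas),
        min_delta_tv12=min(deltas),
        median_delta_tv12=float(statistics.median(deltas)),
        count_increasing=sum(1 for x in deltas if x > 0),
        count_decreasing=sum(1 for x in deltas if x < 0),
        count_unchanged=sum(1 for x in deltas if x == 0),
    )


#: Relative agreement demanded between the closed-form crossover and the
#: root-finder cross-check.
_CROSSOVER_CHECK_RTOL = 1e-6


def crossover_ptv(
    model_cat: ModelParams,
    model_dcat: ModelParams,
    pd: float,
    cross_check: bool = True,
) -> float | None:
    """PTV (cc) at which the CAT and DCAT surfaces predict the same TV12.

    Below the crossover the DCAT prediction is the larger (penumbra
    dominates); above it the CAT prediction is larger.  In log space the two
    surfaces are straight lines at fixed PD, so the crossover is closed form:

        log10(ptv*) = (b_cat - b_dcat) / (m_dcat - m_cat)

    with m(PD) = a*PD^c and b(PD) = log10(n*PD + d) per plan type.  Returns
    ``None`` when the log-space lines are parallel (no unique crossing).
    A bracketed root find on the raw difference independently confirms the
    closed form when ``cross_check`` is set.
    """
    m_cat, m_dcat = model_cat.slope_at(pd), model_dcat.slope_at(pd)
    b_cat, b_dcat = model_cat.intercept_at(pd), model_dcat.intercept_at(pd)
    dm = m_dcat - m_cat
    if abs(dm) < 1e-12:
        return None
    ptv_star = 10.0 ** ((b_cat - b_dcat) / dm)

    if cross_check:
        lo, hi = ptv_star / 10.0, ptv_star * 10.0

        def diff(ptv: float) -> float:
            import warnings

            with warnings.catch_warnings():
                warnings.simplefilter("ignore")
                return predict_tv12(model_dcat, ptv, pd) - predict_tv12(
                    model_cat, ptv, pd
                )

        root = float(optimize.brentq(diff, lo, hi, rtol=1e-12))
        if abs(root - ptv_star) > _CROSSOVER_CHECK_RTOL * ptv_star:
            raise ValidationError(
                f"crossover cross-check failed: closed form {ptv_star!r} vs "
                f"root finder {root!r}"
            )
    return ptv_star
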