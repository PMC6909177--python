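"""Two-stage hierarchical fit of the TV12 surface.

Stage 1.  Within each category (plan type, PD) the 12 Gy volume follows a
power law in target volume, fit as an ordinary least-squares line in base-10
log space:

    log10(TV12/1cc) = m * log10(PTV/1cc) + b

Stage 2.  Across prescription doses the slope and intercept vary smoothly
and are themselves fit, per plan type, as

    m    = a * (PD/1Gy)^c          (nonlinear least squares on the m scale)
    10^b = n * (PD/1Gy) + d        (ordinary least squares on the 10^b scale)

Substituting stage 2 into stage 1 gives the closed-form prediction surface

    TV12/1cc = (n*PD + d) * (PTV/1cc)^(a*PD^c)

with a separate parameter set per delivery type.  All quantities are
normalized by 1 cc / 1 Gy, so every fit parameter is dimensionless.
"""

from __future__ import annotations

import json
from collections import defaultdict
from dataclasses import asdict, dataclass
from pathlib import Path
from typing import Iterable, Literal, NamedTuple, Sequence

import numpy as np
from scipy import optimize, stats

from .errors import FitError
from .records import PlanType

Stage2SlopeMethod = Literal["nls", "loglinear"]


@dataclass(frozen=True)
class Stage1Fit:
    """Log-log line for one (plan type, PD) category."""

    plan_type: PlanType
    pd: float
    m: float
    b: float
    r2: float
    n_points: int

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan_type", PlanType(self.plan_type))
        if self.r2 > 1 + 1e-12:
            raise FitError("r2 cannot exceed 1")
        if self.n_points < 3:
            raise FitError("a stage-1 fit needs at least 3 points")

    def predict_tv12(self, ptv: float) -> float:
        """Category-level prediction: TV12 = 10^b * PTV^m."""
        return 10.0**self.b * ptv**self.m


class PowerLawFit(NamedTuple):
    """Result of the slope-vs-PD fit m = a*PD^c.

    ``r2`` is computed on the m scale; it is ``None`` when undefined
    (all input slopes identical, so SStot = 0).
    """

    a: float
    c: float
    r2: float | None


class LinearFit(NamedTuple):
    """Result of the intercept-vs-PD fit 10^b = n*PD + d (r2 on the 10^b scale)."""

    n: float
    d: float
    r2: float


@dataclass(frozen=True)
class ModelParams:
    """Fitted TV12 surface for one delivery type.

    ``pd_domain`` and ``ptv_domain`` record the data ranges the surface was
    fitted on; queries outside them are flagged, not refused.
    """

    plan_type: PlanType
    a: float
    c: float
    n: float
    d: float
    r2_slope_fit: float | None
    r2_intercept_fit: float
    pd_domain: tuple[float, float]
    ptv_domain: tuple[float, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan_type", PlanType(self.plan_type))
        object.__setattr__(self, "pd_domain", tuple(self.pd_domain))
        object.__setattr__(self, "ptv_domain", tuple(self.ptv_domain))
        if self.a <= 0:
            raise FitError("a must be > 0")
        for pd in self.pd_domain:
            if self.n * pd + self.d <= 0:
                raise FitError(
                    f"dose multiplier n*pd + d is not positive at pd={pd} Gy"
                )

    def slope_at(self, pd: float) -> float:
        """Stage-2 implied log-log slope m(PD) = a*PD^c."""
        return self.a * pd**self.c

    def intercept_at(self, pd: float) -> float:
        """Stage-2 implied log-log intercept b(PD) = log10(n*PD + d)."""
        mult = self.n * pd + self.d
        if mult <= 0:
            raise FitError(f"dose multiplier n*pd + d <= 0 at pd={pd} Gy")
        return float(np.log10(mult))

    def to_dict(self) -> dict:
        out = asdict(self)
        out["plan_type"] = self.plan_type.value
        out["pd_domain"] = list(self.pd_domain)
        out["ptv_domain"] = list(self.ptv_domain)
        return out

    @classmethod
    def from_dict(cls, data: dict) -> "ModelParams":
        return cls(
            plan_type=PlanType(data["plan_type"]),
            a=data["a"],
            c=data["c"],
            n=data["n"],
            d=data["d"],
            r2_slope_fit=data.get("r2_slope_fit"),
            r2_intercept_fit=data["r2_intercept_fit"],
            pd_domain=tuple(data["pd_domain"]),
            ptv_domain=tuple(data["ptv_domain"]),
        )


def _r2(y: np.ndarray, yhat: np.ndarray) -> float | None:
    sstot = float(np.sum((y - y.mean()) ** 2))
    if sstot == 0.0:
        return None
    return 1.0 - float(np.sum((y - yhat) ** 2)) / sstot


def fit_stage1(
    records: Iterable[tuple[float, float]],
    plan_type: PlanType,
    pd: float,
) -> Stage1Fit:
    """OLS of log10(TV12) on log10(PTV) for one (plan type, PD) category.

    ``records`` is an iterable of (ptv_cc, tv12_cc) pairs; both must be
    positive.  r2 is the coefficient of determination on the log10 scale.
    """
    pts = [(float(p), float(t)) for p, t in records]
    if len(pts) < 3:
        raise FitError(f"category ({plan_type}, {pd} Gy): need >= 3 records")
    ptv = np.array([p for p, _ in pts])
    tv12 = np.array([t for _, t in pts])
    if np.any(ptv <= 0) or np.any(tv12 <= 0):
        raise FitError(
            f"category ({plan_type}, {pd} Gy): volumes must be positive to fit "
            "in log space"
        )
    x = np.log10(ptv)
    y = np.log10(tv12)
    if np.allclose(x, x[0]):
        raise FitError(
            f"category ({plan_type}, {pd} Gy): all PTV equal, slope unfittable"
        )
    res = stats.linregress(x, y)
    return Stage1Fit(
        plan_type=PlanType(plan_type),
        pd=float(pd),
        m=float(res.slope),
        b=float(res.intercept),
        r2=float(res.rvalue**2),
        n_points=len(pts),
    )


def _check_stage2_inputs(stage1: Sequence[Stage1Fit], min_pds: int) -> None:
    if not stage1:
        raise FitError("no stage-1 fits supplied")
    types = {f.plan_type for f in stage1}
    if len(types) != 1:
        raise FitError(f"stage-2 fit mixes plan types: {sorted(t.value for t in types)}")
    pds = {f.pd for f in stage1}
    if len(pds) < min_pds:
        raise FitError(
            f"stage-2 fit needs >= {min_pds} distinct PD values, got {len(pds)}"
        )


def fit_slope_vs_pd(
    stage1: Sequence[Stage1Fit],
    method: Stage2SlopeMethod = "nls",
) -> PowerLawFit:
    """Fit the stage-1 slopes to m = a*PD^c for one plan type.

    ``method="nls"`` (default) runs nonlinear least squares on the m scale,
    initialized from the log-log linear solution; ``method="loglinear"``
    returns the log-log linear solution itself (OLS of log10 m on log10 PD).
    """
    _check_stage2_inputs(stage1, min_pds=3)
    pd = np.array([f.pd for f in stage1])
    m = np.array([f.m for f in stage1])
    if np.any(m <= 0):
        raise FitError("stage-1 slopes must be positive to fit a power law")
    if np.allclose(m, m[0]):
        # Constant slopes: a = m, c = 0 exactly; r2 undefined (SStot = 0).
        return PowerLawFit(a=float(m[0]), c=0.0, r2=None)
    lin = stats.linregress(np.log10(pd), np.log10(m))
    a0, c0 = 10.0**lin.intercept, lin.slope
    if method == "loglinear":
        a, c = float(a0), float(c0)
    elif method == "nls":
        try:
            popt, _ = optimize.curve_fit(
                lambda x, a, c: a * x**c, pd, m, p0=(a0, c0), maxfev=10000
            )
        except RuntimeError as exc:
            raise FitError(f"slope-vs-PD fit did not converge: {exc}") from exc
        a, c = float(popt[0]), float(popt[1])
    else:
        raise ValueError(f"unknown method {method!r}")
    return PowerLawFit(a=a, c=c, r2=_r2(m, a * pd**c))


def fit_intercept_vs_pd(stage1: Sequence[Stage1Fit]) -> LinearFit:
    """Fit the stage-1 intercepts to 10^b = n*PD + d for one plan type."""
    _check_stage2_inputs(stage1, min_pds=2)
    pd = np.array([f.pd for f in stage1])
    tb = 10.0 ** np.array([f.b for f in stage1])
    if np.allclose(pd, pd[0]):
        raise FitError("degenerate PDs: intercept-vs-PD fit unfittable")
    res = stats.linregress(pd, tb)
    return LinearFit(n=float(res.slope), d=float(res.intercept), r2=float(res.rvalue**2))


def assemble_model(
    stage1: Sequence[Stage1Fit],
    ptv_domain: tuple[float, float],
    stage2_slope: Stage2SlopeMethod = "nls",
) -> ModelParams:
    """Run both stage-2 fits on a set of stage-1 lines for one plan type."""
    slope = fit_slope_vs_pd(stage1, method=stage2_slope)
    intercept = fit_intercept_vs_pd(stage1)
    pds = [f.pd for f in stage1]
    return ModelParams(
        plan_type=stage1[0].plan_type,
        a=slope.a,
        c=slope.c,
        n=intercept.n,
        d=intercept.d,
        r2_slope_fit=slope.r2,
        r2_intercept_fit=intercept.r2,
        pd_domain=(min(pds), max(pds)),
        ptv_domain=(float(ptv_domain[0]), float(ptv_domain[1])),
    )


def build_model(
    cohort: Iterable,
    stage2_slope: Stage2SlopeMethod = "nls",
    min_category_size: int = 3,
) -> dict[PlanType, ModelParams]:
    """Full hierarchical fit of a cohort; returns one surface per plan type.

    ``cohort`` is any iterable of records exposing ``plan_type``, ``pd``,
    ``ptv`` and ``tv12`` (plain plan records or rescaled plans).  Each
    (plan type, PD) category needs at least ``min_category_size`` records and
    each plan type at least three PD levels.
    """
    groups: dict[tuple[PlanType, float], list[tuple[float, float]]] = defaultdict(list)
    for rec in cohort:
        if rec.tv12 is None:
            raise FitError(f"plan {rec.plan_id}: tv12 is absent, cannot fit")
        groups[(PlanType(rec.plan_type), float(rec.pd))].append((rec.ptv, rec.tv12))

    missing = [
        f"({pt.value}, {pd} Gy): {len(pts)} records < {min_category_size}"
        for (pt, pd), pts in sorted(groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1]))
        if len(pts) < min_category_size
    ]
    if missing:
        raise FitError("undersized categories: " + "; ".join(missing))

    by_type: dict[PlanType, list[Stage1Fit]] = defaultdict(list)
    for (pt, pd), pts in sorted(groups.items(), key=lambda kv: (kv[0][0].value, kv[0][1])):
        by_type[pt].append(fit_stage1(pts, pt, pd))

    models: dict[PlanType, ModelParams] = {}
    for pt, fits in by_type.items():
        if len({f.pd for f in fits}) < 3:
            raise FitError(
                f"plan type {pt.value}: needs >= 3 PD levels, got "
                f"{sorted({f.pd for f in fits})}"
            )
        all_ptv = [
            p for (pt2, _), pts in groups.items() if pt2 == pt for p, _ in pts
        ]
        models[pt] = assemble_model(
            fits,
            ptv_domain=(min(all_ptv), max(all_ptv)),
            stage2_slope=stage2_slope,
        )
    return models


# ---------------------------------------------------------------------------
# Model file (JSON) I/O
# ---------------------------------------------------------------------------

MODEL_FILE_VERSION = 1


def save_model(
    models: dict[PlanType, ModelParams],
    path: str | Path,
    metadata: dict | None = None,
) -> None:
    """Serialize fitted surfaces (one per plan type) to a JSON model file."""
    from . import __version__

    doc = {
        "format_version": MODEL_FILE_VERSION,
        "software_version": __version__,
        "metadata": metadata or {},
        "models": {pt.value: mp.to_dict() for pt, mp in models.items()},
    }
    Path(path).write_text(json.dumps(doc, indent=2) + "\n", encoding="utf-8")


def load_model(path: str | Path) -> dict[PlanType, ModelParams]:
    doc = json.loads(Path(path).read_text(encoding="utf-8"))
    if doc.get("format_version") != MODEL_FILE_VERSION:
        raise FitError(f"unsupported model file version {doc.get('format_version')!r}")
    return {
        PlanType(key): ModelParams.from_dict(val)
        for key, val in doc["models"].items()
    }
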