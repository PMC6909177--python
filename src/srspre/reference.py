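"""Published reference fit parameters for a 50-plan single-isocenter
SRS cohort (CAT and DCAT, PD = 15, 18, 21, 24 Gy, PIDL initially 80%,
PTV <= 2.43 cc, maximal target diameter <= 18.3 mm).

The raw per-plan dosimetry behind these fits is not publicly deposited; what
is available are the stage-1 log-log line parameters per (plan type, PD)
category and the stage-2 surface parameters per plan type.  They are shipped
as package data so that the fitting pipeline can be checked against them and
so the synthetic-cohort generator has a realistic truth surface.

Stage-1 slopes decrease with PD and are lower for DCAT than CAT at every
dose; stage-1 R^2 spans 0.921-0.947 (CAT) and 0.962-0.974 (DCAT).
"""

from __future__ import annotations

import csv
from importlib import resources

from .fitting import ModelParams, Stage1Fit
from .records import PlanType

#: PD levels of the reference cohort, Gy.
REFERENCE_PD_LEVELS = (15.0, 18.0, 21.0, 24.0)

#: PTV range the reference surfaces were fitted on, cc.  The published upper
#: bound is 2.43 cc; the lower bound of the original cohort is not published
#: and 0.05 cc (a ~4.6 mm sphere, the scale of the smallest cone aperture)
#: is used as a nominal floor.
REFERENCE_PTV_DOMAIN = (0.05, 2.43)

#: Number of plans per (plan type, PD) category in the reference cohort.
REFERENCE_CATEGORY_SIZE = 50


def _read_packaged_csv(name: str) -> list[dict[str, str]]:
    with resources.files("srspre.data").joinpath(name).open(
        "r", encoding="utf-8"
    ) as fh:
        return list(csv.DictReader(fh))


def reference_stage1_fits(
    plan_type: PlanType | str | None = None,
) -> list[Stage1Fit]:
    """Stage-1 (m, b, R^2) reference values, optionally for one plan type."""
    rows = _read_packaged_csv("stage1_reference.csv")
    fits = [
        Stage1Fit(
            plan_type=PlanType(row["plan_type"]),
            pd=float(row["pd_gy"]),
            m=float(row["m"]),
            b=float(row["b"]),
            r2=float(row["r2"]),
            n_points=REFERENCE_CATEGORY_SIZE,
        )
        for row in rows
    ]
    if plan_type is not None:
        want = PlanType(plan_type)
        fits = [f for f in fits if f.plan_type is want]
    return fits


def reference_model(plan_type: PlanType | str) -> ModelParams:
    """Published stage-2 surface parameters (a, c, n, d) for one plan type."""
    want = PlanType(plan_type)
    for row in _read_packaged_csv("stage2_reference.csv"):
        if PlanType(row["plan_type"]) is want:
            return ModelParams(
                plan_type=want,
                a=float(row["a"]),
                c=float(row["c"]),
                n=float(row["n"]),
                d=float(row["d"]),
                r2_slope_fit=float(row["r2_slope"]),
                r2_intercept_fit=float(row["r2_intercept"]),
                pd_domain=(REFERENCE_PD_LEVELS[0], REFERENCE_PD_LEVELS[-1]),
                ptv_domain=REFERENCE_PTV_DOMAIN,
            )
    raise KeyError(plan_type)


def reference_models() -> dict[PlanType, ModelParams]:
    """Both published reference surfaces keyed by plan type."""
    return {pt: reference_model(pt) for pt in PlanType}
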