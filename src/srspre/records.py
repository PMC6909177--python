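"""Plan-level domain types, cohort CSV I/O, goal evaluation, and target
geometry utilities.

A cohort is a list of :class:`PlanRecord`, one per treatment plan.  Each
record carries the geometry of the lesion (GTV, PTV, optionally the three
principal-axis diameters) and the dosimetry of the plan (prescription dose
PD, total 12 Gy volume TV12, conformity index CI, coverage COV, prescription
isodose line PIDL, optionally the full isodose-volume curve read off the
DVH).

Conventions: volumes in cc, lengths in mm, doses in Gy, COV and PIDL in
percent.  ``1 cc = 1000 mm^3`` is centralized in :data:`MM3_PER_CC`.
"""

from __future__ import annotations

import csv
import enum
import math
from dataclasses import dataclass, replace
from pathlib import Path
from typing import Iterable, Sequence

import numpy as np

from .errors import CohortParseError, ValidationError

MM3_PER_CC = 1000.0

#: Tolerance (percentage points) for the PIDL = 100*PD/PTVMD consistency check.
PIDL_CONSISTENCY_TOL = 0.1

#: Exponent of the Thomsen approximation to the ellipsoid surface area.
THOMSEN_P = 1.6075


class PlanType(str, enum.Enum):
    """Delivery technique of a single-isocenter SRS plan.

    CAT: circular (cone) arc therapy — non-coplanar arcs collimated by fixed
    circular-aperture stereotactic cones.
    DCAT: dynamic conformal arc therapy — arcs collimated by a
    micro-multileaf collimator conforming to the target's beam's-eye view.
    """

    CAT = "CAT"
    DCAT = "DCAT"


@dataclass(frozen=True)
class IsodoseVolumeCurve:
    """Enclosed volume as a function of isodose level.

    ``percents`` are isodose levels expressed as percent of the plan maximum
    dose, strictly increasing; ``volumes`` are the enclosed volumes in cc,
    non-increasing (a higher isodose surface encloses less volume).
    """

    percents: tuple[float, ...]
    volumes: tuple[float, ...]

    def __post_init__(self) -> None:
        if len(self.percents) != len(self.volumes):
            raise ValidationError("curve percents and volumes differ in length")
        if len(self.percents) < 2:
            raise ValidationError("curve needs at least two points")
        p = np.asarray(self.percents, dtype=float)
        v = np.asarray(self.volumes, dtype=float)
        if not np.all(np.diff(p) > 0):
            raise ValidationError("curve percents must be strictly increasing")
        if np.any(np.diff(v) > 0):
            raise ValidationError("curve volumes must be non-increasing")
        if np.any(v < 0):
            raise ValidationError("curve volumes must be non-negative")

    def volume_at(self, percent_of_max: float) -> float:
        """Linearly interpolated enclosed volume at a percent-of-maximum level."""
        lo, hi = self.percents[0], self.percents[-1]
        if not (lo <= percent_of_max <= hi):
            raise ValidationError(
                f"isodose percent {percent_of_max:.3f}% outside curve range "
                f"[{lo:.3f}, {hi:.3f}]%"
            )
        return float(np.interp(percent_of_max, self.percents, self.volumes))


@dataclass(frozen=True)
class GoalSet:
    """Nominal SRS planning goals: COV > min_cov, CI < max_ci, V12 < max_v12."""

    min_cov: float = 99.0
    max_ci: float = 1.5
    max_v12: float = 3.3

    def __post_init__(self) -> None:
        if min(self.min_cov, self.max_ci, self.max_v12) <= 0:
            raise ValidationError("all goal thresholds must be positive")


DEFAULT_GOALS = GoalSet()


@dataclass(frozen=True)
class GoalReport:
    """Pass/fail of each planning goal for one plan (strict inequalities)."""

    cov: float
    ci: float
    v12: float
    cov_pass: bool
    ci_pass: bool
    v12_pass: bool

    @property
    def overall_pass(self) -> bool:
        return self.cov_pass and self.ci_pass and self.v12_pass


@dataclass(frozen=True)
class PlanRecord:
    """One plan's geometry and dosimetry metrics; the atomic cohort row.

    Optional metrics are ``None`` until measured or derived.  PIDL is derived
    from ``pd`` and ``ptv_max_dose`` when absent; if both are supplied they
    must agree within :data:`PIDL_CONSISTENCY_TOL` percentage points.
    """

    plan_id: str
    plan_type: PlanType
    pd: float              # prescription dose, Gy
    ptv: float             # planning target volume, cc
    gtv: float             # gross tumor volume, cc
    tv12: float | None = None        # total volume >= 12 Gy, cc
    ci: float | None = None          # conformity index PIV/PTV
    cov: float | None = None         # coverage, % of PTV receiving >= PD
    ptv_max_dose: float | None = None  # plan maximum dose, Gy
    pidl: float | None = None        # prescription isodose line, % of max
    diameters: tuple[float, float, float] | None = None  # principal-axis, mm
    curve: IsodoseVolumeCurve | None = None

    def __post_init__(self) -> None:
        object.__setattr__(self, "plan_type", PlanType(self.plan_type))
        if self.ptv <= 0:
            raise ValidationError(f"plan {self.plan_id}: ptv must be > 0")
        if self.gtv < 0:
            raise ValidationError(f"plan {self.plan_id}: gtv must be >= 0")
        if self.gtv > self.ptv:
            raise ValidationError(f"plan {self.plan_id}: gtv <= ptv violated")
        if self.pd <= 0:
            raise ValidationError(f"plan {self.plan_id}: pd must be > 0")
        if self.tv12 is not None and self.tv12 < 0:
            raise ValidationError(f"plan {self.plan_id}: tv12 must be >= 0")
        if self.ci is not None and self.ci <= 0:
            raise ValidationError(f"plan {self.plan_id}: ci must be > 0")
        if self.cov is not None and not (0.0 <= self.cov <= 100.0):
            raise ValidationError(f"plan {self.plan_id}: cov must be in [0, 100]")
        if self.ptv_max_dose is not None:
            if self.ptv_max_dose <= 0:
                raise ValidationError(
                    f"plan {self.plan_id}: ptv_max_dose must be > 0"
                )
            derived = 100.0 * self.pd / self.ptv_max_dose
            if self.pidl is None:
                object.__setattr__(self, "pidl", derived)
            elif abs(self.pidl - derived) > PIDL_CONSISTENCY_TOL:
                raise ValidationError(
                    f"plan {self.plan_id}: pidl {self.pidl:.2f}% inconsistent "
                    f"with 100*pd/ptv_max_dose = {derived:.2f}%"
                )
        if self.pidl is not None and not (0.0 < self.pidl <= 100.0):
            raise ValidationError(f"plan {self.plan_id}: pidl must be in (0, 100]")
        if self.diameters is not None:
            d = tuple(float(x) for x in self.diameters)
            if len(d) != 3 or min(d) <= 0:
                raise ValidationError(
                    f"plan {self.plan_id}: diameters must be three positive lengths"
                )
            object.__setattr__(self, "diameters", d)

    def with_curve(self, curve: IsodoseVolumeCurve) -> "PlanRecord":
        return replace(self, curve=curve)


def derive_v12(record: PlanRecord) -> float:
    """Normal-brain 12 Gy volume, V12 = TV12 - GTV (cc).

    Valid when the 12 Gy isodose surface stays inside brain parenchyma.  A
    negative difference means the record is internally inconsistent (the
    target cannot exceed the 12 Gy volume that encloses it), so it raises
    rather than clamping.
    """
    if record.tv12 is None:
        raise ValidationError(f"plan {record.plan_id}: tv12 is absent")
    if record.tv12 < record.gtv:
        raise ValidationError(
            f"plan {record.plan_id}: inconsistent record, tv12 "
            f"({record.tv12} cc) < gtv ({record.gtv} cc)"
        )
    return record.tv12 - record.gtv


def evaluate_goals(record: PlanRecord, goals: GoalSet = DEFAULT_GOALS) -> GoalReport:
    """Evaluate the three nominal planning goals with strict inequalities."""
    for name in ("cov", "ci", "tv12"):
        if getattr(record, name) is None:
            raise ValidationError(f"plan {record.plan_id}: metric {name} is absent")
    v12 = derive_v12(record)
    return GoalReport(
        cov=record.cov,
        ci=record.ci,
        v12=v12,
        cov_pass=record.cov > goals.min_cov,
        ci_pass=record.ci < goals.max_ci,
        v12_pass=v12 < goals.max_v12,
    )


def ellipsoid_surface_area(
    diameters: Sequence[float], target_volume: float
) -> float:
    """Surface area (mm^2) of the ellipsoid with the given diameter ratios
    and the given volume.

    The three principal-axis diameters (mm) fix only the axis *ratios*: they
    are uniformly rescaled so that the ellipsoid volume pi/6*d1*d2*d3 (mm^3)
    equals ``target_volume`` (cc).  The area of the rescaled ellipsoid is
    computed with the Thomsen approximation (p = 1.6075, maximum relative
    error about 1.06%):

        S ~ 4*pi*(((a*b)^p + (a*c)^p + (b*c)^p) / 3)^(1/p)

    with semi-axes a, b, c.
    """
    d = [float(x) for x in diameters]
    if len(d) != 3 or min(d) <= 0:
        raise ValidationError("diameters must be three positive lengths")
    if target_volume <= 0:
        raise ValidationError("target_volume must be > 0")
    vol_mm3 = target_volume * MM3_PER_CC
    raw_vol = math.pi / 6.0 * d[0] * d[1] * d[2]
    scale = (vol_mm3 / raw_vol) ** (1.0 / 3.0)
    a, b, c = (x * scale / 2.0 for x in d)
    p = THOMSEN_P
    mean = ((a * b) ** p + (a * c) ** p + (b * c) ** p) / 3.0
    return 4.0 * math.pi * mean ** (1.0 / p)


# ---------------------------------------------------------------------------
# Cohort CSV I/O
# ---------------------------------------------------------------------------

#: Column order of the cohort CSV interchange format.  Missing optional
#: values are empty cells.  UTF-8, comma-separated, "." decimal.
COHORT_COLUMNS = (
    "plan_id",
    "plan_type",
    "pd_gy",
    "ptv_cc",
    "gtv_cc",
    "tv12_cc",
    "ci",
    "cov_pct",
    "ptv_max_dose_gy",
    "pidl_pct",
    "d1_mm",
    "d2_mm",
    "d3_mm",
)

_REQUIRED = {"plan_id", "plan_type", "pd_gy", "ptv_cc", "gtv_cc"}


def _parse_cell(row_num: int, column: str, text: str) -> float | None:
    text = text.strip()
    if text == "":
        if column in _REQUIRED:
            raise CohortParseError(
                f"row {row_num}, column {column!r}: required value is missing"
            )
        return None
    try:
        return float(text)
    except ValueError:
        raise CohortParseError(
            f"row {row_num}, column {column!r}: cannot parse {text!r} as a number"
        ) from None


def read_cohort(path: str | Path) -> list[PlanRecord]:
    """Read a cohort CSV (schema :data:`COHORT_COLUMNS`) into validated records.

    Row order is preserved.  Parse failures raise :class:`CohortParseError`
    naming the row and column; invariant violations raise
    :class:`ValidationError` naming the plan.
    """
    path = Path(path)
    records: list[PlanRecord] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        try:
            header = next(reader)
        except StopIteration:
            raise CohortParseError(f"{path}: empty file, header required") from None
        if tuple(h.strip() for h in header) != COHORT_COLUMNS:
            raise CohortParseError(
                f"{path}: header mismatch; expected {','.join(COHORT_COLUMNS)}"
            )
        for row_num, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != len(COHORT_COLUMNS):
                raise CohortParseError(
                    f"row {row_num}: expected {len(COHORT_COLUMNS)} cells, "
                    f"got {len(row)}"
                )
            cells = dict(zip(COHORT_COLUMNS, row))
            plan_id = cells["plan_id"].strip()
            if not plan_id:
                raise CohortParseError(f"row {row_num}, column 'plan_id': empty")
            plan_type = cells["plan_type"].strip()
            if plan_type not in PlanType.__members__:
                raise CohortParseError(
                    f"row {row_num}, column 'plan_type': {plan_type!r} is not "
                    f"one of {sorted(PlanType.__members__)}"
                )
            num = {
                col: _parse_cell(row_num, col, cells[col])
                for col in COHORT_COLUMNS[2:]
            }
            dvals = (num["d1_mm"], num["d2_mm"], num["d3_mm"])
            if any(v is not None for v in dvals) and None in dvals:
                raise CohortParseError(
                    f"row {row_num}: diameters must be all present or all absent"
                )
            records.append(
                PlanRecord(
                    plan_id=plan_id,
                    plan_type=PlanType[plan_type],
                    pd=num["pd_gy"],
                    ptv=num["ptv_cc"],
                    gtv=num["gtv_cc"],
                    tv12=num["tv12_cc"],
                    ci=num["ci"],
                    cov=num["cov_pct"],
                    ptv_max_dose=num["ptv_max_dose_gy"],
                    pidl=num["pidl_pct"],
                    diameters=None if dvals[0] is None else dvals,
                )
            )
    return records


def _fmt(value: float | None) -> str:
    return "" if value is None else format(value, ".10g")


def write_cohort(records: Iterable[PlanRecord], path: str | Path) -> None:
    """Write records to the cohort CSV format (round-trips numeric fields
    exactly for values with up to 10 significant digits)."""
    path = Path(path)
    with path.open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(COHORT_COLUMNS)
        for r in records:
            d = r.diameters or (None, None, None)
            writer.writerow(
                [
                    r.plan_id,
                    r.plan_type.value,
                    _fmt(r.pd),
                    _fmt(r.ptv),
                    _fmt(r.gtv),
                    _fmt(r.tv12),
                    _fmt(r.ci),
                    _fmt(r.cov),
                    _fmt(r.ptv_max_dose),
                    _fmt(r.pidl),
                    _fmt(d[0]),
                    _fmt(d[1]),
                    _fmt(d[2]),
                ]
            )


def read_isodose_curve(path: str | Path) -> IsodoseVolumeCurve:
    """Read a per-plan isodose-volume companion file
    (columns: isodose_pct_of_max, volume_cc)."""
    path = Path(path)
    percents: list[float] = []
    volumes: list[float] = []
    with path.open(newline="", encoding="utf-8") as fh:
        reader = csv.reader(fh)
        header = next(reader, None)
        if header is None or [h.strip() for h in header] != [
            "isodose_pct_of_max",
            "volume_cc",
        ]:
            raise CohortParseError(
                f"{path}: header must be isodose_pct_of_max,volume_cc"
            )
        for row_num, row in enumerate(reader, start=2):
            if not row or all(c.strip() == "" for c in row):
                continue
            if len(row) != 2:
                raise CohortParseError(f"row {row_num}: expected 2 cells")
            percents.append(_parse_cell(row_num, "isodose_pct_of_max", row[0]))
            volumes.append(_parse_cell(row_num, "volume_cc", row[1]))
    return IsodoseVolumeCurve(tuple(percents), tuple(volumes))


def write_isodose_curve(curve: IsodoseVolumeCurve, path: str | Path) -> None:
    with Path(path).open("w", newline="", encoding="utf-8") as fh:
        writer = csv.writer(fh)
        writer.writerow(["isodose_pct_of_max", "volume_cc"])
        for p, v in zip(curve.percents, curve.volumes):
            writer.writerow([_fmt(p), _fmt(v)])
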