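"""Plan-record validation, cohort CSV round trips, goal evaluation, and
ellipsoid surface-area geometry."""

import math

import numpy as np
import pytest
from scipy import special

from srspre import (
    CohortParseError,
    GoalSet,
    IsodoseVolumeCurve,
    PlanRecord,
    PlanType,
    ValidationError,
    derive_v12,
    ellipsoid_surface_area,
    evaluate_goals,
    read_cohort,
    read_isodose_curve,
    write_cohort,
    write_isodose_curve,
)


class TestPlanRecord:
    def test_direct_field_mapping(self):
        r = PlanRecord("p1", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8, tv12=4.4)
        assert (r.plan_id, r.plan_type, r.pd, r.ptv, r.gtv, r.tv12) == (
            "p1", PlanType.CAT, 24, 1.0, 0.8, 4.4,
        )

    def test_gtv_exceeding_ptv_rejected(self):
        with pytest.raises(ValidationError, match="gtv <= ptv"):
            PlanRecord("p1", PlanType.CAT, pd=24, ptv=1.0, gtv=1.2)

    def test_pidl_derived_from_max_dose(self):
        r = PlanRecord("p1", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8,
                       ptv_max_dose=30.0)
        assert r.pidl == pytest.approx(80.0)

    def test_inconsistent_pidl_rejected(self):
        with pytest.raises(ValidationError, match="inconsistent"):
            PlanRecord("p1", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8,
                       ptv_max_dose=30.0, pidl=75.0)

    @pytest.mark.parametrize(
        "kwargs,msg",
        [
            (dict(ptv=-1.0, gtv=0.0), "ptv"),
            (dict(ptv=1.0, gtv=-0.1), "gtv"),
            (dict(ptv=1.0, gtv=0.5, pd=0.0), "pd"),
            (dict(ptv=1.0, gtv=0.5, ci=0.0), "ci"),
            (dict(ptv=1.0, gtv=0.5, cov=101.0), "cov"),
            (dict(ptv=1.0, gtv=0.5, tv12=-0.1), "tv12"),
        ],
    )
    def test_invariant_violations(self, kwargs, msg):
        kwargs.setdefault("pd", 24.0)
        with pytest.raises(ValidationError, match=msg):
            PlanRecord("bad", PlanType.CAT, **kwargs)


class TestIsodoseVolumeCurve:
    def test_non_monotone_rejected(self):
        with pytest.raises(ValidationError):
            IsodoseVolumeCurve((40.0, 50.0, 50.0), (3.0, 2.0, 1.0))
        with pytest.raises(ValidationError):
            IsodoseVolumeCurve((40.0, 50.0, 60.0), (3.0, 3.5, 1.0))

    def test_interpolation_and_range(self, sample_curve):
        assert sample_curve.volume_at(50.0) == pytest.approx(3.5)
        assert sample_curve.volume_at(45.0) == pytest.approx(4.25)
        with pytest.raises(ValidationError, match="outside curve range"):
            sample_curve.volume_at(30.0)


class TestDeriveV12:
    def test_subtraction(self, sample_record):
        assert derive_v12(sample_record) == pytest.approx(3.6)

    def test_zero_gtv_identity(self):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.0, tv12=2.5)
        assert derive_v12(r) == pytest.approx(2.5)

    def test_inconsistent_record_raises(self):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8, tv12=0.5)
        with pytest.raises(ValidationError, match="inconsistent"):
            derive_v12(r)

    def test_absent_tv12_raises(self):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8)
        with pytest.raises(ValidationError, match="absent"):
            derive_v12(r)


class TestEvaluateGoals:
    def test_all_pass_with_default_goals(self):
        r = PlanRecord("p1", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8,
                       tv12=2.8, ci=1.3, cov=99.5)
        rep = evaluate_goals(r)
        assert rep.overall_pass and rep.v12 == pytest.approx(2.0)

    @pytest.mark.parametrize(
        "cov,ci,tv12,failing",
        [
            (99.0, 1.3, 2.8, "cov_pass"),    # boundary COV fails (strict >)
            (99.5, 1.5, 2.8, "ci_pass"),     # boundary CI fails (strict <)
            (99.5, 1.3, 4.1, "v12_pass"),    # v12 = 3.3 exactly fails (strict <)
        ],
    )
    def test_boundaries_fail_strictly(self, cov, ci, tv12, failing):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8,
                       tv12=tv12, ci=ci, cov=cov)
        rep = evaluate_goals(r)
        assert not getattr(rep, failing)
        assert not rep.overall_pass

    def test_missing_metric_named(self):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8, tv12=2.0,
                       cov=99.5)
        with pytest.raises(ValidationError, match="ci"):
            evaluate_goals(r)

    def test_custom_goals(self):
        r = PlanRecord("p", PlanType.CAT, pd=24, ptv=1.0, gtv=0.8,
                       tv12=4.2, ci=1.3, cov=99.5)
        assert not evaluate_goals(r).v12_pass
        assert evaluate_goals(r, GoalSet(max_v12=4.0)).v12_pass


def exact_ellipsoid_area(a, b, c):
    """Exact surface area via Legendre incomplete elliptic integrals,
    for semi-axes a >= b >= c > 0 with a > c."""
    phi = math.acos(c / a)
    m = (a**2 * (b**2 - c**2)) / (b**2 * (a**2 - c**2))
    F = special.ellipkinc(phi, m)
    E = special.ellipeinc(phi, m)
    s = math.sin(phi)
    return 2 * math.pi * c**2 + (2 * math.pi * a * b / s) * (
        E * s**2 + F * math.cos(phi) ** 2
    )


class TestEllipsoidSurfaceArea:
    SPHERE_VOL = math.pi / 6.0 / 1000.0 * 1000.0  # 10 mm sphere in cc -> pi/6

    def test_sphere_closed_form(self):
        area = ellipsoid_surface_area((10, 10, 10), math.pi / 6.0)
        assert area == pytest.approx(math.pi * 100.0, rel=1e-12)

    def test_scale_invariance_of_ratios(self):
        a1 = ellipsoid_surface_area((10, 10, 10), math.pi / 6.0)
        a2 = ellipsoid_surface_area((20, 20, 20), math.pi / 6.0)
        assert a1 == pytest.approx(a2, rel=1e-12)

    @pytest.mark.parametrize("diameters", [(20, 10, 10), (18, 14, 9), (25, 20, 12)])
    def test_thomsen_vs_exact_quadrature(self, diameters):
        vol_cc = math.pi / 6.0
        approx = ellipsoid_surface_area(diameters, vol_cc)
        # rescale the same way, then compare with the exact elliptic-integral area
        raw = math.pi / 6.0 * np.prod(diameters)
        scale = (vol_cc * 1000.0 / raw) ** (1 / 3)
        a, b, c = sorted((d * scale / 2 for d in diameters), reverse=True)
        exact = exact_ellipsoid_area(a, b, c)
        assert approx == pytest.approx(exact, rel=0.011)

    def test_permutation_invariance(self):
        vals = {
            ellipsoid_surface_area(perm, 1.0)
            for perm in [(20, 10, 12), (10, 12, 20), (12, 20, 10)]
        }
        assert max(vals) - min(vals) < 1e-9

    def test_sphere_minimizes_area(self):
        sphere = ellipsoid_surface_area((10, 10, 10), 1.0)
        for diam in [(20, 10, 10), (15, 12, 10), (11, 10, 10)]:
            assert ellipsoid_surface_area(diam, 1.0) > sphere

    def test_non_positive_inputs_rejected(self):
        with pytest.raises(ValidationError):
            ellipsoid_surface_area((0, 10, 10), 1.0)
        with pytest.raises(ValidationError):
            ellipsoid_surface_area((10, 10, 10), 0.0)


class TestCohortIO:
    def _cohort(self):
        return [
            PlanRecord("p1", PlanType.CAT, pd=24.0, ptv=1.234567, gtv=0.8,
                       tv12=4.4, ci=1.3, cov=99.5, ptv_max_dose=30.0,
                       diameters=(12.5, 11.0, 9.75)),
            PlanRecord("p2", PlanType.DCAT, pd=18.0, ptv=0.5, gtv=0.25),
        ]

    def test_round_trip_bit_identical(self, tmp_path):
        path = tmp_path / "cohort.csv"
        original = self._cohort()
        write_cohort(original, path)
        back = read_cohort(path)
        assert back == original  # dataclass equality covers every field

    def test_missing_optionals_stay_absent(self, tmp_path):
        path = tmp_path / "cohort.csv"
        write_cohort(self._cohort(), path)
        r = read_cohort(path)[1]
        assert r.tv12 is None and r.ci is None and r.diameters is None

    def test_parse_error_names_row_and_column(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort(self._cohort(), path)
        text = path.read_text().replace("0.5", "zero.five")
        path.write_text(text)
        with pytest.raises(CohortParseError, match=r"row 3.*ptv_cc"):
            read_cohort(path)

    def test_validation_error_names_plan(self, tmp_path):
        path = tmp_path / "bad.csv"
        write_cohort(self._cohort(), path)
        path.write_text(path.read_text().replace("p2,DCAT,18,0.5,0.25",
                                                 "p2,DCAT,18,0.5,0.75"))
        with pytest.raises(ValidationError, match="p2"):
            read_cohort(path)

    def test_header_mismatch_rejected(self, tmp_path):
        path = tmp_path / "bad.csv"
        path.write_text("a,b,c\n1,2,3\n")
        with pytest.raises(CohortParseError, match="header"):
            read_cohort(path)

    def test_curve_round_trip(self, tmp_path, sample_curve):
        path = tmp_path / "curve.csv"
        write_isodose_curve(sample_curve, path)
        assert read_isodose_curve(path) == sample_curve
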