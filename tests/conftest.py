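import pytest
from hypothesis import HealthCheck, settings

from srspre import (
    CohortSpec,
    IsodoseVolumeCurve,
    PlanRecord,
    PlanType,
    generate,
    reference_model,
    reference_stage1_fits,
)

settings.register_profile(
    "det",
    derandomize=True,
    max_examples=50,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("det")


@pytest.fixture(scope="session")
def cat_model():
    return reference_model(PlanType.CAT)


@pytest.fixture(scope="session")
def dcat_model():
    return reference_model(PlanType.DCAT)


@pytest.fixture(scope="session")
def cat_stage1():
    return reference_stage1_fits(PlanType.CAT)


@pytest.fixture(scope="session")
def dcat_stage1():
    return reference_stage1_fits(PlanType.DCAT)


@pytest.fixture
def sample_record():
    return PlanRecord(
        plan_id="p1",
        plan_type=PlanType.CAT,
        pd=24.0,
        ptv=1.0,
        gtv=0.8,
        tv12=4.4,
        ci=1.3,
        cov=99.5,
        ptv_max_dose=30.0,
    )


@pytest.fixture
def sample_curve():
    """Four-node curve used by the dose-rescaling lookup examples."""
    return IsodoseVolumeCurve(
        percents=(40.0, 50.0, 64.0, 80.0), volumes=(5.0, 3.5, 2.0, 1.0)
    )


@pytest.fixture(scope="session")
def noiseless_cohort():
    """Cohort lying exactly on the reference truth surfaces."""
    return generate(CohortSpec(n_plans=12, log10_noise_sd=0.0, seed=7))


@pytest.fixture(scope="session")
def noisy_paired_cohort():
    return generate(CohortSpec(n_plans=50, paired=True, seed=11, with_curves=False))
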