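import pytest

from npsmap.cohort import CohortSpec, generate_cohort
from npsmap.npiq import score_cohort
from npsmap.wmh import normalize_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """Default synthetic cohort: fixed sex-by-dx margins, no planted effects."""
    return generate_cohort(CohortSpec(seed=11))


@pytest.fixture(scope="session")
def scored_cohort(default_cohort):
    """Default cohort with subsyndrome scores and normalized WMH columns."""
    return normalize_cohort(score_cohort(default_cohort))


@pytest.fixture(scope="session")
def planted_cohort():
    """Cohort with a standardized effect of 0.5 from one thickness region
    onto the apathy subsyndrome."""
    spec = CohortSpec(
        seed=21,
        effect_spec=[("thick_lh_rostralmiddlefrontal", "apathy", 0.5)])
    return normalize_cohort(score_cohort(generate_cohort(spec)))


def no_dx_offset_spec(seed, effect_spec):
    """Spec whose predictors carry no diagnosis-driven covariance, so a
    predictor outside the effect list is genuinely independent of the
    outcomes."""
    return CohortSpec(
        seed=seed,
        effect_spec=effect_spec,
        thickness_params={"baseline_mean": 2.5, "sd": 0.15, "dx_offset": {}},
        wmh_params={"log_mean": {"frontal": 6.9, "parietal": 6.7,
                                 "temporal": 5.9, "occipital": 6.0,
                                 "bgt": 4.3},
                    "log_sd": 1.0, "dx_offset": {}})
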