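import pytest
from hypothesis import HealthCheck, settings

from aspos.scale import Assessment, ItemResponse, build_default_scale
from aspos.simulate import default_params, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


@pytest.fixture(scope="session")
def scale():
    return build_default_scale()


def make_assessment(scores, patient="P001", rater="R1", timepoint="day1_r1"):
    """Assessment from a {item: score-or-None} dict; unlisted items get 0."""
    sc = build_default_scale()
    responses = tuple(
        ItemResponse(item=name, score=scores.get(name, 0)) for name in sc.item_names
    )
    return Assessment(
        patient_id=patient, rater_id=rater, timepoint=timepoint, responses=responses
    )


@pytest.fixture(scope="session")
def default_cohort():
    """One study-sized cohort under the calibrated defaults."""
    return generate_cohort(default_params(seed=11))


@pytest.fixture(scope="session")
def big_cohort():
    """A large cohort for pattern-level (qualitative) checks."""
    return generate_cohort(default_params(seed=5, n_patients=2000))


@pytest.fixture(scope="session")
def zero_noise_cohort():
    """No rater or retest disagreement: all four assessments agree."""
    return generate_cohort(
        default_params(
            seed=2, n_patients=300, rater_disagreement=0.0, retest_disagreement=0.0
        )
    )
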