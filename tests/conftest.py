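import pytest

from appraise.corpus import default_catalogue, default_registry
from appraise.simulate import DrugTruth, SimulationConfig, generate_corpus, generate_patients


@pytest.fixture(scope="session")
def catalogue():
    return default_catalogue()


@pytest.fixture(scope="session")
def registry():
    return default_registry()


@pytest.fixture(scope="session")
def small_config():
    """Three drugs, two trials each: the 6-trial fixture corpus."""
    return SimulationConfig(
        drugs={
            "methylphenidate": DrugTruth(
                n_trials=2, n_per_arm=30, smd={"adhd_symptoms": -0.6},
                dose_options=[20.0, 40.0], eligibility="pediatric",
            ),
            "atomoxetine": DrugTruth(n_trials=2, n_per_arm=30, eligibility="broad"),
            "guanfacine": DrugTruth(
                n_trials=2, n_per_arm=30, eligibility={"age_min": 6, "age_max": 17,
                "excluded_comorbidities": ["epilepsy"]},
            ),
        },
        n_patients=32,
    )


@pytest.fixture(scope="session")
def fixture_corpus(small_config):
    return generate_corpus(small_config, seed=11)


@pytest.fixture(scope="session")
def fixture_cohort(small_config):
    return generate_patients(small_config, seed=11)
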