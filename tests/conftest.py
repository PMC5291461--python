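import pytest

from senemeth.pipeline import analyze, score_against_truth
from senemeth.synthetic_data import SimConfig, simulate_study


@pytest.fixture(scope="session")
def default_cfg():
    return SimConfig(seed=0)


@pytest.fixture(scope="session")
def study(default_cfg):
    """One synthetic study shared by the whole session (seed 0)."""
    return simulate_study(default_cfg)


@pytest.fixture(scope="session")
def result(study):
    return analyze(study)


@pytest.fixture(scope="session")
def recovery(result, study):
    return score_against_truth(result, study)


@pytest.fixture(scope="session")
def noise_free_study():
    cfg = SimConfig(seed=0, beta_noise_sd=0.0, expr_noise_sd=0.0,
                    frac_detection_fail=0.0)
    return simulate_study(cfg)
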