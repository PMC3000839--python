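import numpy as np
import pytest
from hypothesis import settings

from nfkin.pipeline import analyze_cohort, simulate_cohort
from nfkin.motion_sim import get_preset
from nfkin.track_core import AnalysisConfig

settings.register_profile("default", derandomize=True, max_examples=50,
                          deadline=None)
settings.load_profile("default")


@pytest.fixture(scope="session")
def config():
    return AnalysisConfig()


@pytest.fixture(scope="session")
def control_cohort_200():
    """200 control-condition movies with full analyses (shared across tests)."""
    sims = simulate_cohort(get_preset("control"), 200, base_seed=101)
    return sims, analyze_cohort(sims)


@pytest.fixture(scope="session")
def n256s_cohort_200():
    sims = simulate_cohort(get_preset("n256s"), 200, base_seed=202)
    return sims, analyze_cohort(sims)


def mean_sem(values):
    values = np.asarray(values, float)
    return float(values.mean()), float(values.std(ddof=1) / np.sqrt(values.size))
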