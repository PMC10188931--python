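import numpy as np
import pytest

from ebcbe.datasets import load_crossover_pk_metrics, load_ngi_runs
from ebcbe.profiles_pk import CollectionWindow, ConcentrationProfile

# the six standard EBC collection windows (minutes after the second actuation)
STANDARD_WINDOWS = ((0, 4), (14, 18), (28, 32), (42, 46), (56, 60), (70, 74))


@pytest.fixture(scope="session")
def crossover_datasets():
    """Bundled per-subject Cmax/AUC crossover datasets (reference = MDI-1)."""
    return {ds.metric_name: ds for ds in load_crossover_pk_metrics()}


@pytest.fixture(scope="session")
def ngi_runs():
    """Bundled impactor runs keyed by formulation."""
    return {run.formulation_id: run for run in load_ngi_runs()}


@pytest.fixture()
def rng():
    return np.random.default_rng(20231146)


def make_profile(concentrations, windows=STANDARD_WINDOWS, subject="S1", treatment="ref"):
    return ConcentrationProfile(
        subject,
        treatment,
        [
            CollectionWindow(a, b, c)
            for (a, b), c in zip(windows, concentrations)
        ],
    )
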