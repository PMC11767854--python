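import numpy as np
import pytest
from hypothesis import HealthCheck, settings

from evftir.spectra import SampleMeta, SpectraSet, WavenumberAxis

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=25,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def make_set(values, rows, sample_type="cells", condition=None):
    """SpectraSet from a grid and a list of rows, with generated metadata."""
    rows = np.atleast_2d(np.asarray(rows, dtype=float))
    conds = condition or ["control"] * rows.shape[0]
    meta = tuple(
        SampleMeta(f"s{i}", sample_type, conds[i], 1 + i, 1)
        for i in range(rows.shape[0])
    )
    return SpectraSet(WavenumberAxis(np.asarray(values, float)), rows, meta)


@pytest.fixture(scope="session")
def fingerprint_grid():
    """Descending 4000-600 cm^-1 grid at 4 cm^-1 spacing (851 points)."""
    return np.arange(4000.0, 599.0, -4.0)


@pytest.fixture(scope="session")
def ev_dataset():
    from evftir.simulate import default_scenario, simulate_dataset

    return simulate_dataset(default_scenario("EVs", seed=1))


@pytest.fixture(scope="session")
def ev_run(ev_dataset):
    from evftir.workflow import RunConfig, run_workflow

    return run_workflow(ev_dataset, RunConfig(sample_type="EVs"))
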