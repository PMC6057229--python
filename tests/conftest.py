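import numpy as np
import pytest
from hypothesis import HealthCheck, settings

import topostat as ts

settings.register_profile(
    "ci", derandomize=True, deadline=None, suppress_health_check=[HealthCheck.too_slow]
)
settings.load_profile("ci")


def make_dataset(
    n_subjects=2,
    conditions=("A", "B"),
    n_trials=10,
    n_sensors=4,
    n_times=801,
    sampling_rate=1000.0,
    t0=-200.0,
    seed=0,
):
    """Small random-but-reproducible EpochsDataset for structural tests."""
    rng = np.random.default_rng(seed)
    subjects = [f"S{i + 1:02d}" for i in range(n_subjects)]
    data = {
        (s, c): rng.standard_normal((n_trials, n_sensors, n_times))
        for s in subjects
        for c in conditions
    }
    return ts.EpochsDataset(
        subjects=subjects,
        conditions=list(conditions),
        data=data,
        sensor_names=[f"E{i + 1}" for i in range(n_sensors)],
        times=t0 + np.arange(n_times) * 1000.0 / sampling_rate,
        sampling_rate=sampling_rate,
    )


@pytest.fixture
def small_dataset():
    return make_dataset()


@pytest.fixture
def study_view():
    """Extracted 0-200 ms view of a 6-subject null study (fast)."""
    spec = ts.demo_spec(
        "null",
        n_subjects=6,
        n_sensors=8,
        n_trials=(10, 10),
        sampling_rate=100.0,
        epoch_ms=(0.0, 200.0),
        seed=7,
    )
    dataset = ts.simulate(spec)
    target = ts.AnalysisTarget(("A", "B"), (("A", "B"),), (0.0, 200.0), 100.0)
    return ts.extract(dataset, target)
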