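import numpy as np
import pandas as pd
import pytest
from hypothesis import HealthCheck, settings

from zcomp.io_formats import ExpressionDataset
from zcomp.synthetic_data import SimulationConfig, simulate_dataset

settings.register_profile(
    "default",
    derandomize=True,
    max_examples=50,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("default")


def make_dataset(intensities, calls=None, sexes=None, probesets=None, samples=None):
    """Small ExpressionDataset from a plain array; calls default to all-Present."""
    arr = np.asarray(intensities, dtype=float)
    n_p, n_s = arr.shape
    probesets = probesets or [f"PS{i}" for i in range(n_p)]
    samples = samples or [f"S{i}" for i in range(n_s)]
    if calls is None:
        calls = np.full(arr.shape, "P", dtype=object)
    if sexes is None:
        sexes = ["male"] * (n_s // 2) + ["female"] * (n_s - n_s // 2)
    return ExpressionDataset(
        intensities=pd.DataFrame(arr, index=pd.Index(probesets, name="probeset_id"),
                                 columns=samples),
        detection=pd.DataFrame(np.asarray(calls, dtype=object),
                               index=pd.Index(probesets, name="probeset_id"),
                               columns=samples),
        sex=pd.Series(sexes, index=samples, name="sex"),
    )


@pytest.fixture
def small_simulation():
    """Default-shaped but small simulated experiment with ground truth."""
    cfg = SimulationConfig(seed=7, n_autosomal=400, n_z=300, n_w=12)
    return simulate_dataset(cfg)
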