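import numpy as np
import pytest

from mwaskit.core_io import FeatureTable, Injection, Mode, MzFeature
from mwaskit.pipeline import run_pipeline
from mwaskit.synthetic import SimConfig, simulate


def build_table(values, mz=None, rt=None, mode=Mode.HILIC_POS, batch_size=40):
    """Build a FeatureTable from a (features, samples, 3) array (NaN = absent)."""
    values = np.asarray(values, dtype=float)
    if values.ndim == 2:  # (features, injections)
        if values.shape[1] % 3:
            raise ValueError("injection count must be a multiple of 3")
        values = values.reshape(values.shape[0], -1, 3)
    n_feat, n_samp, _ = values.shape
    if mz is None:
        mz = np.linspace(100.0, 900.0, n_feat)
    if rt is None:
        rt = np.linspace(20.0, 600.0, n_feat)
    features = [
        MzFeature(f"{mode.value}_{i:05d}", float(mz[i]), float(rt[i]), mode)
        for i in range(n_feat)
    ]
    injections = [
        Injection(f"S{s:03d}", r, f"B{s // batch_size:02d}")
        for s in range(n_samp)
        for r in (1, 2, 3)
    ]
    return FeatureTable(
        features=features, injections=injections, intensities=values.reshape(n_feat, n_samp * 3)
    )


@pytest.fixture
def make_table():
    return build_table


SMOKE_CFG = dict(n_samples=240, n_features=400, n_planted_features=30)


@pytest.fixture(scope="session")
def smoke_sim():
    """Small synthetic study shared across tests (planted effects + pathway)."""
    return simulate(SimConfig(seed=7, **SMOKE_CFG))


@pytest.fixture(scope="session")
def smoke_pipeline(smoke_sim):
    return run_pipeline(smoke_sim)
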