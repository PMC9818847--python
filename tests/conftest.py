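import numpy as np
import pandas as pd
import pytest

from eggfresh import SimConfig, SpectralDataset


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def small_dataset(rng):
    """20 samples x 30 wavelengths with a simple linear y."""
    wl = np.linspace(550.0, 985.0, 30)
    X = rng.normal(50.0, 5.0, (20, 30))
    y = X[:, 10] * 0.5 + rng.normal(0, 0.5, 20) + 40.0
    return SpectralDataset(wavelengths=wl, X=X, y=y)


@pytest.fixture
def replicate_dataset(rng):
    """Two eggs, three replicate scans each, constant y within an egg."""
    wl = np.arange(5, dtype=float)
    base = rng.normal(30.0, 3.0, (2, 5))
    rows, ids, meta, y = [], [], [], []
    for e in range(2):
        for r in range(3):
            rows.append(base[e] + rng.normal(0, 0.1, 5))
            ids.append(f"e{e}_r{r}")
            meta.append({"egg": f"e{e}", "day": 1, "replicate": r})
            y.append(70.0 + 5 * e)
    return SpectralDataset(
        wavelengths=wl,
        X=np.vstack(rows),
        y=np.array(y),
        sample_ids=ids,
        meta=pd.DataFrame(meta, index=ids),
    )


@pytest.fixture
def tiny_sim_config():
    """A fast SimConfig: few eggs, short wavelength grid."""
    return SimConfig(n_eggs=21, n_wavelengths=201, seed=7)
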