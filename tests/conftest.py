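import numpy as np
import pandas as pd
import pytest

import plantsig as ps
from plantsig.features import FEATURE_NAMES


@pytest.fixture(scope="session")
def tiny_blocks():
    """Small balanced synthetic dataset (12 blocks per class)."""
    cfg = ps.SynthConfig(class_counts=(12, 12, 12), block_len=1024, seed=42)
    return ps.generate_dataset(cfg)


@pytest.fixture(scope="session")
def random_feature_table():
    """Well-behaved feature table with no outliers: iid uniform columns."""
    rng = np.random.default_rng(7)
    n = 200
    table = pd.DataFrame({name: rng.uniform(1, 2, n) for name in FEATURE_NAMES})
    table.insert(0, "block_id", np.arange(n))
    table.insert(1, "stimulus", rng.choice(ps.STIMULI, n))
    table.insert(2, "species", rng.choice(ps.SPECIES, n))
    return table


@pytest.fixture(scope="session")
def pipeline_table():
    """Cleaned + normalized feature table from the synthetic generator.

    Scaled-down class counts keep the full-pipeline tests desk-sized
    while preserving the heavy O3-majority imbalance.
    """
    cfg = ps.SynthConfig(class_counts=(40, 96, 400), seed=11)
    blocks = ps.generate_dataset(cfg)
    fcfg = ps.FilterConfig()
    filtered = [
        ps.SignalBlock(
            samples=ps.highpass_filter(b.samples, b.fs, fcfg),
            fs=b.fs, stimulus=b.stimulus, species=b.species, block_id=b.block_id,
        )
        for b in blocks
    ]
    table = ps.extract_table(filtered)
    cleaned, _ = ps.remove_outliers(table)
    return ps.minmax_normalize(cleaned)


@pytest.fixture(scope="session")
def blob_data():
    """Trivially separable 3-class Gaussian blobs (sigma=0.1, centers 10 apart)."""
    rng = np.random.default_rng(0)
    centers = np.array([[0.0, 0.0], [10.0, 0.0], [0.0, 10.0]])
    x, y = [], []
    for k, c in enumerate(centers):
        x.append(c + 0.1 * rng.standard_normal((60, 2)))
        y.append(np.full(60, k))
    return np.vstack(x), np.concatenate(y)
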