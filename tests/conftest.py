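import numpy as np
import pytest


@pytest.fixture
def rng():
    return np.random.default_rng(0)


@pytest.fixture(scope="session")
def tiny_overlap():
    """A small, fast two-node overlap dataset shared across unit tests."""
    from overlapdr import OverlapSimConfig, simulate_overlap

    cfg = OverlapSimConfig(
        n_voxels=2000, n_subjects=8, n_timepoints=120, node_size=60,
        overlap_fraction=0.25, seed=42,
    )
    data, truth = simulate_overlap(cfg)
    return cfg, data, truth


@pytest.fixture(scope="session")
def separable_dataset():
    """Noiseless data from orthogonal timecourses x disjoint maps.

    The exactly identifiable case: spatial ICA followed by dual regression
    must recover maps and timecourses essentially perfectly.
    """
    rng = np.random.default_rng(7)
    n_t, n_v, k = 200, 2000, 3
    maps = np.zeros((k, n_v))
    for m in range(k):  # sparse disjoint supports, as for real component maps
        maps[m, m * 400:m * 400 + 100] = rng.uniform(2, 8, 100)
    # several "subjects" with different orthogonal timecourses, same maps
    data = []
    all_ts = []
    for _ in range(4):
        t, _ = np.linalg.qr(rng.standard_normal((n_t, k)))
        all_ts.append(t)
        data.append(t @ maps)
    return data, all_ts, maps
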