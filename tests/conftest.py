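import warnings

import numpy as np
import pytest

from admixscan.simulate import SimConfig, simulate_sweep_panel


@pytest.fixture(autouse=True)
def _quiet_sparse_bin_warnings():
    # small simulated panels legitimately leave sparse DAF bins unstandardized
    with warnings.catch_warnings():
        warnings.filterwarnings("ignore", message=".*DAF bin.*")
        yield


@pytest.fixture(scope="session")
def neutral_panel():
    """One mid-sized neutral Wright-Fisher panel shared across tests."""
    cfg = SimConfig(
        Ne=200,
        n_sites=200,
        sample_haplotypes=200,
        s_focal=0.0,
        max_generations=60,
        seed=42,
    )
    return simulate_sweep_panel(cfg)


@pytest.fixture(scope="session")
def small_panel():
    """A small, quick neutral panel for format round-trips and scans."""
    cfg = SimConfig(
        Ne=50,
        n_sites=60,
        region_length_bp=500_000,
        sample_haplotypes=60,
        s_focal=0.0,
        max_generations=30,
        seed=7,
    )
    return simulate_sweep_panel(cfg)


def brute_force_ehh(hap: np.ndarray, carriers: np.ndarray, core: int, marker: int) -> float:
    """Oracle: EHH by explicit pairwise haplotype comparison over [core, marker]."""
    lo, hi = (marker, core) if marker < core else (core, marker)
    seg = hap[np.asarray(carriers)][:, lo : hi + 1]
    n = seg.shape[0]
    same = 0
    for i in range(n):
        for j in range(i + 1, n):
            if np.array_equal(seg[i], seg[j]):
                same += 1
    return same / (n * (n - 1) / 2)
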