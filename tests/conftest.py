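import numpy as np
import pandas as pd
import pytest

from tumevo import SamplePlan, SimParams, simulate_surviving
from tumevo.sampling import SampleTable, sample_population


def standard_plan(seed=0, n_samples=280, whole_tumour_freq_min=None):
    return SamplePlan(layout="honeycomb", n_samples=n_samples,
                      detection_freq_min=0.05,
                      whole_tumour_freq_min=whole_tumour_freq_min, seed=seed)


def make_table(sample_positions, freq_matrix, cell_counts=None, mut_ids=None):
    """Small hand-built sample table: freq_matrix is (n_mut, n_samples)."""
    pos = np.atleast_2d(np.asarray(sample_positions, dtype=float))
    F = np.atleast_2d(np.asarray(freq_matrix, dtype=float))
    n_s = pos.shape[0]
    cc = np.full(n_s, 100) if cell_counts is None else np.asarray(cell_counts)
    mids = np.arange(1, F.shape[0] + 1) if mut_ids is None else np.asarray(mut_ids)
    samples = pd.DataFrame({
        "sample_id": np.arange(n_s),
        "x": pos[:, 0],
        "y": pos[:, 1] if pos.shape[1] > 1 else 0.0,
        "z": pos[:, 2] if pos.shape[1] > 2 else np.nan,
        "cell_count": cc,
    })
    rows = []
    for i, m in enumerate(mids):
        for s in range(n_s):
            if F[i, s] > 0:
                rows.append((s, int(m), F[i, s], True, np.nan, np.nan))
    calls = pd.DataFrame(rows, columns=SampleTable.CALL_COLS)
    return SampleTable(samples, calls, dim=min(pos.shape[1], 3) if pos.shape[1] > 2 else 2)


@pytest.fixture(scope="session")
def small_volume_pop():
    """A modest volume-growth tumour shared by several read-only tests."""
    p = SimParams(dimension=2, b0=1.0, d=0.4, mu=0.3, n_max=1500, seed=11)
    return simulate_surviving(p)


@pytest.fixture(scope="session")
def small_volume_table(small_volume_pop):
    return sample_population(small_volume_pop, standard_plan(seed=3, n_samples=120))
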