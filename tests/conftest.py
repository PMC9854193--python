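import numpy as np
import pytest

from embryotrace import synth


@pytest.fixture
def diffusive_params():
    return synth.TrajectoryParams("diffusive", D_micro=0.25, n_frames=100,
                                  dt=0.01, seed=42)


@pytest.fixture
def small_trace_cohort():
    """Ten cells, noiseless amplitudes apart from the generator's defaults."""
    return synth.gen_trace_pairs(synth.TracePairParams(n_cells=10, seed=7))


def brute_force_msd(positions: np.ndarray, max_lag: int) -> np.ndarray:
    """O(n^2) double-loop MSD oracle."""
    n = len(positions)
    out = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        acc, count = 0.0, 0
        for i in range(n - lag):
            d = positions[i + lag] - positions[i]
            acc += float(d @ d)
            count += 1
        out[lag - 1] = acc / count
    return out
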