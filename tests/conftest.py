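import numpy as np
import pytest

from condensage import MotionModel, SimulationConfig, simulate_trajectories


@pytest.fixture(scope="session")
def brownian_ensemble_large():
    """10^4 Brownian tracks (D = 1 um^2/s, dt = 0.02 s), shared across tests."""
    cfg = SimulationConfig(seed=42, n_particles=10_000, n_frames=60, dt=0.02)
    return simulate_trajectories(cfg, MotionModel(kind="newtonian", D=1.0))


def brute_force_msd(positions: np.ndarray, max_lag: int) -> tuple[np.ndarray, np.ndarray]:
    """O(N^2) all-pairs time+ensemble MSD over a dense (n, m, 2) array."""
    n, m, _ = positions.shape
    sums = np.zeros(max_lag)
    counts = np.zeros(max_lag)
    for lag in range(1, max_lag + 1):
        for i in range(m - lag):
            d = positions[:, i + lag] - positions[:, i]
            sums[lag - 1] += np.sum(d**2)
            counts[lag - 1] += n
    return sums / counts, counts
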