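import numpy as np
import pytest

import intentfuse as itf


@pytest.fixture(scope="session")
def small_design() -> itf.TrialDesign:
    return itf.TrialDesign(
        n_participants=3, n_activities=3, n_trials_per_activity=2,
        category_map=(0, 1, 2),
    )


@pytest.fixture(scope="session")
def small_sensors() -> list[itf.SensorSpec]:
    return itf.default_network(n_semg=2, n_imu=2, informativeness=(1.0, 0.6))


@pytest.fixture(scope="session")
def small_dataset(small_design, small_sensors) -> itf.Dataset:
    trials = itf.generate_dataset(small_design, small_sensors, seed=7)
    return itf.Dataset(trials, small_sensors, small_design, seed=7)


@pytest.fixture(scope="session")
def small_harness(small_dataset) -> itf.Harness:
    return itf.Harness(small_dataset, seed=7)


def brute_force_nn(queries: np.ndarray, train: np.ndarray, labels: np.ndarray,
                   exponent: float = 0.5) -> np.ndarray:
    """Exhaustive nearest-neighbour scan with explicit per-pair distances."""
    out = []
    for q in np.atleast_2d(queries):
        best, best_d = None, np.inf
        for j in range(train.shape[0]):
            d = float(np.sum(np.abs(q - train[j]) ** exponent))
            if d < best_d:
                best, best_d = labels[j], d
        out.append(best)
    return np.array(out)
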