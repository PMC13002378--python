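import numpy as np
import pytest

from meanet.spike_io import SpikeTrainSet, Unit


@pytest.fixture
def tiny_set() -> SpikeTrainSet:
    """Three hand-built units over a 10-second span."""
    return SpikeTrainSet(
        slice_id="tiny", condition="baseline",
        units=[
            Unit("a", "SUA", np.arange(0.0, 10000.0, 100.0), 0.7),
            Unit("b", "SUA", np.arange(50.0, 10000.0, 200.0), 0.2),
            Unit("c", "MUA", np.arange(10.0, 10000.0, 50.0)),
        ],
        duration_ms=10000.0)


@pytest.fixture(scope="session")
def sim_pair():
    """One simulated paired-condition slice under the study scenario."""
    from meanet.synthetic import simulate_slice
    return simulate_slice(1234, slice_id="fix")


def triangle_with_pendant() -> np.ndarray:
    """Edges a-b, b-c, a-c, c-d."""
    A = np.zeros((4, 4), int)
    for i, j in [(0, 1), (1, 2), (0, 2), (2, 3)]:
        A[i, j] = A[j, i] = 1
    return A


def star(m: int) -> np.ndarray:
    A = np.zeros((m + 1, m + 1), int)
    A[0, 1:] = A[1:, 0] = 1
    return A


def complete(n: int) -> np.ndarray:
    return (np.ones((n, n)) - np.eye(n)).astype(int)


def path(n: int) -> np.ndarray:
    A = np.zeros((n, n), int)
    for i in range(n - 1):
        A[i, i + 1] = A[i + 1, i] = 1
    return A


def cycle(n: int) -> np.ndarray:
    A = path(n)
    A[0, n - 1] = A[n - 1, 0] = 1
    return A
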