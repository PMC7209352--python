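import numpy as np
import pytest

from gridmix import HexLattice
from gridmix.experiments import benchmark_1d, capacity_scaling, resolution_sweep

# ---------------------------------------------------------------------------
# Heavy Monte-Carlo runs shared between the acceptance tests and the
# statistical unit tests.  Session-scoped and lazy: they are only computed
# when a test that needs them runs.
# ---------------------------------------------------------------------------


@pytest.fixture(scope="session")
def lattice():
    return HexLattice()


@pytest.fixture(scope="session")
def bench1d_full():
    """1D capacity distributions at the benchmark scale:
    Δ = 0.2, M = 1..4, 200 projection draws per M."""
    return benchmark_1d([1, 2, 3, 4], delta=0.2, trials=200, base_seed=0)


@pytest.fixture(scope="session")
def scaling_030():
    """Capacity over M = 1..4, N = 1..3 at Δ = 0.3, 30 draws per M
    (each draw reused across N through sub-matrix restriction)."""
    return capacity_scaling([1, 2, 3, 4], [1, 2, 3], delta=0.3, trials=30, base_seed=0)


@pytest.fixture(scope="session")
def sweep_delta():
    """Resolution sweep at M = 3, N = 2, Δ ∈ {0.4, 0.3, 0.2, 0.15}, 30 draws,
    with the same draw reused across Δ."""
    return resolution_sweep(3, 2, [0.4, 0.3, 0.2, 0.15], trials=30, base_seed=0)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
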