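import numpy as np
import pytest

from hhcable import CableGrid, MembraneParams


@pytest.fixture(scope="session")
def params():
    """Calibrated default membrane constants."""
    return MembraneParams()


@pytest.fixture(scope="session")
def grid():
    """Calibrated default cable geometry."""
    return CableGrid()


@pytest.fixture(scope="session")
def small_grid():
    """Short, quick cable for structural (non-calibrated) tests."""
    return CableGrid(L=1.5, nx=151, dt=0.01, t_end=30.0)


@pytest.fixture(scope="session")
def critical_mu_cache(grid, params):
    """Session cache of cable critical drives per signal width."""
    from hhcable import find_critical_mu

    cache: dict[float, float] = {}

    def get(x_sig: float) -> float:
        if x_sig not in cache:
            cache[x_sig] = find_critical_mu(grid, params, x_sig)
        return cache[x_sig]

    return get


def spatial_count(V, dx, threshold=45.0):
    from hhcable import count_spikes_spatial

    return count_spikes_spatial(V, dx, threshold=threshold).n_spikes
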