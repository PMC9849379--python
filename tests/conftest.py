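import numpy as np
import pytest

from cvpac import core
from cvpac.simulate import (
    CouplingComponent,
    CouplingProfile,
    generate_coupled_signal,
)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def grid():
    return core.FrequencyGrid.default()


@pytest.fixture(scope="session")
def coupled_window(grid):
    """A strongly coupled window: d=0.8 at (~2.8 Hz, ~105 Hz), psi=pi/2."""
    f_low = float(grid.low_centers[4])
    f_high = float(grid.high_centers[7])
    profile = CouplingProfile(
        components=(CouplingComponent(f_low, f_high, 0.8, np.pi / 2),),
        noise_sd=0.3,
    )
    win = generate_coupled_signal(profile, seed=42)
    return win, (7, 4), np.pi / 2


@pytest.fixture(scope="session")
def coupled_image(coupled_window, grid):
    win, cell, psi = coupled_window
    return core.compute_cvpac(win, grid), cell, psi


def random_simplex(rng, n_draws, n_bins=18):
    """Random points on the probability simplex (flat Dirichlet)."""
    x = rng.dirichlet(np.ones(n_bins), size=n_draws)
    return x


def random_images(rng, n, grid, scale=0.3):
    """Directly constructed comodulograms for container-level tests."""
    out = []
    for _ in range(n):
        z = scale * (rng.standard_normal(grid.shape) + 1j * rng.standard_normal(grid.shape))
        mod = np.abs(z)
        z[mod > 1] /= mod[mod > 1]
        out.append(core.CVPACImage(z, grid))
    return out
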