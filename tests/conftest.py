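import numpy as np
import pytest

from colonyquant import GridSpec, SynthSpec, Gradient, uniform_colonies, generate_plate


@pytest.fixture
def small_grid() -> GridSpec:
    """4x6 grid of 40-px tiles with a one-tile margin around the array."""
    return GridSpec(n_rows=4, n_cols=6, x_tl=40, y_tl=40, x_br=240, y_br=160,
                    x_dim=40, y_dim=40)


@pytest.fixture
def faint_gradient_plate(small_grid):
    """Faint disc colonies under a 0.8-1.2 linear lighting gradient."""
    spec = SynthSpec(
        grid=small_grid,
        colonies=uniform_colonies(small_grid, density=0.15, radius=9),
        gradient=Gradient(kind="linear", min_factor=0.8, max_factor=1.2),
        noise_sigma=2.0,
        seed=5,
    )
    img, truth = generate_plate(spec)
    return spec, img, truth


@pytest.fixture
def colony_free_gradient_plate(small_grid):
    """Colony-free plate with a 0.8-1.2 gradient and realistic noise."""
    spec = SynthSpec(
        grid=small_grid,
        colonies=uniform_colonies(small_grid, present=False),
        gradient=Gradient(kind="linear", min_factor=0.8, max_factor=1.2),
        noise_sigma=2.0,
        seed=7,
    )
    img, truth = generate_plate(spec)
    return spec, img, truth


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
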