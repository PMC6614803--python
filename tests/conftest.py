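import numpy as np
import pytest

from pixulchip.gel.image import GelImage
from pixulchip.gel.ladder import LadderSpec
from pixulchip.sim.distributions import FragmentDistribution
from pixulchip.sim.simulate import GelSimConfig, simulate_gel


@pytest.fixture
def ladder() -> LadderSpec:
    return LadderSpec(sizes_bp=(1500, 1000, 700, 500, 400, 300, 200, 100), name="100bp+")


@pytest.fixture
def small_sim_config():
    """5-lane gel (ladder + 4 samples) sized for fast tests."""

    def _make(seed: int = 0, noise_sigma: float = 0.02, **overrides) -> GelSimConfig:
        params = dict(
            seed=seed,
            noise_sigma=noise_sigma,
            lane_centers=tuple(40 + 60 * i for i in range(5)),
            image_shape=(480, 360),
        )
        params.update(overrides)
        return GelSimConfig(**params)

    return _make


@pytest.fixture
def simulated_gel(ladder, small_sim_config):
    """One seeded 5-lane gel with its truth (seed 0, moderate noise)."""
    cfg = small_sim_config(seed=0)
    rng = np.random.default_rng(0)
    dists = [
        FragmentDistribution.single(m, s)
        for m, s in zip(rng.uniform(250, 400, 4), rng.uniform(0.12, 0.18, 4))
    ]
    gel, truth = simulate_gel(dists, ladder, cfg)
    return gel, truth, cfg, dists


def single_band_image(
    n_rows: int = 200,
    n_cols: int = 100,
    center_col: int = 50,
    half_width: int = 10,
    band_row: float = 80.0,
    band_sigma: float = 3.0,
    amplitude: float = 0.5,
    background: float = 0.0,
) -> GelImage:
    """One lane with a single Gaussian band; used as a hand-built oracle."""
    rows = np.arange(n_rows, dtype=float)
    band = amplitude * np.exp(-0.5 * ((rows - band_row) / band_sigma) ** 2)
    pixels = np.full((n_rows, n_cols), background)
    pixels[:, center_col - half_width : center_col + half_width + 1] += band[:, None]
    return GelImage(pixels=pixels)
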