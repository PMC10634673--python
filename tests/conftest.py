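import numpy as np
import pytest

from cryopicker import SimConfig, simulate_micrograph


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def noisy_disk():
    """A bright soft disk on a flat background with seeded Gaussian noise,
    plus the foreground/background masks used for SNR readouts."""
    rng = np.random.default_rng(7)
    h = w = 96
    yy, xx = np.mgrid[0:h, 0:w]
    r = np.sqrt((xx - 48) ** 2 + (yy - 48) ** 2)
    clean = 100.0 + 60.0 / (1.0 + np.exp(r - 14.0))
    noisy = clean + rng.normal(0, 30.0, size=(h, w))
    fg = r <= 10
    bg = r >= 22
    return noisy, clean, fg, bg


@pytest.fixture
def sim_cfg():
    """Small simulation profile for fast structural tests."""
    return SimConfig(
        image_size=(96, 96),
        n_particles_range=(5, 5),
        particle_radius_range=(6.0, 9.0),
        noise_sd=10.0,
        n_distractors_range=(0, 1),
        seed=11,
    )


@pytest.fixture
def sim_sample(sim_cfg):
    return simulate_micrograph(sim_cfg, 0)
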