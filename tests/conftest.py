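import math

import numpy as np
import pytest

from octavd import PhantomConfig, ScirdBank, generate_vessel_network


@pytest.fixture(scope="session")
def small_bank() -> ScirdBank:
    """A fast 24-kernel bank for backend and invariance tests."""
    return ScirdBank(sigma1_values=(2.0,), sigma2_values=(1.0, 1.5),
                     k_values=(-0.05, 0.0, 0.05),
                     theta_values=tuple(i * math.pi / 4 for i in range(4)),
                     kernel_halfsize=6)


@pytest.fixture(scope="session")
def clean_phantom():
    """Noise-free 128-px phantom with its truth mask (6 vessels)."""
    cfg = PhantomConfig(grid_size=128, n_vessels=6, background_noise_sd=0.0,
                        seed=7)
    image, mask = generate_vessel_network(cfg)
    return image, mask


@pytest.fixture()
def noise_image():
    rng = np.random.default_rng(11)
    return np.abs(rng.normal(40.0, 10.0, size=(96, 96)))


def fast_pipeline_config():
    """Config overrides sized for quick end-to-end tests."""
    from octavd.config import load_config
    return load_config(overrides={
        "simulate.grid_size": 64,
        "simulate.n_vessels": 4,
        "simulate.n_image_subjects": 2,
        "simulate.n_subjects": 30,
        "scird.sigma1": [2.0],
        "scird.sigma2": [1.0, 1.5],
        "scird.k": [-0.05, 0.0, 0.05],
        "scird.n_theta": 4,
        "scird.halfsize": 6,
    })
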