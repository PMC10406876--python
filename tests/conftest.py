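import numpy as np
import pytest

from iccs_coloc.io_masks import NuclearMask
from iccs_coloc.synth import NO_NOISE, FociSimParams, NoiseModel, simulate_two_channel


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture
def full_mask_16():
    return NuclearMask(mask=np.ones((16, 16), dtype=bool))


def make_foci_image(f_true, n_foci=50, seed=0, noise="poisson", **kw):
    """Shared helper: simulated two-channel nucleus plus its true mask."""
    noise_model = NoiseModel(poisson=True) if noise == "poisson" else NO_NOISE
    params = FociSimParams(
        f_true=f_true,
        n_foci_a=n_foci,
        n_foci_b=n_foci,
        seed=seed,
        noise=noise_model,
        **kw,
    )
    image, truth = simulate_two_channel(params)
    return image, truth, NuclearMask(mask=truth.nucleus_mask_true)
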