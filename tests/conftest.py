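"""Shared fixtures: small, fast synthetic configurations."""

import numpy as np
import pytest

from nbquant import simgen


@pytest.fixture
def small_field_params():
    """A quick 256x256 field with a handful of nuclei."""
    return simgen.SimFieldParams(field_size_px=(256, 256), n_nuclei=3, seed=42)


@pytest.fixture
def noiseless_field_params():
    return simgen.SimFieldParams(
        field_size_px=(256, 256),
        n_nuclei=3,
        gaussian_read_noise_sd=0.0,
        poisson_scale=np.inf,
        camera_offset=0.0,
        seed=42,
    )


@pytest.fixture
def small_movie():
    """A short noiseless FRAP movie on a compact field (fast to render)."""
    fp = simgen.frap_field_params(
        seed=5, snr=np.inf, field_size_px=(256, 256), nucleus_radius_um=4.0
    )
    pp = simgen.FrapSimParams(n_postbleach_frames=40, seed=5)
    return simgen.make_frap_movie(fp, pp)


@pytest.fixture
def default_movie():
    """Noiseless movie at the full default acquisition geometry."""
    fp = simgen.frap_field_params(seed=11, snr=np.inf)
    pp = simgen.FrapSimParams(seed=11)
    return simgen.make_frap_movie(fp, pp)
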