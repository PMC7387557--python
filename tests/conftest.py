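"""Shared fixtures: small synthetic movies generated at test time."""

import numpy as np
import pytest

from calfluor.simulate import SimParams, simulate


def small_params(**overrides) -> SimParams:
    """A fast-to-render 96x96 field with 5 cells; noiseless by default."""
    base = dict(
        field_height_px=96,
        field_width_px=96,
        n_cells=5,
        n_frames=40,
        frame_period_s=1.0,
        rate_independent_hz=0.02,
        rate_network_hz=0.05,
        p_sync=0.8,
        shot_noise=False,
        read_noise_sd=0.0,
        seed=0,
    )
    base.update(overrides)
    return SimParams(**base)


@pytest.fixture(scope="session")
def clean_movie():
    """Noiseless 5-cell movie plus ground truth."""
    return simulate(small_params())


@pytest.fixture(scope="session")
def noisy_movie():
    """Same field with shot + read noise."""
    return simulate(small_params(shot_noise=True, read_noise_sd=2.0))


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
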