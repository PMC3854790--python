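"""Shared fixtures: small simulated movies reused across test modules.

Session-scoped fixtures cache rendered stacks so the suite stays fast;
tests must not mutate them.
"""

import numpy as np
import pytest

from spermbeat.simulate import (RenderParams, WaveformParams,
                                simulate_tethered_movie)


@pytest.fixture(scope="session")
def default_wave():
    return WaveformParams()


@pytest.fixture(scope="session")
def default_render():
    return RenderParams(noise_sd=20.0, seed=7)


@pytest.fixture(scope="session")
def tethered_movie(default_wave, default_render):
    """0.5 s tethered movie (100 frames at 200 fps), symmetric beat."""
    return simulate_tethered_movie(default_wave, default_render, 0.5)


@pytest.fixture(scope="session")
def asymmetric_movie():
    """Tethered movie with a strong static (anti-hook) curvature."""
    wave = WaveformParams(static_curvature_per_um=0.005)
    return simulate_tethered_movie(wave, RenderParams(noise_sd=20.0, seed=8),
                                   0.5)


@pytest.fixture(scope="session")
def noisefree_movie(default_wave):
    """Short noise-free movie for geometric accuracy checks."""
    return simulate_tethered_movie(default_wave,
                                   RenderParams(noise_sd=0.0, seed=9), 0.25)


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)
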