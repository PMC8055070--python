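"""Shared fixtures: small synthetic movies and analytic fields.

Movies use a 50 Hz frame rate and a 2 Hz carrier so that short stacks
still contain many oscillation cycles; the analysis band is widened or the
Hilbert edge margin shortened accordingly in the individual tests.
"""

import numpy as np
import pytest

import cortexwave as cw

FRAME_RATE = 50.0
OMEGA = cw.omega_from_hz(2.0, FRAME_RATE)  # radians/frame


def plane_spec(T=80, H=24, W=28, k=(0.0, 0.25), noise_sd=0.0, seed=0):
    return cw.MovieSpec(
        shape=(T, H, W), frame_rate=FRAME_RATE, noise_sd=noise_sd, seed=seed,
        components=[cw.WaveComponentSpec(kind="plane", angular_frequency=OMEGA,
                                         wavevector=k)])


def radial_spec(kind, T=60, H=36, W=36, k_r=0.3, noise_sd=0.0, seed=0,
                center=None):
    return cw.MovieSpec(
        shape=(T, H, W), frame_rate=FRAME_RATE, noise_sd=noise_sd, seed=seed,
        components=[cw.WaveComponentSpec(kind=kind, angular_frequency=OMEGA,
                                         radial_wavenumber=k_r, center=center)])


def phase_of(movie, edge_s=0.2):
    from cortexwave.preprocess import instantaneous_phase
    return instantaneous_phase(movie, edge_s=edge_s)


@pytest.fixture(scope="session")
def plane_movie():
    return cw.generate_movie(plane_spec())


@pytest.fixture(scope="session")
def plane_field(plane_movie):
    ph = phase_of(plane_movie)
    return cw.estimate_pvf(ph, 40)


@pytest.fixture(scope="session")
def source_field():
    movie = cw.generate_movie(radial_spec("source"))
    ph = phase_of(movie)
    return cw.estimate_pvf(ph, 30)
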