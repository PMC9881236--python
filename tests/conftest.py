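import dataclasses

import numpy as np
import pytest

import cacflow as cf


@pytest.fixture(scope="session")
def ref_acq():
    """Reference acquisition: 3.5 MHz, 3 kHz PRF, M=64, K=14, 12 Hz frames."""
    return cf.default_acquisition()


@pytest.fixture(scope="session")
def small_acq():
    return cf.AcquisitionParams(f0=3.5e6, prf=3e3, n_channels=4, ensemble=4)


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


def _single_tone_ensemble(phi0, acq, n_ax=1, n_lat=1, amplitude=1.0):
    """Channel ensemble whose every channel carries exp(j*phi0*k)."""
    k = np.arange(acq.ensemble)
    tone = amplitude * np.exp(1j * phi0 * k)
    data = np.broadcast_to(
        tone, (n_ax, n_lat, acq.n_channels, acq.ensemble)).astype(complex)
    grid = cf.PixelGrid.regular((n_ax, n_lat), 0.4)
    return cf.ChannelEnsemble(data=data.copy(), grid=grid, acq=acq)


@pytest.fixture(scope="session")
def single_tone_factory():
    return _single_tone_ensemble


# ---------------------------------------------------------------------------
# Shared simulated scenes (session-scoped: these drive the behavioral and
# acceptance checks and take seconds each to process)
# ---------------------------------------------------------------------------

TREND_SHAPE = (32, 32)


@pytest.fixture(scope="session")
def bank():
    return cf.default_bank()


@pytest.fixture(scope="session")
def water_slow(ref_acq):
    scene = cf.scene_presets("water_path", shape=TREND_SHAPE, seed=101)
    return scene, cf.simulate_scene(scene, ref_acq, n_frames=3)


@pytest.fixture(scope="session")
def water_fast(ref_acq):
    """Clutter-free reference condition at the fast pump setting."""
    scene = cf.scene_presets("water_path", shape=TREND_SHAPE,
                             axial_velocity_cm_s=10.0, seed=102)
    return scene, cf.simulate_scene(scene, ref_acq, n_frames=3)


@pytest.fixture(scope="session")
def tissue1_fast(ref_acq):
    scene = cf.scene_presets("tissue1", shape=TREND_SHAPE, seed=103)
    return scene, cf.simulate_scene(scene, ref_acq, n_frames=6)


@pytest.fixture(scope="session")
def tissue2_fast(ref_acq):
    scene = cf.scene_presets("tissue2", shape=TREND_SHAPE, seed=104)
    return scene, cf.simulate_scene(scene, ref_acq, n_frames=6)


@pytest.fixture(scope="session")
def stationary_speckle(ref_acq):
    """Speckle + thermal noise only: no vessel, no clutter."""
    scene = dataclasses.replace(
        cf.scene_presets("water_path", shape=TREND_SHAPE, seed=105),
        vessel=None, blood=None)
    return scene, cf.simulate_scene(scene, ref_acq, n_frames=3)
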