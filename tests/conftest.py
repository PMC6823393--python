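import numpy as np
import pytest

from minwave.synthgen import LiposomeSceneSpec, NoiseModel, SlbWaveSpec, render_liposome_movie, render_slb_movie


@pytest.fixture(scope="session")
def pulsing_scene():
    """Noiseless pulsing liposome movie + ground truth (period 50 s, dt 2 s)."""
    spec = LiposomeSceneSpec(mode="pulsing", period=50.0, n_frames=100,
                             noise=NoiseModel(), seed=11)
    return render_liposome_movie(spec) + (spec,)


@pytest.fixture(scope="session")
def deforming_scene():
    """Area-preserving elongating liposome (amplitude 1.2), noiseless."""
    spec = LiposomeSceneSpec(mode="pulsing", period=50.0, n_frames=75,
                             elongation_amplitude=1.2,
                             elongation_phase_lag=10.0,
                             noise=NoiseModel(), seed=12)
    return render_liposome_movie(spec) + (spec,)


@pytest.fixture(scope="session")
def traveling_movie():
    """Noiseless traveling SLB wave: λ=40 µm, v=0.5 µm/s, 1 µm/px, dt 2 s."""
    spec = SlbWaveSpec(kind="traveling", image_size=(16, 256), n_frames=120,
                       wavelength=40.0, velocity=0.5, noise=NoiseModel(),
                       seed=13)
    return render_slb_movie(spec), spec


@pytest.fixture
def disk_mask():
    yy, xx = np.mgrid[0:41, 0:41]
    return (yy - 20) ** 2 + (xx - 20) ** 2 <= 10 ** 2


@pytest.fixture
def initial_seed_mask():
    seed = np.zeros((96, 96), dtype=bool)
    seed[42:54, 42:54] = True
    return seed
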