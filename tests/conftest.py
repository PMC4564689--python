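import numpy as np
import pytest

from spavg.io_volumes import SeedPair, Volume
from spavg.synthetic import make_scene, render_scene


@pytest.fixture
def rng():
    return np.random.default_rng(1234)


@pytest.fixture
def ones_volume():
    """2-channel, 8-slice, 32x32 volume of ones."""
    return Volume(
        data=np.ones((2, 8, 32, 32)),
        voxel_size=(125.0, 40.0, 40.0),
        image_id="ones",
    )


def seedpair_from_truth(spec, jitter=None):
    """Build a SeedPair at the true mother/distal lateral pixel positions."""
    particle = spec.particles[0]
    dxv = spec.voxel_size[2]
    dyv = spec.voxel_size[1]
    mx, my, _ = particle.mother_position
    sx, sy, _ = particle.distal_position
    j = np.zeros(4) if jitter is None else np.asarray(jitter, dtype=float)
    return SeedPair(
        image_id=spec.image_id,
        fit_channel=spec.fit_channel,
        reference_channel=spec.reference_channel,
        mother_seed=(mx / dxv + j[0], my / dyv + j[1]),
        distal_seed=(sx / dxv + j[2], sy / dyv + j[3]),
    )


@pytest.fixture
def pair_scene():
    """A noiseless two-spot scene plus its exact-truth seed pair."""
    spec = make_scene("pair", rng_seed=7)
    volume, truth = render_scene(spec)
    return spec, volume, truth, seedpair_from_truth(spec)


@pytest.fixture
def noisy_pair_scene():
    spec = make_scene("pair", params={"noise_sd": 2.0}, rng_seed=7)
    volume, truth = render_scene(spec)
    return spec, volume, truth, seedpair_from_truth(spec)
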