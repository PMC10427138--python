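import numpy as np
import pytest

from glottiseg import DomainSpec, TrainConfig, UNetSpec, generate_corpus
from glottiseg.dataset_io import frames_from_samples


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def small_domain():
    return DomainSpec(name="cam_a", height=64, width=48, seed=0)


@pytest.fixture(scope="session")
def shifted_domain():
    # flexible-endoscope-like: darker, noisier, blurrier, honeycomb lattice
    return DomainSpec(
        name="cam_b",
        height=80,
        width=64,
        background_level=90.0,
        glottis_contrast=55.0,
        noise_sd=10.0,
        blur_sigma=1.2,
        vignette_strength=0.35,
        honeycomb=True,
        honeycomb_pitch=7,
        seed=1,
    )


@pytest.fixture(scope="session")
def tiny_corpus(small_domain):
    return generate_corpus([small_domain], videos_per_domain=6, frames_per_video=8, seed=7)


@pytest.fixture(scope="session")
def tiny_frames(tiny_corpus):
    return frames_from_samples(tiny_corpus)


@pytest.fixture
def fast_cfg():
    return TrainConfig(seed=1, max_epochs=3, patience=2)


@pytest.fixture
def micro_spec():
    return UNetSpec.micro()


def split_videos(frames, n_test):
    """Hold out the first n_test videos (by sorted id) as a test set."""
    vids = sorted({f.video_id for f in frames})
    test = set(vids[:n_test])
    return (
        [f for f in frames if f.video_id not in test],
        [f for f in frames if f.video_id in test],
    )
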