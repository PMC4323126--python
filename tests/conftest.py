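import numpy as np
import pytest
from hypothesis import settings

from perfquant.phantom import (
    PhantomSpec,
    SignalModelParams,
    generate_phantom,
)
from perfquant.pipeline import StudyData

settings.register_profile("ci", deadline=None, derandomize=True, max_examples=50)
settings.load_profile("ci")


def uniform_signal(value: float = 1.0) -> SignalModelParams:
    """Signal model in which every tissue class is identical (uniform tissue)."""
    classes = ("myocardium", "blood", "body", "fat", "liver", "lung")
    return SignalModelParams(
        r1_0_per_s={c: 1.0 for c in classes},
        s0={c: value for c in classes},
    )


@pytest.fixture(scope="session")
def fast_spec() -> PhantomSpec:
    """Small noisy phantom used by most integration tests."""
    return PhantomSpec.scaled_default(seed=7, grid=48, snr=20.0)


@pytest.fixture(scope="session")
def fast_study(fast_spec) -> StudyData:
    return StudyData.from_phantom(*generate_phantom(fast_spec))


@pytest.fixture(scope="session")
def clean_study() -> StudyData:
    """Noise-free uniform-gain phantom: every myocardial curve identical."""
    spec = PhantomSpec.scaled_default(
        seed=1, grid=48, snr=None,
        coil_gains=[((0.0, 24.0), 0.0, 24.0)],
    )
    return StudyData.from_phantom(*generate_phantom(spec))


@pytest.fixture()
def rng() -> np.random.Generator:
    return np.random.default_rng(20260929)
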