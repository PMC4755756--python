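import numpy as np
import pytest

from femose.synthetic import FixtureSpec, build_fixture, render_map


@pytest.fixture(scope="session")
def default_scene():
    """Resting-state scene (Se fully at X2B) at default noise, seed 7."""
    spec = FixtureSpec(seed=7)
    scene = build_fixture(spec)
    render_map(scene)
    return scene


@pytest.fixture(scope="session")
def noiseless_half_scene():
    """Noiseless scene with all belt sites planted at a 50/50 Se/S mixture."""
    spec = FixtureSpec(seed=11, noise_rms=0.0).with_belt(
        {"X2B": (0.5, 0.5), "X5A": (0.5, 0.5), "X3A": (0.5, 0.5)})
    scene = build_fixture(spec)
    render_map(scene)
    return scene


@pytest.fixture
def make_scene():
    def _make(seed=0, noise_rms=0.02, belt=None, **kwargs):
        spec = FixtureSpec(seed=seed, noise_rms=noise_rms, **kwargs)
        if belt is not None:
            spec = spec.with_belt(belt)
        scene = build_fixture(spec)
        render_map(scene)
        return scene
    return _make


@pytest.fixture
def rng():
    return np.random.default_rng(42)
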