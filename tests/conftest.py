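import numpy as np
import pytest

from fastsw.synth import MotionSpec, generate_quaternion_motion, make_fixture_suite


@pytest.fixture(scope="session")
def suite():
    """The deterministic named fixture bundle used across test modules."""
    return make_fixture_suite(seed=0)


@pytest.fixture(scope="session")
def motion_signal():
    """One medium mixed motion/rest quaternion stream (3000 samples at 50 Hz)."""
    return generate_quaternion_motion(
        MotionSpec(duration=60.0, n_keyframes=20, rest_fraction=0.3, noise_deg=0.5, seed=77)
    )


@pytest.fixture
def rng():
    # fresh, identically-seeded generator per test: deterministic and order-independent
    return np.random.default_rng(12345)


def random_unit_pairs(rng, n):
    """n pairs of independent uniform unit quaternions."""
    from fastsw.synth import random_unit_quaternion

    return random_unit_quaternion(rng, n), random_unit_quaternion(rng, n)
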