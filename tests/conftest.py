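import numpy as np
import pytest

from bimanip.skeleton import ArmSkeleton, HandSkeleton


@pytest.fixture
def arm() -> ArmSkeleton:
    return ArmSkeleton()


@pytest.fixture
def hand() -> HandSkeleton:
    return HandSkeleton()


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(20260921)


def random_in_limit_q(skel, rng, margin: float = 0.02) -> np.ndarray:
    lo, hi = skel.joint_limits[:, 0], skel.joint_limits[:, 1]
    return lo + (hi - lo) * rng.uniform(margin, 1.0 - margin, lo.size)
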