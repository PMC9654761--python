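import numpy as np
import pytest

from skgait.features import feature_matrix
from skgait.simulate import default_config, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """The default synthetic cohort at a fixed seed (shared, read-only)."""
    return generate_cohort(default_config(seed=1))


@pytest.fixture(scope="session")
def cohort_features(default_cohort):
    return feature_matrix(default_cohort)


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)


def random_cycle(rng, n_bumps=1):
    """A hand-rolled smooth random gait cycle (independent of the generator)."""
    from skgait.gait_data import GaitCycle

    t = np.arange(101, dtype=float)
    toe_off = float(rng.uniform(55, 68))
    knee = 5 + 12 * np.exp(-((t - 15) ** 2) / 40.0)
    centers = np.sort(rng.uniform(toe_off + 4, 92, size=n_bumps))
    for c in centers:
        knee = knee + rng.uniform(10, 40) * np.exp(-((t - c) ** 2) / rng.uniform(30, 80))
    hip = 10 + rng.uniform(10, 22) * np.cos(2 * np.pi * (t - 88) / 100)
    ankle = 5 * np.sin(2 * np.pi * t / 100) - rng.uniform(0, 6)
    return GaitCycle(
        hip_angle=hip, knee_angle=knee, ankle_angle=ankle,
        toe_off=toe_off,
        contralateral_foot_strike=toe_off - 10,
        tibia_vertical=float(rng.uniform(toe_off + 15, 96)),
        cycle_duration=float(rng.uniform(0.9, 1.8)),
    )
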