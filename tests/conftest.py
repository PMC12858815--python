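import numpy as np
import pytest

from mobgait.synth import (
    generate_gait_test,
    generate_week_recording,
    phenotype_presets,
    schedule_for_group,
)


@pytest.fixture(scope="session")
def pd_preset():
    return phenotype_presets("PD")


@pytest.fixture(scope="session")
def noiseless_pd_test(pd_preset):
    """A clean two-pass walk test with ground truth (PD preset)."""
    return generate_gait_test(pd_preset, n_strides_per_pass=8, seed=42, noise_sd=(0.0, 0.0))


@pytest.fixture(scope="session")
def straight_walk(pd_preset):
    """Single straight pass, 20 strides per foot, noiseless (no turn)."""
    return generate_gait_test(
        pd_preset, n_strides_per_pass=20, n_passes=1, seed=7, noise_sd=(0.0, 0.0)
    )


@pytest.fixture(scope="session")
def small_week():
    """A scaled-down 4-day MSA week at 25.6 Hz (few bouts per day)."""
    ph = phenotype_presets("MSA")
    rng = np.random.default_rng(3)
    counts = {"short": 10, "medium": 2, "long": 1}
    schedules = [
        schedule_for_group(ph, rng, bout_counts=counts, target_steps=600,
                           wear_hours=8.4, nonwear_minutes=0.0)
        for _ in range(4)
    ]
    return generate_week_recording(schedules, ph, seed=9, fs=25.6)
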