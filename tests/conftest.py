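import numpy as np
import pytest

from tapkin import CohortSpec, HandKinematicParams, generate_cohort


@pytest.fixture
def noiseless_params():
    """Deterministic hand kinematics: every stochastic knob switched off."""
    return HandKinematicParams(
        tap_count=18,
        amp_mean_pct=80.0,
        amp_sd_pct=0.0,
        decrement_per_tap_pct=0.0,
        halt_prob=0.0,
        timing_jitter_cv=0.0,
        noise_sd_pct=0.0,
    )


@pytest.fixture(scope="session")
def small_cohort():
    """A 12+12 cohort from the default clinical presets (session-cached)."""
    return generate_cohort(CohortSpec(n_control=12, n_pd=12, seed=123))


@pytest.fixture
def rng():
    return np.random.default_rng(20260919)
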