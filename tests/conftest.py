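import numpy as np
import pandas as pd
import pytest

from quercinus.io import captures_to_frame
from quercinus.simulate import (
    SyntheticConfig,
    simulate_captures,
    simulate_population,
)


@pytest.fixture
def small_config():
    """Small but fully structured synthetic study."""
    return SyntheticConfig(n_juveniles_per_period=20, n_adults_per_period=10)


@pytest.fixture
def zero_noise_config():
    """Deterministic generator: no noise, no rounding, certain detection."""
    return SyntheticConfig(
        n_juveniles_per_period=20,
        n_adults_per_period=10,
        tl_noise_sd=0.0,
        adult_intercept_sd=0.0,
        adult_residual_sd=0.0,
        juvenile_intercept_sd=0.0,
        juvenile_residual_sd=0.0,
        temp_noise_sd=0.0,
        round_measurements=False,
        detection_prob=1.0,
    )


@pytest.fixture
def capture_frame(small_config):
    roster = simulate_population(small_config, 42)
    frame = captures_to_frame(simulate_captures(roster, small_config, 43))
    return frame.merge(
        roster[["individual_id", "birth_week"]], on="individual_id", how="left"
    )
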