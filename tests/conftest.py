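"""Shared fixtures: miniature and mid-sized populations generated in-process."""

import numpy as np
import pytest

from svycausal import PopulationConfig, generate_population
from svycausal.config import substream


@pytest.fixture(scope="session")
def midi_config():
    """Mid-sized 8-stratum population: big enough for stable survey samples,
    small enough to regenerate in well under a second."""
    return PopulationConfig(
        n_bg=80,
        bg_per_stratum=(10,) * 8,
        hh_per_bg_mean=120.0,
        seed=42,
    )


@pytest.fixture(scope="session")
def midi_population(midi_config):
    return generate_population(midi_config)


@pytest.fixture(scope="session")
def midi_sample(midi_population):
    from svycausal import draw_survey_sample

    return draw_survey_sample(midi_population, 1, substream(7, "replicate", 1, 0))


@pytest.fixture()
def rng():
    return np.random.default_rng(12345)
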