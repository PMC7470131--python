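import numpy as np
import pytest

from mfrelease.kinetics import StageWindow
from mfrelease.synthetic_data import SyntheticConfig, generate_release_curve


@pytest.fixture
def burst_window():
    return StageWindow(1.0, 8.0, "first stage")


@pytest.fixture
def sustained_window():
    return StageWindow(24.0, 120.0, "second stage")


@pytest.fixture
def hourly_schedule():
    return np.array([1.0, 2.0, 3.0, 4.0, 6.0, 8.0])


def make_curve(model_id, params, schedule, units="percent", noise_sd=0.0, seed=0,
               plateau=None):
    """Synthetic single-stage curve straight from a truth model."""
    cfg = SyntheticConfig(truth_model=model_id, truth_params=[params],
                          plateau=plateau, noise_sd=noise_sd, seed=seed,
                          schedule=schedule, units=units)
    return generate_release_curve(cfg)


@pytest.fixture
def two_stage_noisy_curve():
    """A realistic two-stage profile: burst then sustained, 5% noise, 70% plateau."""
    cfg = SyntheticConfig(
        truth_model="korsmeyer_peppas",
        truth_params=[{"k": 0.15, "n": 0.75}, {"k": 0.02, "n": 0.5}],
        stage_bounds=[StageWindow(1.0, 8.0), StageWindow(24.0, 240.0)],
        plateau=0.70, noise_sd=0.05, seed=42, units="fraction")
    curve, truth = generate_release_curve(cfg)
    return curve, truth
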