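import numpy as np
import pytest

from curvmap.stimuli import StimulusSpec
from curvmap.synth import CortexParams, NoiseSpec, make_cortical_model, simulate_session


@pytest.fixture()
def rng():
    return np.random.default_rng(1234)


@pytest.fixture(scope="session")
def small_model():
    """A 64x64 model with one curvature and one straight domain, noiseless-
    friendly amplitudes; shared across read-only tests."""
    params = CortexParams(
        shape=(64, 64),
        n_curvature_domains=1,
        n_straight_domains=1,
        curvature_ratios=(5.0,),
        domain_radius_mm=(0.15, 0.15),
        amplitude_range=(2e-4, 2e-4),
        band_period_mm=1.6,
        min_separation_mm=0.5,
    )
    return make_cortical_model(params, seed=42)


@pytest.fixture(scope="session")
def tiny_conditions():
    return {
        "c5_up": StimulusSpec("curved_grating", 5.0, "up"),
        "s0": StimulusSpec("straight_grating", 0.0, 0.0),
        "s90": StimulusSpec("straight_grating", 0.0, 90.0),
        "blank": StimulusSpec("blank"),
    }


@pytest.fixture(scope="session")
def noiseless_session(small_model, tiny_conditions):
    """Exact forward model: no noise, float64."""
    return simulate_session(
        small_model, tiny_conditions, n_trials=3,
        noise=NoiseSpec(pixel_noise_sd=0.0, drift_amplitude=0.0,
                        vascular_contrast=0.0),
        seed=7, dtype=np.float64,
    )
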