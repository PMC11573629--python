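"""Shared fixtures: small synthetic colonies sized for fast unit tests.

The clean fixture disables noise and drift so detector outputs are exact;
scenario tests that need noise or drift build their own configs.
"""

import numpy as np
import pytest

from colonykymo import (AnalysisParams, SimulationConfig, run_analysis,
                        simulate_colony)


@pytest.fixture(scope="session")
def clean_config():
    return SimulationConfig(
        image_size=192, pixel_size=0.04, t_end=54.0,
        noise_model="none", noise_scale=0.0,
        drift_max_translation=0.0, drift_max_rotation=0.0,
        background_level=50.0, background_gradient=0.05, seed=0,
    )


@pytest.fixture(scope="session")
def clean_stack_truth(clean_config):
    return simulate_colony(clean_config)


@pytest.fixture(scope="session")
def clean_result(clean_stack_truth):
    stack, _ = clean_stack_truth
    return run_analysis(stack, AnalysisParams(register=False))


@pytest.fixture(scope="session")
def noisy_config():
    """Default-style study conditions at reduced resolution."""
    return SimulationConfig(image_size=256, pixel_size=0.03, t_end=54.0,
                            seed=3)


@pytest.fixture(scope="session")
def noisy_result(noisy_config):
    stack, truth = simulate_colony(noisy_config)
    return run_analysis(stack), truth


@pytest.fixture()
def rng():
    return np.random.default_rng(42)
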