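import numpy as np
import pytest

from bcperf import (
    NoiseSpec,
    NoiseWeights,
    PhysioParams,
    StimulusDesign,
    estimate_baselines,
    simulate_measured_pair,
    simulate_truth,
)


@pytest.fixture
def rng():
    return np.random.default_rng(20230131)


@pytest.fixture
def paper_design():
    """Reference block design: 60 s rest, 4 x (20 s on / 60 s off), 30 s rest."""
    return StimulusDesign()


@pytest.fixture
def default_params():
    return PhysioParams()  # M=0.11, alpha_v=0.2, lam=0.35 -> k=0.0495


@pytest.fixture
def nominal_weights():
    """Weights from the nominal noise magnitudes (36% of f0=28, 0.5% of b0=11200)."""
    return NoiseWeights.from_sigmas(0.36 * 28.0, 0.005 * 11200.0)


@pytest.fixture
def noise_free_pair(paper_design, default_params):
    truth = simulate_truth(paper_design, default_params)
    pair = simulate_measured_pair(truth, noise=NoiseSpec(0.0, 0.0))
    pair.f0, pair.b0 = estimate_baselines(pair, 20)
    return truth, pair


@pytest.fixture
def noisy_pair(paper_design, default_params):
    truth = simulate_truth(paper_design, default_params)
    pair = simulate_measured_pair(truth, noise=NoiseSpec(seed=42))
    pair.f0, pair.b0 = estimate_baselines(pair, 20)
    return truth, pair
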