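import numpy as np
import pytest
from hypothesis import settings

settings.register_profile("ci", derandomize=True, max_examples=25, deadline=None)
settings.load_profile("ci")


@pytest.fixture
def rng():
    return np.random.default_rng(20260301)


@pytest.fixture(scope="session")
def tiny_fit():
    """A very small simulated dataset with a short fitted chain, shared by
    tests that only need plausible posterior draws (not a converged fit)."""
    from otubayes.sampler import MCMCConfig, run_mcmc
    from otubayes.synthetic import SimConfig, simulate_dataset

    cfg = SimConfig(
        J=6, n_times=8, years=1.0, replicates=(2,), P_continuous=2,
        categorical_levels=(2,), missing_prob=0.25,
    )
    data, covars, truth = simulate_dataset(cfg, seed=42)
    mc = MCMCConfig(
        iterations=400, burn_in=200, thin=2, L_r=5, L_alpha=5,
        M=4, t1p=0.2, t2p=0.2,
    )
    draws = run_mcmc(data, covars, mc, seed=7)
    return data, covars, truth, draws, mc
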