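import numpy as np
import pytest

from triomr.simulate import default_params, simulate_assortative


@pytest.fixture
def rng():
    return np.random.default_rng(12345)


@pytest.fixture(scope="session")
def assortative_dataset():
    """One simulated population with strong assortment (shared, read-only)."""
    return simulate_assortative(
        default_params(p_assort=0.8, n_trios=1000, beta_XY=1.0, seed=424242))


def noiseless_params(**overrides):
    """Fully deterministic configuration: exact two-stage recovery expected.

    The exposure is an exact function of the genotype codings and the outcome
    equals the exposure, so every estimator must return the generative effect
    exactly.
    """
    base = dict(freq_A=0.5, freq_B=0.5, beta_GD_X=1.0, beta_GA_X=0.5,
                beta_HA_X=0.0, beta_HD_X=0.0, beta_HA_Y=0.0, beta_HD_Y=0.0,
                beta_U_X=0.0, beta_U_Y=0.0, beta_XY=1.0,
                var_U=0.0, var_eps_X=0.0, var_eps_Y=0.0)
    base.update(overrides)
    return default_params(**base)
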