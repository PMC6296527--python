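import numpy as np
import pytest

from cryptscore.simulate import CryptSimParams, TrialSimParams, simulate_crypt_image, simulate_trial


@pytest.fixture(scope="session")
def uniform_crypt():
    """Noiseless uniform-profile synthetic crypt with total OD 100."""
    params = CryptSimParams(profile_kind="uniform", total_od=100.0, noise_sd=0.0, seed=7)
    image, outline, truth = simulate_crypt_image(params)
    return params, image, outline, truth


@pytest.fixture(scope="session")
def basal_crypt():
    """Noiseless basal-gradient crypt (signal concentrated at the base)."""
    params = CryptSimParams(profile_kind="basal_gradient", total_od=100.0, noise_sd=0.0, seed=11)
    image, outline, truth = simulate_crypt_image(params)
    return params, image, outline, truth


@pytest.fixture(scope="session")
def null_trial_df():
    """Study-sized trial with no treatment effect, one variable."""
    params = TrialSimParams(
        baseline_log_mean={("mib1", "whole"): 7.0},
        seed=100,
    )
    return simulate_trial(params)


@pytest.fixture(scope="session")
def effect_trial_df():
    """Study-sized trial with a planted 1.3 relative effect of vitamin D."""
    params = TrialSimParams(
        baseline_log_mean={("mib1", "whole"): 7.0},
        true_relative_effect={"D": 1.3, "CaD": 1.3, "CaD2arm": 1.3},
        seed=101,
    )
    return simulate_trial(params)


@pytest.fixture
def rng():
    return np.random.default_rng(2024)
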