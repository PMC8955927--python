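import numpy as np
import pytest

from reportmix import (
    DecayLaw,
    FitResult,
    GaussianComponent,
    MixtureSpec,
    ModelCParams,
    bic_score,
)


@pytest.fixture
def model_c_params() -> ModelCParams:
    """A Model C truth with well-separated component SDs."""
    return ModelCParams(
        omega1=0.75,
        omega2=0.50,
        sm_decay=DecayLaw("exponential_approach", sigma0=19.0, sigma_inf=40.0, tau=500.0),
        sigma_attention=8.0,
        sigma_stm=6.0,
    )


@pytest.fixture
def one_gauss_spec() -> MixtureSpec:
    return MixtureSpec((GaussianComponent(0.0, 12.0, 0.7),), 0.3)


def make_fit_result(spec: MixtureSpec, log_likelihood: float = -100.0,
                    n_obs: int = 100, n_free_params: int = 3) -> FitResult:
    """A structurally valid FitResult for tests that only need the spec."""
    return FitResult(
        spec=spec,
        log_likelihood=log_likelihood,
        n_obs=n_obs,
        n_free_params=n_free_params,
        bic=bic_score(n_free_params, n_obs, log_likelihood),
        converged=True,
        n_starts_used=1,
        best_start_index=0,
    )


@pytest.fixture
def rng() -> np.random.Generator:
    return np.random.default_rng(12345)
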