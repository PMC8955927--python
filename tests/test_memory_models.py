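"""Block-diagram reductions, decay laws, and the sampling/reduction equivalence."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from reportmix import (
    DecayLaw,
    ExperimentDesign,
    GaussianComponent,
    GenerativeScenario,
    ModelCParams,
    ModelDParams,
    mixture_cdf,
    reduce_model_a_b,
    reduce_model_c,
    reduce_model_d,
    simulate_trials,
)


# ---------------------------------------------------------------------------
# decay laws


@pytest.mark.parametrize(
    "law",
    [
        DecayLaw("constant", 10.0),
        DecayLaw("linear_saturating", 10.0, 30.0, 400.0),
        DecayLaw("exponential_approach", 10.0, 30.0, 400.0),
    ],
)
def test_decay_starts_at_sigma0_and_is_nondecreasing(law):
    assert law.sigma_at(0.0) == pytest.approx(10.0)
    ts = np.linspace(0.0, 3000.0, 50)
    vals = [law.sigma_at(t) for t in ts]
    assert all(b >= a - 1e-12 for a, b in zip(vals, vals[1:]))
    if law.form != "constant":
        assert vals[-1] <= 30.0 + 1e-12


def test_decay_validation():
    with pytest.raises(ValueError):
        DecayLaw("exponential_approach", 10.0, 5.0, 400.0)  # sigma_inf < sigma0
    with pytest.raises(ValueError):
        DecayLaw("linear_saturating", 10.0, 30.0, 0.0)  # tau <= 0
    with pytest.raises(ValueError):
        DecayLaw("exponential_approach", 10.0)  # missing sigma_inf/tau


# ---------------------------------------------------------------------------
# Models A and B


def test_model_b_reduction_is_one_gaussian_with_convolved_sd():
    spec = reduce_model_a_b(
        (GaussianComponent(0.0, 6.0, 1.0), GaussianComponent(0.0, 8.0, 1.0)), 0.7
    )
    assert spec.n_components == 1
    assert spec.components[0].sigma == pytest.approx(10.0)
    assert spec.components[0].weight == pytest.approx(0.7)
    assert spec.uniform_weight == pytest.approx(0.3)


def test_model_ab_degenerate_omegas():
    pure_guess = reduce_model_a_b(GaussianComponent(0.0, 10.0, 1.0), 0.0)
    assert pure_guess.n_components == 0
    assert pure_guess.uniform_weight == 1.0

    tiny_stm = reduce_model_a_b(
        (GaussianComponent(0.0, 10.0, 1.0), GaussianComponent(0.0, 1e-9, 1.0)), 1.0
    )
    assert tiny_stm.uniform_weight == 0.0
    assert tiny_stm.components[0].sigma == pytest.approx(10.0)


# ---------------------------------------------------------------------------
# Model C


def test_model_c_weights(model_c_params):
    p = model_c_params  # omega1=0.75, omega2=0.5
    spec = reduce_model_c(p, 0.0)
    weights = sorted(c.weight for c in spec.components)
    assert weights == pytest.approx([0.375, 0.375])
    assert spec.uniform_weight == pytest.approx(0.25)


@settings(derandomize=True, max_examples=100)
@given(st.floats(0.01, 0.99), st.floats(0.01, 0.99))
def test_model_c_weights_always_sum_to_one(omega1, omega2):
    p = ModelCParams(
        omega1, omega2, DecayLaw("constant", 15.0), sigma_attention=8.0, sigma_stm=6.0
    )
    spec = reduce_model_c(p, 100.0)
    total = sum(c.weight for c in spec.components) + spec.uniform_weight
    assert total == pytest.approx(1.0, abs=1e-12)


def test_model_c_collapses_to_model_b_when_omega2_is_one(model_c_params):
    from dataclasses import replace

    spec = reduce_model_c(replace(model_c_params, omega2=1.0), 0.0)
    assert spec.n_components == 1
    assert spec.components[0].sigma == pytest.approx(math.hypot(19.0, 6.0))


def test_model_c_signature_only_sm_component_depends_on_delay(model_c_params):
    early = reduce_model_c(model_c_params, 0.0)
    late = reduce_model_c(model_c_params, 1600.0)
    # narrow (attention-routed) component identical at both delays
    assert early.components[0].sigma == pytest.approx(late.components[0].sigma)
    # wide (SM-routed) component grows with delay
    assert late.components[1].sigma > early.components[1].sigma + 5.0


# ---------------------------------------------------------------------------
# Model D


def _model_d_params(decaying: bool = True) -> ModelDParams:
    decay = (
        DecayLaw("exponential_approach", 12.0, 35.0, 400.0)
        if decaying
        else DecayLaw("constant", 12.0)
    )
    return ModelDParams(
        omega1=0.5,
        omega2=0.3,
        sm_decay1=decay,
        sigma_stm1=5.0,
        sm_decay2=decay,
        sigma_stm2=9.0,
    )


def test_model_d_uniform_weight():
    spec = reduce_model_d(_model_d_params(), 0.0)
    assert spec.uniform_weight == pytest.approx(0.2)
    assert sorted(c.weight for c in spec.components) == pytest.approx([0.3, 0.5])


def test_model_d_identical_routes_merge():
    p = ModelDParams(
        omega1=0.5,
        omega2=0.3,
        sm_decay1=DecayLaw("constant", 10.0),
        sigma_stm1=5.0,
        sm_decay2=DecayLaw("constant", 10.0),
        sigma_stm2=5.0,
    )
    spec = reduce_model_d(p, 0.0)
    assert spec.n_components == 1
    assert spec.components[0].weight == pytest.approx(0.8)


def test_model_d_signature_both_components_depend_on_delay():
    early = reduce_model_d(_model_d_params(), 0.0)
    late = reduce_model_d(_model_d_params(), 1600.0)
    for e, l in zip(early.components, late.components):
        assert l.sigma > e.sigma + 3.0


# ---------------------------------------------------------------------------
# sequential sampling vs analytic reduction


def _sampled_cell(scenario, n, seed, delay=400.0):
    design = ExperimentDesign(
        experiment="cue_delay",
        cue_delays_ms=(delay,),
        trials_per_cell=n,
        subjects=1,
        report_conditions=("SR",),
        seed=seed,
    )
    recs = simulate_trials(design, scenario)
    return np.array([r.error_deg for r in recs])


def test_sequential_sampling_matches_model_c_reduction(model_c_params):
    """Stage-wise simulation and the convolution reduction agree (KS)."""
    scenario = GenerativeScenario(
        model="C", params=model_c_params, sigma_jitter_sd=0.0, weight_logit_jitter_sd=0.0
    )
    errs = _sampled_cell(scenario, 20_000, seed=7)
    spec = reduce_model_c(model_c_params, 400.0)
    p = stats.kstest(errs, lambda x: mixture_cdf(spec, x)).pvalue
    assert p > 0.01


def test_clipping_discrepancy_grows_with_sigma(model_c_params):
    """Near-90-deg SDs make the Gaussian reduction approximate: the KS distance
    between wrapped stage-sampling and the truncated density must grow."""
    from dataclasses import replace

    narrow = model_c_params
    wide = replace(
        narrow,
        sm_decay=DecayLaw("constant", 90.0),
        sigma_attention=85.0,
        sigma_stm=30.0,
    )
    stat = {}
    for name, p in [("narrow", narrow), ("wide", wide)]:
        scenario = GenerativeScenario(
            model="C", params=p, sigma_jitter_sd=0.0, weight_logit_jitter_sd=0.0
        )
        errs = _sampled_cell(scenario, 20_000, seed=11)
        spec = reduce_model_c(p, 400.0)
        stat[name] = stats.kstest(errs, lambda x: mixture_cdf(spec, x)).statistic
    assert stat["wide"] > stat["narrow"]
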