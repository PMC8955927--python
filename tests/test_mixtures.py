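"""Densities, transforms and types on the bounded error domain."""

import json
import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats
from scipy.integrate import quad

from reportmix import (
    GaussianComponent,
    MixtureSpec,
    TrialRecord,
    convolve_gaussians,
    mixture_cdf,
    mixture_pdf,
    mixture_quantile,
    sample_mixture,
    transform_performance,
    wrap_error,
)


# ---------------------------------------------------------------------------
# transformed performance


@pytest.mark.parametrize(
    "err,expected",
    [(0.0, 1.0), (180.0, 0.0), (-180.0, 0.0), (-90.0, 0.5), (90.0, 0.5)],
)
def test_transform_performance_anchors(err, expected):
    assert transform_performance(err) == pytest.approx(expected)


def test_transform_performance_rejects_out_of_range():
    with pytest.raises(ValueError):
        transform_performance(181.0)
    with pytest.raises(ValueError):
        transform_performance(np.inf)


def test_transform_performance_vectorized():
    out = transform_performance([0.0, 90.0, 180.0])
    assert np.allclose(out, [1.0, 0.5, 0.0])


# ---------------------------------------------------------------------------
# wrapping


@pytest.mark.parametrize(
    "angle,expected", [(190.0, -170.0), (-180.0, 180.0), (45.0, 45.0), (540.0, 180.0)]
)
def test_wrap_error_examples(angle, expected):
    assert wrap_error(angle) == pytest.approx(expected)


def test_wrap_error_rejects_non_finite():
    with pytest.raises(ValueError):
        wrap_error(np.nan)


@settings(derandomize=True, max_examples=200)
@given(st.floats(min_value=-2000.0, max_value=2000.0))
def test_wrap_error_is_mod_360_onto_half_open_interval(angle):
    w = wrap_error(angle)
    assert -180.0 < w <= 180.0
    assert math.isclose(math.cos(math.radians(w - angle)), 1.0, abs_tol=1e-9)


# ---------------------------------------------------------------------------
# densities


def uniform_only() -> MixtureSpec:
    return MixtureSpec((), 1.0)


def test_uniform_only_density_is_1_over_360():
    spec = uniform_only()
    for e in (-179.0, 0.0, 33.3, 180.0):
        assert mixture_pdf(spec, e) == pytest.approx(1.0 / 360.0)


def test_single_gaussian_peak_density_plain():
    spec = MixtureSpec((GaussianComponent(0.0, 10.0, 1.0),), 0.0)
    assert mixture_pdf(spec, 0.0, "plain") == pytest.approx(
        1.0 / (10.0 * math.sqrt(2 * math.pi))
    )


def test_half_mixture_density_and_unit_mass():
    spec = MixtureSpec((GaussianComponent(0.0, 10.0, 0.5),), 0.5)
    # plain-mode value: half peak + half uniform (truncation negligible at 10 deg)
    expected = 0.5 / (10.0 * math.sqrt(2 * math.pi)) + 0.5 / 360.0
    assert mixture_pdf(spec, 0.0, "plain") == pytest.approx(expected)
    mass, err = quad(lambda x: mixture_pdf(spec, x), -180.0, 180.0)
    assert mass == pytest.approx(1.0, abs=1e-8)


@st.composite
def valid_specs(draw):
    n = draw(st.integers(min_value=0, max_value=3))
    mus = [draw(st.floats(-60.0, 60.0)) for _ in range(n)]
    sigmas = [draw(st.floats(1.0, 120.0)) for _ in range(n)]
    raw = [draw(st.floats(0.05, 1.0)) for _ in range(n + 1)]
    total = sum(raw)
    comps = tuple(
        GaussianComponent(m, s, w / total) for m, s, w in zip(mus, sigmas, raw[:n])
    )
    return MixtureSpec(comps, raw[n] / total)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(valid_specs())
def test_truncated_pdf_integrates_to_one(spec):
    mass, _ = quad(
        lambda x: mixture_pdf(spec, x),
        -180.0,
        180.0,
        limit=200,
        points=[c.mu for c in spec.components],
    )
    assert mass == pytest.approx(1.0, abs=1e-6)


@settings(derandomize=True, max_examples=40, deadline=None)
@given(valid_specs())
def test_cdf_monotone_and_bounded(spec):
    xs = np.linspace(-180.0, 180.0, 181)
    cdf = mixture_cdf(spec, xs)
    assert np.all(np.diff(cdf) >= -1e-12)
    assert cdf[0] == pytest.approx(0.0, abs=1e-12)
    assert cdf[-1] == pytest.approx(1.0, abs=1e-9)


def test_cdf_symmetry_values():
    assert mixture_cdf(uniform_only(), 0.0) == pytest.approx(0.5)
    spec = MixtureSpec(
        (GaussianComponent(0.0, 10.0, 0.4), GaussianComponent(0.0, 40.0, 0.3)), 0.3
    )
    assert mixture_cdf(spec, 0.0) == pytest.approx(0.5, abs=1e-9)
    shifted = MixtureSpec((GaussianComponent(30.0, 5.0, 1.0),), 0.0)
    assert mixture_cdf(shifted, 30.0) == pytest.approx(0.5, abs=1e-6)


def test_cdf_quantile_identity():
    spec = MixtureSpec((GaussianComponent(5.0, 20.0, 0.6),), 0.4)
    for q in (0.05, 0.3, 0.5, 0.9, 0.99):
        x = mixture_quantile(spec, q)
        assert mixture_cdf(spec, x) == pytest.approx(q, abs=1e-6)


def test_degenerate_sigma_rejected():
    with pytest.raises(ValueError):
        GaussianComponent(0.0, 0.0, 1.0)
    with pytest.raises(ValueError):
        GaussianComponent(0.0, -3.0, 1.0)


# ---------------------------------------------------------------------------
# convolution


@pytest.mark.parametrize(
    "g1,g2,mu,sigma",
    [
        ((0.0, 3.0), (0.0, 4.0), 0.0, 5.0),
        ((2.0, 1.0), (-2.0, 1.0), 0.0, math.sqrt(2.0)),
    ],
)
def test_convolution_arithmetic(g1, g2, mu, sigma):
    out = convolve_gaussians(
        GaussianComponent(*g1, 1.0), GaussianComponent(*g2, 1.0)
    )
    assert out.mu == pytest.approx(mu)
    assert out.sigma == pytest.approx(sigma)


def test_convolution_matches_sampled_sum(rng):
    """Monte-Carlo oracle: X + Y for Gaussian X, Y follows the convolved law."""
    g1, g2 = GaussianComponent(3.0, 6.0, 1.0), GaussianComponent(-1.0, 8.0, 1.0)
    out = convolve_gaussians(g1, g2)
    x = rng.normal(g1.mu, g1.sigma, 100_000) + rng.normal(g2.mu, g2.sigma, 100_000)
    p = stats.kstest(x, stats.norm(out.mu, out.sigma).cdf).pvalue
    assert p > 0.01


# ---------------------------------------------------------------------------
# types


def test_spec_sorts_components_by_sigma():
    spec = MixtureSpec(
        (GaussianComponent(0.0, 30.0, 0.3), GaussianComponent(0.0, 8.0, 0.4)), 0.3
    )
    assert [c.sigma for c in spec.components] == [8.0, 30.0]


def test_spec_rejects_bad_weight_sum():
    with pytest.raises(ValueError):
        MixtureSpec((GaussianComponent(0.0, 10.0, 0.5),), 0.6)


def test_spec_rejects_more_than_five_components():
    comps = tuple(GaussianComponent(0.0, 5.0 + i, 0.1) for i in range(6))
    with pytest.raises(ValueError):
        MixtureSpec(comps, 0.4)


def test_spec_json_roundtrip():
    spec = MixtureSpec(
        (GaussianComponent(1.5, 9.0, 0.45), GaussianComponent(-2.0, 33.0, 0.25)), 0.3
    )
    again = MixtureSpec.from_json(spec.to_json())
    assert again == spec
    assert json.loads(spec.to_json())["support"] == [-180.0, 180.0]


def test_trial_record_validation():
    TrialRecord("s1", "cue_delay", "SR", 3, 400.0, 12.5)
    with pytest.raises(ValueError):
        TrialRecord("s1", "cue_delay", "SR", 3, 400.0, -180.0)
    with pytest.raises(ValueError):
        TrialRecord("s1", "cue_delay", "SR", 0, 400.0, 0.0)
    with pytest.raises(ValueError):
        TrialRecord("s1", "nope", "SR", 3, 400.0, 0.0)


def test_sample_mixture_stays_on_support(rng):
    spec = MixtureSpec((GaussianComponent(170.0, 40.0, 0.8),), 0.2)
    x = sample_mixture(spec, 5000, rng)
    assert np.all(x > -180.0) and np.all(x <= 180.0)
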