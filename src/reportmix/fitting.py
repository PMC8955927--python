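"""Maximum-likelihood fitting of n-Gaussian + uniform mixtures.

Mixtures with n = 1..5 Gaussian components plus a uniform guessing
component are fit to report-error samples by derivative-free simplex
(Nelder-Mead) search over an unconstrained parameterisation:

* component SDs through a logistic transform of log-sigma between the
  configured bounds (default 0.5-180 deg; the lower bound prevents spike
  components on repeated values);
* mixture weights through a softmax over component logits with the uniform
  logit pinned at 0, which keeps the weights on the simplex;
* component means either free (unconstrained) or fixed at 0.

Mixture likelihoods are multimodal, so each fit runs from multiple start
points (one moment-based deterministic start plus stratified random
starts: SDs log-uniform on [2, 90] deg, weights Dirichlet-uniform, means
N(0, 10) when free) and keeps the best.  All likelihood computation is in
log space on the truncated-renormalized density by default, so the
objective is a proper log-likelihood and BIC comparisons are valid.

Two objectives are available: ``max_likelihood`` (default) and
``cdf_least_squares``, which minimises the squared distance between the
model CDF and the empirical CDF at the sorted sample; the log-likelihood
is reported at the optimum either way so BIC stays comparable.

Model comparison fits each n with a shared seeding policy and picks the
smallest BIC (ties broken toward smaller n).  Fits for n are warm-started
from the best (n-1)-fit with a near-zero-weight extra component, which
also guarantees the in-sample likelihood never degrades as n grows.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
from scipy.optimize import minimize
from scipy.special import expit, logit

from .mixtures import (
    SUPPORT,
    ClipMode,
    GaussianComponent,
    MixtureSpec,
    _cdf_arrays,
    _check_clip_mode,
    _pdf_arrays,
)

__all__ = [
    "FitOptions",
    "FitResult",
    "ModelComparison",
    "bic_score",
    "compare_models",
    "fit_cdf_least_squares",
    "fit_mixture",
    "neg_log_likelihood",
]

_DENSITY_FLOOR = 1e-300


def bic_score(n_free_params: int, n_obs: int, log_likelihood: float) -> float:
    """Bayesian information criterion, k*ln(N) - 2*ln(L), in nats."""
    if n_obs <= 0:
        raise ValueError("n_obs must be positive")
    return n_free_params * math.log(n_obs) - 2.0 * log_likelihood


@dataclass(frozen=True)
class FitOptions:
    """Configuration of a single mixture fit.

    ``n_components`` counts Gaussian components (1..5).  Free-parameter
    count per Gaussian is 3 (mu, sigma, weight; the uniform weight is
    implied) or 2 with ``fix_means_at_zero``.
    """

    n_components: int = 1
    objective: str = "max_likelihood"  # or "cdf_least_squares"
    clip_mode: ClipMode = "truncated_renormalized"
    fix_means_at_zero: bool = False
    n_starts: int = 20
    seed: int = 0
    sigma_bounds: tuple[float, float] = (0.5, 180.0)
    min_component_weight: float = 0.0
    max_iterations: int = 4000
    convergence_tolerance: float = 1e-8

    def __post_init__(self) -> None:
        if not 1 <= self.n_components <= 5:
            raise ValueError("n_components must lie in 1..5")
        if self.objective not in ("max_likelihood", "cdf_least_squares"):
            raise ValueError(f"unknown objective {self.objective!r}")
        _check_clip_mode(self.clip_mode)
        if self.n_starts < 1:
            raise ValueError("n_starts must be >= 1")
        lo, hi = self.sigma_bounds
        if not (0.5 <= lo < hi <= 180.0):
            raise ValueError("sigma_bounds must satisfy 0.5 <= lo < hi <= 180")
        if not (0.0 <= self.min_component_weight <= 0.1):
            raise ValueError("min_component_weight must lie in [0, 0.1]")

    @property
    def n_free_params(self) -> int:
        per = 2 if self.fix_means_at_zero else 3
        return per * self.n_components


@dataclass(frozen=True)
class FitResult:
    """A fitted mixture with its objective and model-comparison metadata."""

    spec: MixtureSpec
    log_likelihood: float
    n_obs: int
    n_free_params: int
    bic: float
    converged: bool
    n_starts_used: int
    best_start_index: int
    objective: str = "max_likelihood"
    objective_value: float = math.nan
    warnings: tuple[str, ...] = ()
    objective_value_trace: tuple[float, ...] | None = None

    def __post_init__(self) -> None:
        expected = bic_score(self.n_free_params, self.n_obs, self.log_likelihood)
        if abs(self.bic - expected) > 1e-9:
            raise ValueError("bic inconsistent with k*ln(N) - 2*ln(L)")

    def to_dict(self) -> dict:
        return {
            "spec": self.spec.to_dict(),
            "log_likelihood": self.log_likelihood,
            "n_obs": self.n_obs,
            "n_free_params": self.n_free_params,
            "bic": self.bic,
            "converged": self.converged,
            "n_starts_used": self.n_starts_used,
            "best_start_index": self.best_start_index,
            "objective": self.objective,
            "objective_value": self.objective_value,
            "warnings": list(self.warnings),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def bic(fit: FitResult) -> float:
    """BIC of a fitted result (k*ln(N) - 2*ln(L))."""
    return bic_score(fit.n_free_params, fit.n_obs, fit.log_likelihood)


# ---------------------------------------------------------------------------
# objective functions


def _validate_errors(errors) -> np.ndarray:
    e = np.asarray(errors, dtype=float).ravel()
    if e.size == 0:
        raise ValueError("no observations supplied")
    if not np.all(np.isfinite(e)):
        raise ValueError("errors must be finite")
    if np.any(e <= SUPPORT[0]) or np.any(e > SUPPORT[1]):
        raise ValueError("errors must lie in (-180, 180]")
    return e


def neg_log_likelihood(
    spec: MixtureSpec, errors, clip_mode: ClipMode = "truncated_renormalized"
) -> float:
    """Negative log-likelihood (nats) of errors under the mixture.

    Returns +inf when some observation has zero density (possible only when
    the uniform weight is zero), which fitting treats as a rejected state.
    """
    _check_clip_mode(clip_mode)
    e = _validate_errors(errors)
    mu = np.array([c.mu for c in spec.components])
    sigma = np.array([c.sigma for c in spec.components])
    w = np.array([c.weight for c in spec.components])
    dens = _pdf_arrays(mu, sigma, w, spec.uniform_weight, e, clip_mode)
    if np.any(dens <= 0.0):
        return math.inf
    if clip_mode == "plain":
        dens = np.maximum(dens, _DENSITY_FLOOR)
    return float(-np.sum(np.log(dens)))


# ---------------------------------------------------------------------------
# unconstrained parameterisation


def _unpack(theta: np.ndarray, n: int, opts: FitOptions):
    """theta -> (mu, sigma, component weights, uniform weight)."""
    lo, hi = np.log(opts.sigma_bounds[0]), np.log(opts.sigma_bounds[1])
    if opts.fix_means_at_zero:
        mu = np.zeros(n)
        z_sigma = theta[:n]
        l_w = theta[n:]
    else:
        mu = theta[:n]
        z_sigma = theta[n : 2 * n]
        l_w = theta[2 * n :]
    sigma = np.exp(lo + (hi - lo) * expit(z_sigma))
    logits = np.concatenate([l_w, [0.0]])
    logits = logits - logits.max()
    ew = np.exp(logits)
    wts = ew / ew.sum()
    floor = opts.min_component_weight
    if floor > 0.0:
        # weight floor: rules out degenerate spike/absorbed components
        wts = floor + (1.0 - floor * (n + 1)) * wts
    return mu, sigma, wts[:n], wts[n]


def _pack(spec: MixtureSpec, opts: FitOptions) -> np.ndarray:
    """Invert _unpack for a warm start (clipped into the open transforms)."""
    n = opts.n_components
    if spec.n_components != n:
        raise ValueError("spec component count does not match options")
    lo, hi = np.log(opts.sigma_bounds[0]), np.log(opts.sigma_bounds[1])
    sig = np.clip(
        np.array([c.sigma for c in spec.components]),
        opts.sigma_bounds[0] * 1.0001,
        opts.sigma_bounds[1] * 0.9999,
    )
    z_sigma = logit((np.log(sig) - lo) / (hi - lo))
    floor = opts.min_component_weight
    w = np.array([c.weight for c in spec.components])
    uw = spec.uniform_weight
    if floor > 0.0:
        scale = 1.0 - floor * (n + 2)  # keep inverted weights strictly above floor
        w = floor + scale * w
        uw = floor + scale * uw
    uw = max(uw, 1e-8)
    l_w = np.log(np.maximum(w, 1e-8) / uw)
    if opts.fix_means_at_zero:
        return np.concatenate([z_sigma, l_w])
    mu = np.array([c.mu for c in spec.components])
    return np.concatenate([mu, z_sigma, l_w])


def _spec_from_theta(theta: np.ndarray, opts: FitOptions) -> MixtureSpec:
    mu, sigma, w, uw = _unpack(theta, opts.n_components, opts)
    total = w.sum() + uw
    comps = tuple(
        GaussianComponent(float(m), float(s), float(x / total))
        for m, s, x in zip(mu, sigma, w)
    )
    return MixtureSpec(comps, float(uw / total))


def _initial_starts(
    e: np.ndarray, opts: FitOptions, extra_starts: Sequence[MixtureSpec]
) -> list[np.ndarray]:
    """Moment-based start, warm starts, then stratified random starts."""
    n = opts.n_components
    rng = np.random.default_rng(opts.seed)
    starts: list[np.ndarray] = []

    # deterministic moment start: a ladder of SDs around the sample spread,
    # equal weights, modest guess rate
    s = float(np.clip(np.std(e), 2.0, 90.0))
    ladder = s * np.geomspace(0.5, 2.0, n) if n > 1 else np.array([s])
    ladder = np.clip(ladder, opts.sigma_bounds[0] * 1.01, opts.sigma_bounds[1] * 0.99)
    comps = tuple(
        GaussianComponent(0.0, float(x), 0.8 / n) for x in np.sort(ladder)
    )
    starts.append(_pack(MixtureSpec(comps, 0.2), opts))

    for spec in extra_starts:
        starts.append(_pack(spec, opts))

    while len(starts) < opts.n_starts:
        sig = np.sort(rng.uniform(np.log(2.0), np.log(90.0), n))
        sig = np.exp(sig)
        wts = rng.dirichlet(np.ones(n + 1))
        comps = tuple(
            GaussianComponent(
                0.0 if opts.fix_means_at_zero else float(rng.normal(0.0, 10.0)),
                float(s_),
                float(w_),
            )
            for s_, w_ in zip(sig, np.maximum(wts[:n], 1e-4))
        )
        total = sum(c.weight for c in comps) + max(wts[n], 1e-4)
        comps = tuple(
            GaussianComponent(c.mu, c.sigma, c.weight / total) for c in comps
        )
        starts.append(_pack(MixtureSpec(comps, max(wts[n], 1e-4) / total), opts))
    return starts[: max(opts.n_starts, len(starts))]


def _run_fit(errors, opts: FitOptions, extra_starts: Sequence[MixtureSpec]):
    e = _validate_errors(errors)
    n = opts.n_components
    if e.size < 10 * opts.n_free_params:
        warn = (
            f"only {e.size} observations for {opts.n_free_params} free "
            "parameters; estimates may be unstable",
        )
    else:
        warn = ()

    sorted_e = np.sort(e)
    ecdf = (np.arange(1, e.size + 1) - 0.5) / e.size

    def nll_of(theta: np.ndarray) -> float:
        mu, sigma, w, uw = _unpack(theta, n, opts)
        dens = _pdf_arrays(mu, sigma, w, uw, e, opts.clip_mode)
        if np.any(dens <= 0.0):
            return math.inf
        if opts.clip_mode == "plain":
            dens = np.maximum(dens, _DENSITY_FLOOR)
        return float(-np.sum(np.log(dens)))

    def cdf_sse_of(theta: np.ndarray) -> float:
        mu, sigma, w, uw = _unpack(theta, n, opts)
        model = _cdf_arrays(mu, sigma, w, uw, sorted_e, opts.clip_mode)
        if opts.clip_mode == "plain":
            # plain-mode CDF may not reach 1; compare on the raw scale anyway
            pass
        r = model - ecdf
        return float(r @ r)

    objective = nll_of if opts.objective == "max_likelihood" else cdf_sse_of

    starts = _initial_starts(e, opts, extra_starts)
    best_val = math.inf
    best_theta = starts[0]
    best_idx = 0
    best_success = False
    trace: list[float] = []
    for i, theta0 in enumerate(starts):
        res = minimize(
            objective,
            theta0,
            method="Nelder-Mead",
            options={
                "maxiter": opts.max_iterations,
                "xatol": 1e-6,
                "fatol": opts.convergence_tolerance,
            },
        )
        trace.append(float(res.fun))
        if res.fun < best_val:
            best_val = float(res.fun)
            best_theta = res.x
            best_idx = i
            best_success = bool(res.success)

    spec = _spec_from_theta(best_theta, opts)
    warns = list(warn)
    if any(c.sigma <= opts.sigma_bounds[0] * 1.02 for c in spec.components):
        warns.append("a component SD is pinned at the lower bound (degenerate data?)")
    ll = -neg_log_likelihood(spec, e, opts.clip_mode)
    return FitResult(
        spec=spec,
        log_likelihood=ll,
        n_obs=int(e.size),
        n_free_params=opts.n_free_params,
        bic=bic_score(opts.n_free_params, int(e.size), ll),
        converged=best_success,
        n_starts_used=len(starts),
        best_start_index=best_idx,
        objective=opts.objective,
        objective_value=best_val,
        warnings=tuple(warns),
        objective_value_trace=tuple(trace),
    )


def fit_mixture(
    errors,
    opts: FitOptions,
    extra_starts: Sequence[MixtureSpec] = (),
) -> FitResult:
    """Fit an n-Gaussian + uniform mixture by the configured objective.

    ``extra_starts`` are additional warm-start specs (same component count)
    appended after the deterministic moment-based start; the total number of
    starts never drops below ``opts.n_starts``.  Deterministic given
    identical data, options and seed.
    """
    if opts.objective != "max_likelihood":
        opts = replace(opts, objective="max_likelihood")
    return _run_fit(errors, opts, extra_starts)


def fit_cdf_least_squares(
    errors,
    opts: FitOptions,
    extra_starts: Sequence[MixtureSpec] = (),
) -> FitResult:
    """Fit by least squares between the model and empirical CDFs.

    The empirical CDF uses Hazen plotting positions (i - 0.5)/N at the
    sorted sample.  The log-likelihood is still evaluated at the optimum so
    the result remains BIC-comparable with ML fits.
    """
    opts = replace(opts, objective="cdf_least_squares")
    return _run_fit(errors, opts, extra_starts)


# ---------------------------------------------------------------------------
# model comparison


@dataclass(frozen=True)
class ModelComparison:
    """Per-n fit results with BIC winner and runner-up.

    ``delta_bic`` maps each fitted n to its BIC minus the winner's BIC
    (0 for the winner).  Ties are broken toward smaller n (parsimony).
    """

    results: Mapping[int, FitResult]
    winner: int
    runner_up: int | None
    delta_bic: Mapping[int, float]
    failed: tuple[int, ...] = ()

    def to_dict(self) -> dict:
        return {
            "results": {str(n): r.to_dict() for n, r in self.results.items()},
            "winner": self.winner,
            "runner_up": self.runner_up,
            "delta_bic": {str(n): v for n, v in self.delta_bic.items()},
            "failed": list(self.failed),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)


def _embed_spec(spec: MixtureSpec, opts: FitOptions) -> MixtureSpec:
    """Embed an (n-1)-component spec as an n-component warm start."""
    eps = 1e-3
    widest = max((c.sigma for c in spec.components), default=20.0)
    extra_sigma = min(widest * 1.5, opts.sigma_bounds[1] * 0.9)
    scale = 1.0 - eps
    comps = [
        GaussianComponent(c.mu, c.sigma, c.weight * scale) for c in spec.components
    ]
    comps.append(GaussianComponent(0.0, extra_sigma, eps))
    return MixtureSpec(tuple(comps), spec.uniform_weight * scale)


def compare_models(
    errors,
    base_opts: FitOptions,
    n_list: Sequence[int] = (1, 2, 3, 4, 5),
) -> ModelComparison:
    """Fit each candidate n and rank by BIC (smallest wins).

    All fits share ``base_opts`` except ``n_components``; per-n seeds are
    derived deterministically from the base seed.  Fits for larger n are
    additionally warm-started from the previous best fit embedded with a
    near-zero-weight extra component.  A candidate whose fit raises is
    recorded in ``failed`` and excluded from the ranking.
    """
    n_list = sorted(set(int(n) for n in n_list))
    if not n_list:
        raise ValueError("n_list must be nonempty")
    results: dict[int, FitResult] = {}
    failed: list[int] = []
    prev_spec: MixtureSpec | None = None
    for n in n_list:
        opts = replace(base_opts, n_components=n, seed=base_opts.seed * 100 + n)
        extra: list[MixtureSpec] = []
        if prev_spec is not None and prev_spec.n_components == n - 1:
            extra.append(_embed_spec(prev_spec, opts))
        try:
            fit = _run_fit(errors, opts, extra)
        except ValueError:
            raise
        except Exception as exc:  # numerical failure of one candidate
            warnings.warn(f"fit for n={n} failed: {exc}")
            failed.append(n)
            continue
        results[n] = fit
        prev_spec = fit.spec
    if not results:
        raise RuntimeError("all candidate fits failed")
    order = sorted(results, key=lambda n: (results[n].bic, n))
    winner = order[0]
    runner_up = order[1] if len(order) > 1 else None
    wb = results[winner].bic
    delta = {n: results[n].bic - wb for n in results}
    return ModelComparison(
        results=results,
        winner=winner,
        runner_up=runner_up,
        delta_bic=delta,
        failed=tuple(failed),
    )
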