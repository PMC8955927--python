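"""Gaussian + uniform mixtures on the bounded report-error domain.

Continuous-report experiments record, on every trial, a signed angular
error between a presented feature (here a direction of motion) and the
observer's report.  Errors live on the half-open interval (-180, 180]
degrees.  The standard descriptive model for such data is a finite mixture
of Gaussian components — reports driven by stored information, each with an
accuracy ``mu``, a precision ``1/sigma`` and an intake weight — plus a
uniform component modelling guesses made with no stored information.

This module provides the mixture types, their densities, distribution and
quantile functions, the Gaussian convolution identity used to collapse
sequential processing stages into a single component, and small utilities
(error wrapping, the transformed-performance score).

Two density conventions are supported, selected by ``clip_mode``:

``"truncated_renormalized"`` (default)
    each Gaussian is divided by its probability mass on [-180, 180], so the
    mixture integrates to exactly 1 on the support and log-likelihoods are
    proper.  This is the mode used for fitting and BIC.
``"plain"``
    unnormalized Gaussian tails are allowed to spill past +/-180.  For
    component SDs up to ~30 deg the spilled mass is negligible and the two
    modes agree; the plain mode is kept for diagnostics against analyses
    that ignore clipping.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
from scipy.optimize import brentq
from scipy.special import ndtr

__all__ = [
    "SUPPORT",
    "ClipMode",
    "GaussianComponent",
    "MixtureSpec",
    "TrialRecord",
    "convolve_gaussians",
    "mixture_cdf",
    "mixture_pdf",
    "mixture_quantile",
    "sample_mixture",
    "transform_performance",
    "wrap_error",
]

#: Fixed error-angle support in degrees, half-open (-180, 180].
SUPPORT: tuple[float, float] = (-180.0, 180.0)

_SUPPORT_WIDTH = SUPPORT[1] - SUPPORT[0]

ClipMode = Literal["plain", "truncated_renormalized"]

_CLIP_MODES = ("plain", "truncated_renormalized")

_REPORT_CONDITIONS = ("SR", "FR1", "FR_other", "pre_SR", "pre_FR")
_EXPERIMENTS = ("set_size", "cue_delay")


def wrap_error(angle_deg):
    """Wrap an angle (degrees) onto the half-open interval (-180, 180].

    Accepts scalars or arrays.  -180 maps to +180 so that a report exactly
    opposite the target has a unique representation.
    """
    a = np.asarray(angle_deg, dtype=float)
    if not np.all(np.isfinite(a)):
        raise ValueError("angle must be finite")
    w = np.mod(a, 360.0)
    w = np.where(w > 180.0, w - 360.0, w)
    # mod may return exactly -0.0 patterns; map the 180/-180 seam upward
    w = np.where(w == -180.0, 180.0, w)
    if np.isscalar(angle_deg) or np.ndim(angle_deg) == 0:
        return float(w)
    return w


def transform_performance(error_deg):
    """Transformed performance TP = 1 - |error|/180.

    A bounded, probability-like score of single-trial report quality: 1 for
    a perfect report, 0 for a report 180 deg off, and 0.5 on average under
    uniform guessing (chance level).  Input must lie in [-180, 180].
    """
    e = np.asarray(error_deg, dtype=float)
    if not np.all(np.isfinite(e)):
        raise ValueError("error angle must be finite")
    if np.any(np.abs(e) > 180.0):
        raise ValueError("error angle must lie in [-180, 180] degrees")
    tp = 1.0 - np.abs(e) / 180.0
    if np.isscalar(error_deg) or np.ndim(error_deg) == 0:
        return float(tp)
    return tp


@dataclass(frozen=True)
class TrialRecord:
    """One behavioural observation: condition labels plus the report error.

    ``hidden_route`` is only populated by the synthetic-data generator and
    records which mixture route produced the trial; it is ground truth that
    real data never carry.
    """

    subject_id: str
    experiment: str  # "set_size" | "cue_delay"
    report_condition: str  # "SR" | "FR1" | "FR_other" | "pre_SR" | "pre_FR"
    set_size: int
    cue_delay_ms: float
    error_deg: float
    hidden_route: str | None = None

    def __post_init__(self) -> None:
        if self.experiment not in _EXPERIMENTS:
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.report_condition not in _REPORT_CONDITIONS:
            raise ValueError(f"unknown report condition {self.report_condition!r}")
        if self.set_size < 1:
            raise ValueError("set_size must be >= 1")
        if self.cue_delay_ms < 0:
            raise ValueError("cue_delay_ms must be >= 0")
        if not (-180.0 < self.error_deg <= 180.0):
            raise ValueError("error_deg must lie in (-180, 180]")


@dataclass(frozen=True)
class GaussianComponent:
    """A Gaussian mixture component: accuracy mu, SD sigma, intake weight."""

    mu: float
    sigma: float
    weight: float

    def __post_init__(self) -> None:
        if not math.isfinite(self.mu):
            raise ValueError("mu must be finite")
        if not (self.sigma > 0 and math.isfinite(self.sigma)):
            raise ValueError("sigma must be positive and finite")
        if not (0.0 <= self.weight <= 1.0):
            raise ValueError("weight must lie in [0, 1]")

    @property
    def precision(self) -> float:
        """Reciprocal SD, 1/sigma, in 1/degrees."""
        return 1.0 / self.sigma


@dataclass(frozen=True)
class MixtureSpec:
    """An n-Gaussian + uniform mixture on (-180, 180] degrees.

    Components are stored sorted by sigma ascending (Sigma1 = narrowest),
    which fixes the component labelling and resolves mixture label
    switching.  Weights plus ``uniform_weight`` must sum to 1.
    """

    components: tuple[GaussianComponent, ...]
    uniform_weight: float
    support: tuple[float, float] = SUPPORT

    def __post_init__(self) -> None:
        comps = tuple(sorted(self.components, key=lambda c: c.sigma))
        object.__setattr__(self, "components", comps)
        if len(comps) > 5:
            raise ValueError("at most 5 Gaussian components are supported")
        if not (0.0 <= self.uniform_weight <= 1.0):
            raise ValueError("uniform_weight must lie in [0, 1]")
        total = sum(c.weight for c in comps) + self.uniform_weight
        if abs(total - 1.0) > 1e-9:
            raise ValueError(f"weights must sum to 1 (got {total!r})")
        if tuple(self.support) != SUPPORT:
            raise ValueError("support is fixed at (-180, 180]")

    @property
    def n_components(self) -> int:
        return len(self.components)

    @property
    def intake(self) -> float:
        """Total Gaussian weight: the proportion of informed responses."""
        return float(sum(c.weight for c in self.components))

    @property
    def guess_rate(self) -> float:
        return float(self.uniform_weight)

    # -- serialization ----------------------------------------------------
    def to_dict(self) -> dict:
        return {
            "components": [
                {"mu": c.mu, "sigma": c.sigma, "weight": c.weight}
                for c in self.components
            ],
            "uniform_weight": self.uniform_weight,
            "support": list(self.support),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "MixtureSpec":
        comps = tuple(
            GaussianComponent(c["mu"], c["sigma"], c["weight"])
            for c in d["components"]
        )
        return cls(comps, d["uniform_weight"])

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), sort_keys=True)

    @classmethod
    def from_json(cls, s: str) -> "MixtureSpec":
        return cls.from_dict(json.loads(s))


def convolve_gaussians(
    g1: GaussianComponent, g2: GaussianComponent
) -> GaussianComponent:
    """Convolution of two Gaussians: means add, variances add, weights multiply.

    This is the identity that collapses sequential processing stages (e.g.
    sensory-memory noise followed by short-term-memory noise) into a single
    Gaussian component.  On a bounded domain it is exact only up to the
    clipped tail mass, which is negligible while SDs stay well below the
    half-width of the support.
    """
    return GaussianComponent(
        mu=g1.mu + g2.mu,
        sigma=math.hypot(g1.sigma, g2.sigma),
        weight=g1.weight * g2.weight,
    )


# ---------------------------------------------------------------------------
# densities — array kernels shared with the fitting module


def _check_clip_mode(clip_mode: str) -> None:
    if clip_mode not in _CLIP_MODES:
        raise ValueError(f"clip_mode must be one of {_CLIP_MODES}")


def _trunc_mass(mu: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Gaussian probability mass on [-180, 180] for each (mu, sigma)."""
    lo = (SUPPORT[0] - mu) / sigma
    hi = (SUPPORT[1] - mu) / sigma
    return ndtr(hi) - ndtr(lo)


def _pdf_arrays(mu, sigma, w, uniform_weight, x, clip_mode):
    """Mixture pdf evaluated at x for component arrays (internal kernel)."""
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    dens = np.full(x.shape, uniform_weight / _SUPPORT_WIDTH)
    if mu.size:
        z = (x[..., None] - mu) / sigma
        g = np.exp(-0.5 * z * z) / (sigma * math.sqrt(2.0 * math.pi))
        if clip_mode == "truncated_renormalized":
            g = g / _trunc_mass(mu, sigma)
        dens = dens + g @ w
    return dens


def _cdf_arrays(mu, sigma, w, uniform_weight, x, clip_mode):
    mu = np.asarray(mu, float)
    sigma = np.asarray(sigma, float)
    w = np.asarray(w, float)
    x = np.asarray(x, float)
    cdf = uniform_weight * (x - SUPPORT[0]) / _SUPPORT_WIDTH
    if mu.size:
        z = (x[..., None] - mu) / sigma
        z_lo = (SUPPORT[0] - mu) / sigma
        g = ndtr(z) - ndtr(z_lo)
        if clip_mode == "truncated_renormalized":
            g = g / _trunc_mass(mu, sigma)
        cdf = cdf + g @ w
    return cdf


def _spec_arrays(spec: MixtureSpec):
    mu = np.array([c.mu for c in spec.components])
    sigma = np.array([c.sigma for c in spec.components])
    w = np.array([c.weight for c in spec.components])
    return mu, sigma, w


def mixture_pdf(
    spec: MixtureSpec, error_deg, clip_mode: ClipMode = "truncated_renormalized"
):
    """Mixture probability density (per degree) at the given error angle(s).

    Under ``truncated_renormalized`` the density integrates to 1 over
    (-180, 180]; under ``plain`` Gaussian tails beyond the support are not
    renormalized.
    """
    _check_clip_mode(clip_mode)
    mu, sigma, w = _spec_arrays(spec)
    x = np.asarray(error_deg, float)
    out = _pdf_arrays(mu, sigma, w, spec.uniform_weight, x, clip_mode)
    if np.isscalar(error_deg) or np.ndim(error_deg) == 0:
        return float(out)
    return out


def mixture_cdf(
    spec: MixtureSpec, error_deg, clip_mode: ClipMode = "truncated_renormalized"
):
    """Mixture distribution function on the support, F(-180) = 0.

    Under ``truncated_renormalized``, F(180) = 1 exactly.
    """
    _check_clip_mode(clip_mode)
    mu, sigma, w = _spec_arrays(spec)
    x = np.asarray(error_deg, float)
    out = _cdf_arrays(mu, sigma, w, spec.uniform_weight, x, clip_mode)
    if np.isscalar(error_deg) or np.ndim(error_deg) == 0:
        return float(out)
    return out


def mixture_quantile(
    spec: MixtureSpec, q, clip_mode: ClipMode = "truncated_renormalized"
):
    """Inverse of :func:`mixture_cdf` by bracketing root search."""
    _check_clip_mode(clip_mode)

    def _one(p: float) -> float:
        if not (0.0 < p < 1.0):
            raise ValueError("quantile level must lie strictly in (0, 1)")
        return brentq(
            lambda x: mixture_cdf(spec, x, clip_mode) - p,
            SUPPORT[0],
            SUPPORT[1],
            xtol=1e-10,
        )

    if np.isscalar(q) or np.ndim(q) == 0:
        return _one(float(q))
    return np.array([_one(float(p)) for p in np.asarray(q, float)])


def sample_mixture(spec: MixtureSpec, n: int, rng: np.random.Generator) -> np.ndarray:
    """Draw n errors from the mixture; Gaussian draws are wrapped onto the support.

    For component SDs well below 90 deg wrapping is indistinguishable from
    truncation; the generator and the fitted density then agree.
    """
    weights = [c.weight for c in spec.components] + [spec.uniform_weight]
    route = rng.choice(len(weights), size=n, p=weights)
    out = np.empty(n)
    for i, comp in enumerate(spec.components):
        m = route == i
        out[m] = rng.normal(comp.mu, comp.sigma, m.sum())
    m = route == len(spec.components)
    out[m] = rng.uniform(SUPPORT[0], SUPPORT[1], m.sum())
    return wrap_error(out)
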