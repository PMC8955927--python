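"""Block-diagram memory models and their reduction to mixture form.

Four architectures for how a reported motion direction is produced, each a
chain (or parallel set of chains) of noisy processing stages plus a uniform
guessing route:

* Model A — a single lumped memory stage: one Gaussian + uniform.
* Model B — sensory memory (SM) feeding short-term memory (STM) in series;
  the convolution of the two stage Gaussians is again a Gaussian, so this
  is still one Gaussian + uniform.
* Model C — an attention stage in parallel with (post-attentive relative
  to) SM, both feeding STM: two Gaussians + uniform with weights
  ``w1*w2`` (SM route), ``w1*(1-w2)`` (attention route) and ``1-w1``
  (guessing).  Only the SM-routed component inherits the time-dependent
  SM SD, so exactly one component SD grows with cue delay — the Model C
  signature.
* Model D — two parallel SM->STM chains (nonselective vs selective
  transfer) with weights ``w1`` and ``w2`` and guessing ``1-w1-w2``.  Both
  chains pass through SM, so with active decay both component SDs grow
  with cue delay — the Model D signature.

SM decay is parameterised by :class:`DecayLaw`: the SM stage SD is a
nondecreasing function of cue delay, reflecting the rapid loss of quality
of unattended sensory traces over the first second or so.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Literal, Sequence, Union

from .mixtures import GaussianComponent, MixtureSpec, convolve_gaussians

__all__ = [
    "DecayLaw",
    "ModelCParams",
    "ModelDParams",
    "reduce_model_a_b",
    "reduce_model_c",
    "reduce_model_d",
]

_ZERO_WEIGHT = 1e-12


@dataclass(frozen=True)
class DecayLaw:
    """SD of the sensory-memory stage as a nondecreasing function of delay.

    Forms:

    * ``constant`` — sigma(t) = sigma0 (sigma_inf ignored).
    * ``linear_saturating`` — sigma rises linearly from sigma0, reaching
      sigma_inf at t = tau and saturating there.
    * ``exponential_approach`` — sigma(t) = sigma_inf -
      (sigma_inf - sigma0) * exp(-t / tau); the default generator form, a
      saturating approach matching the flattening of empirical decay
      curves at long delays.

    Units: sigma0, sigma_inf in degrees; tau in milliseconds.
    """

    form: Literal["constant", "linear_saturating", "exponential_approach"]
    sigma0: float
    sigma_inf: float | None = None
    tau: float | None = None

    def __post_init__(self) -> None:
        if self.sigma0 <= 0:
            raise ValueError("sigma0 must be positive")
        if self.form == "constant":
            return
        if self.form not in ("linear_saturating", "exponential_approach"):
            raise ValueError(f"unknown decay form {self.form!r}")
        if self.sigma_inf is None or self.tau is None:
            raise ValueError(f"{self.form} decay requires sigma_inf and tau")
        if self.sigma_inf < self.sigma0:
            raise ValueError("sigma_inf must be >= sigma0")
        if self.tau <= 0:
            raise ValueError("tau must be positive")

    def sigma_at(self, t_ms: float) -> float:
        """Evaluate the SM SD (degrees) at cue delay t (ms)."""
        if t_ms < 0:
            raise ValueError("delay must be nonnegative")
        if self.form == "constant":
            return self.sigma0
        if self.form == "linear_saturating":
            return min(
                self.sigma0 + (self.sigma_inf - self.sigma0) * t_ms / self.tau,
                self.sigma_inf,
            )
        return self.sigma_inf - (self.sigma_inf - self.sigma0) * math.exp(
            -t_ms / self.tau
        )


@dataclass(frozen=True)
class ModelCParams:
    """Generative parameters for Model C (SM + attention + STM + guessing).

    ``omega1`` is the non-guess rate; ``omega2`` the fraction of informed
    responses routed through SM (the remainder go through attention).  Stage
    means are accuracies in degrees; stage SDs in degrees.  The SM SD at
    delay t is ``sm_decay.sigma_at(t)``.
    """

    omega1: float
    omega2: float
    sm_decay: DecayLaw
    sigma_attention: float
    sigma_stm: float
    mu_sm: float = 0.0
    mu_attention: float = 0.0
    mu_stm: float = 0.0

    def __post_init__(self) -> None:
        for name in ("omega1", "omega2"):
            v = getattr(self, name)
            if not (0.0 <= v <= 1.0):
                raise ValueError(f"{name} must lie in [0, 1]")
        if self.sigma_attention <= 0 or self.sigma_stm <= 0:
            raise ValueError("stage SDs must be positive")

    @property
    def sigma_sm0(self) -> float:
        """SM SD at zero delay."""
        return self.sm_decay.sigma0


@dataclass(frozen=True)
class ModelDParams:
    """Generative parameters for Model D (two parallel SM->STM routes).

    Route 1 carries weight ``omega1`` (nonselective transfer), route 2
    ``omega2`` (selective transfer); guessing has weight 1 - omega1 -
    omega2.  Each route has its own SM decay law and STM stage; passing the
    same DecayLaw object shares the decay between routes.
    """

    omega1: float
    omega2: float
    sm_decay1: DecayLaw
    sigma_stm1: float
    sm_decay2: DecayLaw
    sigma_stm2: float
    mu_sm1: float = 0.0
    mu_stm1: float = 0.0
    mu_sm2: float = 0.0
    mu_stm2: float = 0.0

    def __post_init__(self) -> None:
        if not (0.0 <= self.omega1 <= 1.0 and 0.0 <= self.omega2 <= 1.0):
            raise ValueError("route weights must lie in [0, 1]")
        if self.omega1 + self.omega2 > 1.0 + 1e-12:
            raise ValueError("omega1 + omega2 must not exceed 1")
        if self.sigma_stm1 <= 0 or self.sigma_stm2 <= 0:
            raise ValueError("STM SDs must be positive")


def _build_spec(components: Sequence[GaussianComponent], uniform_weight: float
                ) -> MixtureSpec:
    """Drop zero-weight components, merge identical ones, build the spec."""
    kept: list[GaussianComponent] = []
    for c in components:
        if c.weight <= _ZERO_WEIGHT:
            continue
        for i, k in enumerate(kept):
            if k.mu == c.mu and k.sigma == c.sigma:
                kept[i] = GaussianComponent(k.mu, k.sigma, k.weight + c.weight)
                break
        else:
            kept.append(c)
    return MixtureSpec(tuple(kept), uniform_weight)


def reduce_model_a_b(
    memory: Union[GaussianComponent, tuple[GaussianComponent, GaussianComponent]],
    omega: float,
) -> MixtureSpec:
    """Reduce Model A (single stage) or Model B (SM then STM) to mixture form.

    ``memory`` is either a single stage Gaussian (Model A) or the (SM, STM)
    stage pair (Model B), in which case the stages are convolved.  The
    result is a one-Gaussian + uniform spec with Gaussian weight ``omega``.
    """
    if not (0.0 <= omega <= 1.0):
        raise ValueError("omega must lie in [0, 1]")
    if isinstance(memory, GaussianComponent):
        g = memory
    else:
        sm, stm = memory
        g = convolve_gaussians(sm, stm)
    g = GaussianComponent(g.mu, g.sigma, omega)
    return _build_spec([g], 1.0 - omega)


def reduce_model_c(p: ModelCParams, t_ms: float) -> MixtureSpec:
    """Reduce Model C at cue delay t to its two-Gaussian + uniform mixture.

    Component 1 (SM route): mean mu_SM + mu_STM, SD
    sqrt(sigma_SM(t)^2 + sigma_STM^2), weight omega1*omega2.  Component 2
    (attention route): mean mu_att + mu_STM, SD
    sqrt(sigma_att^2 + sigma_STM^2), weight omega1*(1-omega2).  Uniform
    weight 1 - omega1.  Only component 1's SD depends on t.
    """
    sigma_sm = p.sm_decay.sigma_at(t_ms)
    g_sm = GaussianComponent(
        p.mu_sm + p.mu_stm,
        math.hypot(sigma_sm, p.sigma_stm),
        p.omega1 * p.omega2,
    )
    g_att = GaussianComponent(
        p.mu_attention + p.mu_stm,
        math.hypot(p.sigma_attention, p.sigma_stm),
        p.omega1 * (1.0 - p.omega2),
    )
    return _build_spec([g_sm, g_att], 1.0 - p.omega1)


def reduce_model_d(p: ModelDParams, t_ms: float) -> MixtureSpec:
    """Reduce Model D at cue delay t to its two-Gaussian + uniform mixture.

    Route i contributes a Gaussian with mean mu_SMi + mu_STMi, SD
    sqrt(sigma_SMi(t)^2 + sigma_STMi^2) and weight omega_i; the uniform
    weight is 1 - omega1 - omega2.  Both SDs inherit the SM decay, so both
    grow with t when decay is active.
    """
    g1 = GaussianComponent(
        p.mu_sm1 + p.mu_stm1,
        math.hypot(p.sm_decay1.sigma_at(t_ms), p.sigma_stm1),
        p.omega1,
    )
    g2 = GaussianComponent(
        p.mu_sm2 + p.mu_stm2,
        math.hypot(p.sm_decay2.sigma_at(t_ms), p.sigma_stm2),
        p.omega2,
    )
    return _build_spec([g1, g2], 1.0 - p.omega1 - p.omega2)
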