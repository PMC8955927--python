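"""Synthetic trial generator for continuous-report memory experiments.

The behavioural data this package analyses are per-trial report errors from
a modified multiple-object-tracking paradigm: observers report directions
of motion of moving disks, either a single randomly cued disk (SR) or all
disks in free order, of which only the first report (FR1) is modelled.
Two designs are emulated: a set-size experiment (1-4 disks, zero cue
delay) and a cue-delay experiment (set size 3, delays 0-1600 ms).

Errors are generated route-wise from a block-diagram memory model: a route
(sensory memory, attention, guessing, ...) is chosen by the mixture
weights, stage noises are sampled sequentially (e.g. SM noise at the
delay-dependent SD, then STM noise), summed, and wrapped onto (-180, 180].
Per-trial route labels are retained as hidden ground truth.  This is the
generative counterpart of the analytic stage-convolution reductions in
:mod:`reportmix.memory_models`, and agreement between the two is one of
the package's core correctness checks.

Real data differ from this generator in ways it does not attempt to
capture: no misbinding/interference components, no event segmentation, no
response times, and subject heterogeneity reduced to smooth multiplicative
jitter.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Mapping, Sequence

import numpy as np
import pandas as pd

from .memory_models import (
    DecayLaw,
    ModelCParams,
    ModelDParams,
    reduce_model_a_b,
    reduce_model_c,
    reduce_model_d,
)
from .mixtures import SUPPORT, GaussianComponent, MixtureSpec, TrialRecord, wrap_error

__all__ = [
    "ExperimentDesign",
    "GenerativeScenario",
    "default_scenario",
    "emulate_study_dataset",
    "simulate_trials",
    "trials_to_frame",
    "write_trials_csv",
]

TRIAL_COLUMNS = (
    "subject_id",
    "experiment",
    "report_condition",
    "set_size",
    "cue_delay_ms",
    "error_deg",
)


@dataclass(frozen=True)
class ExperimentDesign:
    """Factorial layout of a simulated experiment.

    The set-size experiment crosses set sizes 1-4 at zero cue delay; the
    cue-delay experiment fixes set size 3 and crosses delays
    0/100/200/400/800/1600 ms.  Defaults follow those designs with 5
    subjects and both SR and FR1 report conditions.
    """

    experiment: str  # "set_size" | "cue_delay"
    set_sizes: tuple[int, ...] = (1, 2, 3, 4)
    cue_delays_ms: tuple[float, ...] = (0.0, 100.0, 200.0, 400.0, 800.0, 1600.0)
    trials_per_cell: int = 300
    subjects: int = 5
    report_conditions: tuple[str, ...] = ("SR", "FR1")
    seed: int = 0

    def __post_init__(self) -> None:
        if self.experiment not in ("set_size", "cue_delay"):
            raise ValueError(f"unknown experiment {self.experiment!r}")
        if self.trials_per_cell < 1:
            raise ValueError("trials_per_cell must be >= 1")
        if any(d < 0 for d in self.cue_delays_ms):
            raise ValueError("cue delays must be nonnegative")
        if self.subjects < 1:
            raise ValueError("need at least one subject")

    def cells(self):
        """Yield (set_size, cue_delay_ms) design cells."""
        if self.experiment == "set_size":
            for s in self.set_sizes:
                yield int(s), 0.0
        else:
            for d in self.cue_delays_ms:
                yield 3, float(d)


@dataclass(frozen=True)
class GenerativeScenario:
    """Generative truth for a simulation run.

    ``params`` holds the base block-diagram parameters; for models A/B a
    dict ``{"memory": GaussianComponent | (sm, stm) pair, "omega": float}``
    is expected.  ``condition_params`` optionally overrides the base
    parameters per report condition (SR vs FR1 differ in how much of the
    informed traffic is routed through decaying sensory memory).
    ``set_size_effects`` maps set size -> overrides applied on top
    (keys: ``omega1``, ``omega2``, ``sigma_scale``).  Subject heterogeneity
    is log-normal multiplicative jitter on stage SDs and additive jitter on
    weight logits.
    """

    model: str  # "A" | "B" | "C" | "D"
    params: object
    condition_params: Mapping[str, object] = field(default_factory=dict)
    set_size_effects: Mapping[int, Mapping[str, float]] = field(default_factory=dict)
    sigma_jitter_sd: float = 0.10  # SD of log-normal multiplier on stage SDs
    weight_logit_jitter_sd: float = 0.20  # SD of additive jitter on logit weights

    def __post_init__(self) -> None:
        if self.model not in ("A", "B", "C", "D"):
            raise ValueError(f"unknown model {self.model!r}")


def _jitter_weight(w: float, shift: float) -> float:
    if w <= 0.0 or w >= 1.0:
        return w
    return float(1.0 / (1.0 + math.exp(-(math.log(w / (1.0 - w)) + shift))))


def _cell_params_c(
    base: ModelCParams,
    effects: Mapping[str, float],
    sig_mult: float,
    w_shift: tuple[float, float],
) -> ModelCParams:
    omega1 = _jitter_weight(float(effects.get("omega1", base.omega1)), w_shift[0])
    omega2 = _jitter_weight(float(effects.get("omega2", base.omega2)), w_shift[1])
    scale = float(effects.get("sigma_scale", 1.0)) * sig_mult
    decay = base.sm_decay
    decay = replace(
        decay,
        sigma0=decay.sigma0 * scale,
        sigma_inf=None if decay.sigma_inf is None else decay.sigma_inf * scale,
    )
    return replace(
        base,
        omega1=omega1,
        omega2=omega2,
        sm_decay=decay,
        sigma_attention=base.sigma_attention * scale,
        sigma_stm=base.sigma_stm * scale,
    )


def _cell_params_d(
    base: ModelDParams,
    effects: Mapping[str, float],
    sig_mult: float,
    w_shift: tuple[float, float],
) -> ModelDParams:
    omega1 = _jitter_weight(float(effects.get("omega1", base.omega1)), w_shift[0])
    omega2 = _jitter_weight(float(effects.get("omega2", base.omega2)), w_shift[1])
    if omega1 + omega2 > 0.999:
        norm = 0.999 / (omega1 + omega2)
        omega1, omega2 = omega1 * norm, omega2 * norm
    scale = float(effects.get("sigma_scale", 1.0)) * sig_mult

    def _scale_decay(d: DecayLaw) -> DecayLaw:
        return replace(
            d,
            sigma0=d.sigma0 * scale,
            sigma_inf=None if d.sigma_inf is None else d.sigma_inf * scale,
        )

    return replace(
        base,
        omega1=omega1,
        omega2=omega2,
        sm_decay1=_scale_decay(base.sm_decay1),
        sm_decay2=_scale_decay(base.sm_decay2),
        sigma_stm1=base.sigma_stm1 * scale,
        sigma_stm2=base.sigma_stm2 * scale,
    )


def cell_spec(
    scenario: GenerativeScenario,
    condition: str,
    set_size: int,
    cue_delay_ms: float,
    sig_mult: float = 1.0,
    w_shift: tuple[float, float] = (0.0, 0.0),
) -> MixtureSpec:
    """Reduced mixture for one design cell (with optional subject jitter)."""
    params = scenario.condition_params.get(condition, scenario.params)
    effects = scenario.set_size_effects.get(set_size, {})
    if scenario.model == "C":
        p = _cell_params_c(params, effects, sig_mult, w_shift)
        return reduce_model_c(p, cue_delay_ms)
    if scenario.model == "D":
        p = _cell_params_d(params, effects, sig_mult, w_shift)
        return reduce_model_d(p, cue_delay_ms)
    # models A and B: params is {"memory": ..., "omega": ...}
    memory = params["memory"]
    omega = _jitter_weight(float(effects.get("omega1", params["omega"])), w_shift[0])
    scale = float(effects.get("sigma_scale", 1.0)) * sig_mult
    if isinstance(memory, GaussianComponent):
        memory = GaussianComponent(memory.mu, memory.sigma * scale, memory.weight)
    else:
        sm, stm = memory
        memory = (
            GaussianComponent(sm.mu, sm.sigma * scale, sm.weight),
            GaussianComponent(stm.mu, stm.sigma * scale, stm.weight),
        )
    return reduce_model_a_b(memory, omega)


def _sample_cell_c(
    p: ModelCParams, t: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    """Sequential-stage sampling for Model C; returns (errors, route labels)."""
    routes = np.array(["sm", "attention", "guess"])
    probs = [p.omega1 * p.omega2, p.omega1 * (1 - p.omega2), 1 - p.omega1]
    idx = rng.choice(3, size=n, p=probs)
    out = np.empty(n)
    m = idx == 0
    out[m] = rng.normal(p.mu_sm, p.sm_decay.sigma_at(t), m.sum()) + rng.normal(
        p.mu_stm, p.sigma_stm, m.sum()
    )
    m = idx == 1
    out[m] = rng.normal(p.mu_attention, p.sigma_attention, m.sum()) + rng.normal(
        p.mu_stm, p.sigma_stm, m.sum()
    )
    m = idx == 2
    out[m] = rng.uniform(SUPPORT[0], SUPPORT[1], m.sum())
    return wrap_error(out), routes[idx]


def _sample_cell_d(
    p: ModelDParams, t: float, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    routes = np.array(["route1", "route2", "guess"])
    probs = [p.omega1, p.omega2, 1 - p.omega1 - p.omega2]
    probs = [max(x, 0.0) for x in probs]
    total = sum(probs)
    probs = [x / total for x in probs]
    idx = rng.choice(3, size=n, p=probs)
    out = np.empty(n)
    m = idx == 0
    out[m] = rng.normal(p.mu_sm1, p.sm_decay1.sigma_at(t), m.sum()) + rng.normal(
        p.mu_stm1, p.sigma_stm1, m.sum()
    )
    m = idx == 1
    out[m] = rng.normal(p.mu_sm2, p.sm_decay2.sigma_at(t), m.sum()) + rng.normal(
        p.mu_stm2, p.sigma_stm2, m.sum()
    )
    m = idx == 2
    out[m] = rng.uniform(SUPPORT[0], SUPPORT[1], m.sum())
    return wrap_error(out), routes[idx]


def _sample_cell_ab(
    params: Mapping, n: int, rng: np.random.Generator
) -> tuple[np.ndarray, np.ndarray]:
    memory = params["memory"]
    omega = float(params["omega"])
    idx = rng.choice(2, size=n, p=[omega, 1.0 - omega])
    out = np.empty(n)
    m = idx == 0
    if isinstance(memory, GaussianComponent):
        out[m] = rng.normal(memory.mu, memory.sigma, m.sum())
    else:
        sm, stm = memory
        out[m] = rng.normal(sm.mu, sm.sigma, m.sum()) + rng.normal(
            stm.mu, stm.sigma, m.sum()
        )
    m = idx == 1
    out[m] = rng.uniform(SUPPORT[0], SUPPORT[1], m.sum())
    routes = np.array(["memory", "guess"])
    return wrap_error(out), routes[idx]


def simulate_trials(
    design: ExperimentDesign, scenario: GenerativeScenario
) -> list[TrialRecord]:
    """Draw per-trial report errors for every cell of the design.

    Sampling is sequential-stage (route choice, then stage noises, then
    wrapping), not a draw from the reduced mixture, so it also exercises
    the stage-convolution identity.  Fully reproducible from
    ``design.seed``; per-trial route labels are kept in ``hidden_route``.
    """
    # validate every cell spec before any sampling
    for cond in design.report_conditions:
        for set_size, delay in design.cells():
            cell_spec(scenario, cond, set_size, delay)

    ss = np.random.SeedSequence(design.seed)
    subject_seeds = ss.spawn(design.subjects)
    records: list[TrialRecord] = []
    for s_idx, sseed in enumerate(subject_seeds):
        subject_id = f"S{s_idx + 1:02d}"
        jit_rng = np.random.default_rng(sseed.spawn(1)[0])
        sig_mult = float(
            np.exp(jit_rng.normal(0.0, scenario.sigma_jitter_sd))
        )
        w_shift = tuple(jit_rng.normal(0.0, scenario.weight_logit_jitter_sd, 2))
        for c_idx, cond in enumerate(design.report_conditions):
            for cell_idx, (set_size, delay) in enumerate(design.cells()):
                cell_ss = sseed.spawn(1)[0]
                rng = np.random.default_rng(cell_ss)
                params = scenario.condition_params.get(cond, scenario.params)
                effects = scenario.set_size_effects.get(set_size, {})
                n = design.trials_per_cell
                if scenario.model == "C":
                    p = _cell_params_c(params, effects, sig_mult, w_shift)
                    errs, routes = _sample_cell_c(p, delay, n, rng)
                elif scenario.model == "D":
                    p = _cell_params_d(params, effects, sig_mult, w_shift)
                    errs, routes = _sample_cell_d(p, delay, n, rng)
                else:
                    omega = _jitter_weight(
                        float(effects.get("omega1", params["omega"])), w_shift[0]
                    )
                    scale = float(effects.get("sigma_scale", 1.0)) * sig_mult
                    memory = params["memory"]
                    if isinstance(memory, GaussianComponent):
                        mem = GaussianComponent(
                            memory.mu, memory.sigma * scale, memory.weight
                        )
                    else:
                        sm, stm = memory
                        mem = (
                            GaussianComponent(sm.mu, sm.sigma * scale, sm.weight),
                            GaussianComponent(stm.mu, stm.sigma * scale, stm.weight),
                        )
                    errs, routes = _sample_cell_ab(
                        {"memory": mem, "omega": omega}, n, rng
                    )
                for e, r in zip(errs, routes):
                    records.append(
                        TrialRecord(
                            subject_id=subject_id,
                            experiment=design.experiment,
                            report_condition=cond,
                            set_size=set_size,
                            cue_delay_ms=delay,
                            error_deg=float(e),
                            hidden_route=str(r),
                        )
                    )
    return records


# ---------------------------------------------------------------------------
# packaged default scenario


def default_scenario() -> GenerativeScenario:
    """The packaged Model C truth used by :func:`emulate_study_dataset`.

    Values are chosen to sit in the empirically plausible range for motion
    direction reports: attention+STM components around 10 deg SD, an SM
    route whose combined SD grows from ~20 deg at zero delay toward ~40
    deg by 1600 ms, intake around 0.75 for single report, and a guess rate
    of ~0.25 at set size 3.  SR routes half its informed traffic through
    decaying SM; FR1 (the best-remembered item, already transferred to
    STM) routes most traffic through the stable attention path, so its
    delay dependence is weak.  The set-size map lowers intake and inflates
    SDs as load grows.
    """
    decay = DecayLaw("exponential_approach", sigma0=19.0, sigma_inf=40.0, tau=500.0)
    sr = ModelCParams(
        omega1=0.75,
        omega2=0.50,
        sm_decay=decay,
        sigma_attention=8.0,
        sigma_stm=6.0,
    )
    fr1 = ModelCParams(
        omega1=0.85,
        omega2=0.25,
        sm_decay=decay,
        sigma_attention=8.0,
        sigma_stm=6.0,
    )
    return GenerativeScenario(
        model="C",
        params=sr,
        condition_params={"SR": sr, "FR1": fr1},
        set_size_effects={
            1: {"omega1": 0.95, "sigma_scale": 0.80},
            2: {"omega1": 0.85, "sigma_scale": 0.90},
            3: {},
            4: {"omega1": 0.62, "sigma_scale": 1.15},
        },
    )


def emulate_study_dataset(
    seed: int = 0,
    trials_per_cell: int = 300,
    experiments: Sequence[str] = ("set_size", "cue_delay"),
) -> list[TrialRecord]:
    """A packaged default dataset: both experiments, 5 subjects, SR + FR1.

    Generated from :func:`default_scenario` (Model C).  Its fitted
    summaries reproduce the qualitative signatures the analysis targets:
    the narrow component SD flat in cue delay, the wide SR component SD
    increasing with delay, and intake decreasing with set size.
    """
    scenario = default_scenario()
    records: list[TrialRecord] = []
    for i, exp in enumerate(experiments):
        design = ExperimentDesign(
            experiment=exp,
            trials_per_cell=trials_per_cell,
            seed=seed * 7919 + i,
        )
        records.extend(simulate_trials(design, scenario))
    return records


# ---------------------------------------------------------------------------
# table I/O


def trials_to_frame(
    records: Sequence[TrialRecord], include_hidden: bool = False
) -> pd.DataFrame:
    """Trial records as a tidy DataFrame (hidden route excluded by default)."""
    cols = {
        "subject_id": [r.subject_id for r in records],
        "experiment": [r.experiment for r in records],
        "report_condition": [r.report_condition for r in records],
        "set_size": [r.set_size for r in records],
        "cue_delay_ms": [r.cue_delay_ms for r in records],
        "error_deg": [r.error_deg for r in records],
    }
    if include_hidden:
        cols["hidden_route"] = [r.hidden_route for r in records]
    return pd.DataFrame(cols)


def write_trials_csv(
    records: Sequence[TrialRecord], path, include_hidden: bool = False
) -> None:
    """Write the trial table CSV consumed by the analysis pipeline."""
    trials_to_frame(records, include_hidden=include_hidden).to_csv(path, index=False)
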