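"""End-to-end analysis of continuous-report trial tables.

The pipeline mirrors how such datasets are analysed in practice:

1. load the per-trial error table (CSV) and validate it;
2. fit mixtures per subject x condition cell;
3. compare candidate component counts by BIC and build a winner map;
4. extract intake (total Gaussian weight), precision (1/sigma) and guess
   rate per cell;
5. test whether each sorted component SD (Sigma1 = narrower, Sigma2 =
   wider) depends on cue delay — one-way repeated-measures ANOVA across
   delay levels with subjects as blocks, plus a within-subject permutation
   test of linear trend as a small-sample alternative;
6. classify the dataset as consistent with a single decaying route
   ("C-consistent": exactly one component SD delay-dependent), two
   decaying routes ("D-consistent": both), or indeterminate.

``run_pipeline`` orchestrates all stages from a config dict/YAML and
writes JSON/CSV tables (and optional figures: 4-degree binned histograms
with fitted densities, and the winner-map heatmap).
"""

from __future__ import annotations

import json
import logging
import math
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats

from .fitting import FitOptions, FitResult, ModelComparison, compare_models, fit_mixture
from .mixtures import MixtureSpec, TrialRecord, mixture_pdf, wrap_error
from .simulate import TRIAL_COLUMNS, emulate_study_dataset, trials_to_frame

__all__ = [
    "ConditionSummary",
    "TrendTestResult",
    "WinnerMap",
    "fit_cells",
    "load_trials",
    "model_c_vs_d_verdict",
    "rm_anova_oneway",
    "run_pipeline",
    "sigma_trend_test",
    "summarize_condition",
    "trend_test_matrix",
    "winner_map",
]

log = logging.getLogger("reportmix")

_COMPONENT_INDEX = {"Sigma1": 0, "Sigma2": 1}


# ---------------------------------------------------------------------------
# loading


def load_trials(path) -> list[TrialRecord]:
    """Read a trial-table CSV into validated records.

    Errors outside (-180, 180] are wrapped onto the support (with a logged
    warning); malformed rows are rejected collectively with their line
    numbers.  An empty table is an error.
    """
    path = Path(path)
    try:
        df = pd.read_csv(path)
    except pd.errors.EmptyDataError as exc:
        raise ValueError(f"{path}: empty input file") from exc
    missing = [c for c in TRIAL_COLUMNS if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")
    if len(df) == 0:
        raise ValueError(f"{path}: no data rows")

    records: list[TrialRecord] = []
    bad: list[str] = []
    n_wrapped = 0
    for pos, row in enumerate(df.itertuples(index=False)):
        line = pos + 2  # header is line 1
        try:
            err = float(getattr(row, "error_deg"))
            if not math.isfinite(err):
                raise ValueError("non-finite error_deg")
            if not (-180.0 < err <= 180.0):
                err = wrap_error(err)
                n_wrapped += 1
            records.append(
                TrialRecord(
                    subject_id=str(getattr(row, "subject_id")),
                    experiment=str(getattr(row, "experiment")),
                    report_condition=str(getattr(row, "report_condition")),
                    set_size=int(getattr(row, "set_size")),
                    cue_delay_ms=float(getattr(row, "cue_delay_ms")),
                    error_deg=err,
                )
            )
        except (TypeError, ValueError) as exc:
            bad.append(f"line {line}: {exc}")
    if bad:
        head = "; ".join(bad[:10])
        more = f" (+{len(bad) - 10} more)" if len(bad) > 10 else ""
        raise ValueError(f"{path}: {len(bad)} malformed rows: {head}{more}")
    if n_wrapped:
        log.warning("%s: wrapped %d out-of-range error angles", path, n_wrapped)
    return records


# ---------------------------------------------------------------------------
# per-condition summaries


@dataclass(frozen=True)
class ConditionSummary:
    """Intake/precision summary of one fitted subject x condition cell.

    ``precision``/``sd``/``accuracy`` describe the designated component
    (by sorted index); they are None for a pure-guessing fit, where
    precision is undefined rather than zero.
    """

    subject_id: str
    keys: Mapping[str, object]
    intake: float
    guess_rate: float
    accuracy: float | None
    sd: float | None
    precision: float | None
    n_model: int

    def to_row(self) -> dict:
        row = {"subject_id": self.subject_id, **self.keys}
        row.update(
            intake=self.intake,
            guess_rate=self.guess_rate,
            accuracy=self.accuracy,
            sd=self.sd,
            precision=self.precision,
            n_model=self.n_model,
        )
        return row


def summarize_condition(
    fit: FitResult,
    subject_id: str,
    keys: Mapping[str, object],
    component: int = 0,
) -> ConditionSummary:
    """Extract intake, precision and accuracy from a fitted cell.

    ``component`` selects which sorted component supplies the precision
    (0 = narrowest; for one-Gaussian fits the only one).
    """
    spec = fit.spec
    if spec.n_components == 0:
        return ConditionSummary(
            subject_id=subject_id,
            keys=dict(keys),
            intake=0.0,
            guess_rate=1.0,
            accuracy=None,
            sd=None,
            precision=None,
            n_model=0,
        )
    if component >= spec.n_components:
        raise ValueError(
            f"component {component} requested but fit has {spec.n_components}"
        )
    c = spec.components[component]
    return ConditionSummary(
        subject_id=subject_id,
        keys=dict(keys),
        intake=spec.intake,
        guess_rate=spec.guess_rate,
        accuracy=c.mu,
        sd=c.sigma,
        precision=1.0 / c.sigma,
        n_model=spec.n_components,
    )


# ---------------------------------------------------------------------------
# per-cell fitting


def _cell_frame(trials) -> pd.DataFrame:
    if isinstance(trials, pd.DataFrame):
        return trials
    return trials_to_frame(trials)


def fit_cells(
    trials,
    grouping: Sequence[str],
    opts: FitOptions,
) -> dict[tuple, FitResult]:
    """Fit one mixture per (subject x grouping) cell.

    Returns a dict keyed by (subject_id, *grouping values).  Cell seeds are
    derived deterministically from ``opts.seed`` and the cell order.
    """
    df = _cell_frame(trials)
    out: dict[tuple, FitResult] = {}
    groups = df.groupby(["subject_id", *grouping], sort=True)
    for i, (key, sub) in enumerate(groups):
        cell_opts = FitOptions(
            **{**opts.__dict__, "seed": opts.seed * 1000 + i}
        )
        out[key if isinstance(key, tuple) else (key,)] = fit_mixture(
            sub["error_deg"].to_numpy(), cell_opts
        )
    return out


# ---------------------------------------------------------------------------
# winner map


@dataclass(frozen=True)
class WinnerMap:
    """BIC winner/runner-up per cell, as a tidy table plus tallies."""

    cells: pd.DataFrame  # subject_id, grouping cols, winner, runner_up, ...
    grouping: tuple[str, ...]
    comparisons: Mapping[tuple, ModelComparison] = field(repr=False, default=None)

    def tally(self) -> dict[int, int]:
        """Count of cells won by each component count (failures excluded)."""
        ok = self.cells[~self.cells["failed"]]
        return ok["winner"].value_counts().sort_index().to_dict()

    @property
    def n_failed(self) -> int:
        return int(self.cells["failed"].sum())


def winner_map(
    trials,
    grouping: Sequence[str],
    opts: FitOptions,
    n_list: Sequence[int] = (1, 2, 3, 4, 5),
    min_trials: int = 50,
) -> WinnerMap:
    """Model comparison per subject x condition cell.

    Cells below ``min_trials`` observations are still fit but logged; cells
    whose comparison fails outright are flagged and excluded from tallies.
    """
    df = _cell_frame(trials)
    rows = []
    comps: dict[tuple, ModelComparison] = {}
    groups = df.groupby(["subject_id", *grouping], sort=True)
    for i, (key, sub) in enumerate(groups):
        key = key if isinstance(key, tuple) else (key,)
        n_obs = len(sub)
        if n_obs < min_trials:
            log.warning("cell %s has only %d trials", key, n_obs)
        cell_opts = FitOptions(**{**opts.__dict__, "seed": opts.seed * 1000 + i})
        row = dict(zip(["subject_id", *grouping], key))
        row["n_obs"] = n_obs
        try:
            cmp_ = compare_models(sub["error_deg"].to_numpy(), cell_opts, n_list)
        except Exception as exc:
            log.warning("cell %s failed: %s", key, exc)
            row.update(winner=None, runner_up=None, delta_bic=None, failed=True)
            rows.append(row)
            continue
        comps[key] = cmp_
        delta = (
            cmp_.results[cmp_.runner_up].bic - cmp_.results[cmp_.winner].bic
            if cmp_.runner_up is not None
            else None
        )
        row.update(
            winner=cmp_.winner, runner_up=cmp_.runner_up, delta_bic=delta, failed=False
        )
        rows.append(row)
    return WinnerMap(
        cells=pd.DataFrame(rows), grouping=tuple(grouping), comparisons=comps
    )


# ---------------------------------------------------------------------------
# trend tests


def rm_anova_oneway(matrix: np.ndarray) -> tuple[float, tuple[int, int], float]:
    """One-way repeated-measures ANOVA (subjects x levels matrix).

    Returns (F, (df1, df2), p) with df = (levels-1, (levels-1)*(subjects-1)),
    sphericity uncorrected.
    """
    y = np.asarray(matrix, float)
    if y.ndim != 2 or y.shape[0] < 2 or y.shape[1] < 2:
        raise ValueError("need a subjects x levels matrix with both dims >= 2")
    s, l = y.shape
    grand = y.mean()
    ss_subj = l * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cond = s * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_subj - ss_cond
    df1, df2 = l - 1, (l - 1) * (s - 1)
    ms_cond = ss_cond / df1
    ms_err = ss_err / df2
    f = ms_cond / ms_err if ms_err > 0 else math.inf
    p = float(stats.f.sf(f, df1, df2)) if math.isfinite(f) else 0.0
    return float(f), (df1, df2), p


def _linear_trend_stat(y: np.ndarray, scores: np.ndarray) -> float:
    c = scores - scores.mean()
    return float(np.sum(y @ c))


@dataclass(frozen=True)
class TrendTestResult:
    """Delay-dependence test of one sorted component SD.

    ``sigma_matrix`` holds the raw fitted SDs (subjects x delays);
    ``log_scale`` records whether the tests ran on log SDs.
    """

    condition: str
    component: str  # "Sigma1" | "Sigma2"
    f_statistic: float
    df: tuple[int, int]
    p_value: float
    permutation_p: float
    sigma_matrix: np.ndarray = field(repr=False, default=None)
    delays: tuple[float, ...] = ()
    subjects: tuple[str, ...] = ()
    log_scale: bool = False

    def to_row(self) -> dict:
        return {
            "condition": self.condition,
            "component": self.component,
            "F": self.f_statistic,
            "df1": self.df[0],
            "df2": self.df[1],
            "p": self.p_value,
            "permutation_p": self.permutation_p,
        }


def trend_test_matrix(
    matrix: np.ndarray,
    delays: Sequence[float],
    subjects: Sequence[str] = (),
    condition: str = "",
    component: str = "",
    n_permutations: int = 999,
    seed: int = 0,
    log_scale: bool = False,
) -> TrendTestResult:
    """Trend tests on a prepared subjects x delays SD matrix.

    Runs the repeated-measures F test across delay levels (subjects as
    blocks) and a seeded permutation test of linear trend in which the
    delay labels are permuted within each subject (trend scores = delay
    ranks, two-sided).  With ``log_scale`` both tests run on log values:
    appropriate for SDs, whose subject and load effects are
    multiplicative and whose estimates are heavy-tailed to the right.
    """
    raw = np.asarray(matrix, float)
    mat = np.log(raw) if log_scale else raw
    f, df, p = rm_anova_oneway(mat)

    scores = np.argsort(np.argsort(delays)).astype(float)
    c = scores - scores.mean()
    obs = _linear_trend_stat(mat, scores)
    rng = np.random.default_rng(seed)
    count = 0
    for _ in range(n_permutations):
        perm = np.array([rng.permutation(c) for _ in range(mat.shape[0])])
        stat = float(np.sum(mat * perm))
        if abs(stat) >= abs(obs) - 1e-12:
            count += 1
    perm_p = (count + 1) / (n_permutations + 1)

    return TrendTestResult(
        condition=condition,
        component=component,
        f_statistic=f,
        df=df,
        p_value=p,
        permutation_p=perm_p,
        sigma_matrix=raw,
        delays=tuple(float(d) for d in delays),
        subjects=tuple(subjects),
        log_scale=log_scale,
    )


def sigma_trend_test(
    fits: Mapping[tuple, FitResult],
    component: str,
    condition: str = "",
    n_permutations: int = 999,
    seed: int = 0,
    log_scale: bool = True,
) -> TrendTestResult:
    """Test whether a sorted component SD varies with cue delay.

    ``fits`` maps (subject_id, cue_delay_ms) to a fitted mixture with at
    least two components when ``component`` is ``"Sigma2"``.  See
    :func:`trend_test_matrix` for the tests performed; by default they run
    on log SDs, the natural scale for multiplicative subject and decay
    effects on a positive quantity.
    """
    if component not in _COMPONENT_INDEX:
        raise ValueError("component must be 'Sigma1' or 'Sigma2'")
    idx = _COMPONENT_INDEX[component]
    subjects = sorted({k[0] for k in fits})
    delays = sorted({k[1] for k in fits})
    missing = [
        (s, d) for s in subjects for d in delays if (s, d) not in fits
    ]
    if missing:
        raise ValueError(f"missing fits for subject/delay cells: {missing}")
    mat = np.empty((len(subjects), len(delays)))
    for i, s in enumerate(subjects):
        for j, d in enumerate(delays):
            spec = fits[(s, d)].spec
            if spec.n_components <= idx:
                raise ValueError(
                    f"fit for subject {s}, delay {d} has {spec.n_components} "
                    f"components; cannot extract {component}"
                )
            mat[i, j] = spec.components[idx].sigma
    return trend_test_matrix(
        mat,
        delays,
        subjects=subjects,
        condition=condition,
        component=component,
        n_permutations=n_permutations,
        seed=seed,
        log_scale=log_scale,
    )


def model_c_vs_d_verdict(
    trends: Mapping[str, Mapping[str, TrendTestResult]],
    alpha: float = 0.05,
    use_permutation: bool = True,
) -> dict:
    """Classify each condition by which component SDs depend on cue delay.

    Exactly one significant SD trend -> "C-consistent" (one decaying route,
    one stable); both significant -> "D-consistent" (both routes decay);
    neither -> "indeterminate".
    """
    out = {}
    for condition, comps in trends.items():
        p1 = (
            comps["Sigma1"].permutation_p
            if use_permutation
            else comps["Sigma1"].p_value
        )
        p2 = (
            comps["Sigma2"].permutation_p
            if use_permutation
            else comps["Sigma2"].p_value
        )
        sig = (p1 < alpha, p2 < alpha)
        if sig == (True, True):
            verdict = "D-consistent"
        elif sig == (False, False):
            verdict = "indeterminate"
        else:
            verdict = "C-consistent"
        out[condition] = {
            "verdict": verdict,
            "alpha": alpha,
            "p_sigma1": p1,
            "p_sigma2": p2,
            "significant_sigma1": bool(sig[0]),
            "significant_sigma2": bool(sig[1]),
        }
    return out


# ---------------------------------------------------------------------------
# orchestration


_CONFIG_DEFAULTS = {
    "seed": 0,
    "input_csv": None,
    "scenario": "default",
    "trials_per_cell": 300,
    "experiments": ["set_size", "cue_delay"],
    "n_list": [1, 2, 3, 4, 5],
    "trend_n": 2,
    "trend_min_weight": 0.05,
    "alpha": 0.05,
    "n_starts": 20,
    "fix_means_at_zero": False,
    "clip_mode": "truncated_renormalized",
    "out_dir": "reportmix_out",
    "make_figures": True,
    "max_figure_cells": 12,
}


def _load_config(config) -> dict:
    if isinstance(config, (str, Path)):
        import yaml

        with open(config) as fh:
            config = yaml.safe_load(fh)
    cfg = dict(_CONFIG_DEFAULTS)
    unknown = set(config) - set(cfg)
    if unknown:
        raise ValueError(f"unknown config keys: {sorted(unknown)}")
    cfg.update(config)
    bad = [n for n in cfg["n_list"] if not (isinstance(n, int) and 1 <= n <= 5)]
    if bad:
        raise ValueError(f"invalid model ids in n_list: {bad} (must be 1..5)")
    if cfg["trend_n"] < 2:
        raise ValueError("trend_n must be >= 2 to define Sigma1 and Sigma2")
    if cfg["scenario"] not in ("default",) and cfg["input_csv"] is None:
        raise ValueError(f"unknown scenario {cfg['scenario']!r}")
    return cfg


def _grouping_for(experiment: str) -> list[str]:
    return ["report_condition", "set_size" if experiment == "set_size" else "cue_delay_ms"]


def _json_bytes(obj) -> bytes:
    return json.dumps(obj, sort_keys=True, indent=1).encode()


def run_pipeline(config) -> dict:
    """Run the full analysis and write a report bundle to ``out_dir``.

    Stages: acquire trials (CSV or packaged generator), per-cell model
    comparison and winner map, one-Gaussian condition summaries, component
    SD trend tests on the cue-delay experiment, and the C-vs-D verdict.
    Outputs (all deterministic given the seed): ``fits.json``,
    ``summaries.csv``, ``winner_map.csv``, ``trend_tests.csv``,
    ``verdict.json``, ``run_log.txt`` and optional figures.
    Returns the bundle as a dict.
    """
    cfg = _load_config(config)
    out_dir = Path(cfg["out_dir"])
    out_dir.mkdir(parents=True, exist_ok=True)
    seed = int(cfg["seed"])

    # -- stage 1: data
    if cfg["input_csv"] is not None:
        records = load_trials(cfg["input_csv"])
    else:
        records = emulate_study_dataset(
            seed=seed,
            trials_per_cell=int(cfg["trials_per_cell"]),
            experiments=tuple(cfg["experiments"]),
        )
    df = trials_to_frame(records)
    experiments = sorted(df["experiment"].unique())

    base_opts = FitOptions(
        n_components=1,
        n_starts=int(cfg["n_starts"]),
        fix_means_at_zero=bool(cfg["fix_means_at_zero"]),
        clip_mode=cfg["clip_mode"],
        seed=seed,
    )

    bundle: dict = {"config": cfg, "n_trials": int(len(df))}
    fits_json: dict = {}
    summary_rows: list[dict] = []
    winner_frames: list[pd.DataFrame] = []
    trend_rows: list[dict] = []
    verdicts: dict = {}
    winner_maps: dict[str, WinnerMap] = {}

    for experiment in experiments:
        sub = df[df["experiment"] == experiment]
        grouping = _grouping_for(experiment)

        # -- stage 2: model comparison / winner map
        wm = winner_map(sub, grouping, base_opts, n_list=cfg["n_list"])
        winner_maps[experiment] = wm
        frame = wm.cells.copy()
        frame.insert(0, "experiment", experiment)
        winner_frames.append(frame)
        for key, cmp_ in wm.comparisons.items():
            fits_json["/".join(str(k) for k in (experiment, *key))] = cmp_.to_dict()

        # -- stage 3: one-Gaussian summaries (intake / precision curves)
        one_fits = fit_cells(sub, grouping, base_opts)
        for key, fit in one_fits.items():
            keys = dict(zip(grouping, key[1:]))
            summary_rows.append(
                summarize_condition(fit, key[0], {"experiment": experiment, **keys})
                .to_row()
            )

        # -- stage 4: trend tests (cue-delay design only)
        if experiment == "cue_delay":
            # weight floor guards the Sigma1/Sigma2 labels against
            # degenerate spike or uniform-absorbing components
            trend_opts = FitOptions(
                **{
                    **base_opts.__dict__,
                    "n_components": int(cfg["trend_n"]),
                    "min_component_weight": float(cfg["trend_min_weight"]),
                }
            )
            trends: dict[str, dict[str, TrendTestResult]] = {}
            for cond in sorted(sub["report_condition"].unique()):
                cc = sub[sub["report_condition"] == cond]
                cell_fits = fit_cells(cc, ["cue_delay_ms"], trend_opts)
                keyed = {(k[0], k[1]): v for k, v in cell_fits.items()}
                trends[cond] = {}
                for comp in ("Sigma1", "Sigma2"):
                    tr = sigma_trend_test(
                        keyed, comp, condition=cond,
                        seed=seed + _COMPONENT_INDEX[comp],
                    )
                    trends[cond][comp] = tr
                    trend_rows.append(tr.to_row())
            verdicts = model_c_vs_d_verdict(trends, alpha=float(cfg["alpha"]))

    # -- stage 5: outputs
    (out_dir / "fits.json").write_bytes(_json_bytes(fits_json))
    summaries = pd.DataFrame(summary_rows)
    summaries.to_csv(out_dir / "summaries.csv", index=False)
    winners = pd.concat(winner_frames, ignore_index=True)
    winners.to_csv(out_dir / "winner_map.csv", index=False)
    pd.DataFrame(trend_rows).to_csv(out_dir / "trend_tests.csv", index=False)
    (out_dir / "verdict.json").write_bytes(_json_bytes(verdicts))

    import platform

    (out_dir / "run_log.txt").write_text(
        "reportmix pipeline run\n"
        f"seed: {seed}\n"
        f"n_trials: {len(df)}\n"
        f"experiments: {experiments}\n"
        f"python: {platform.python_version()}\n"
        f"numpy: {np.__version__}\npandas: {pd.__version__}\n"
    )

    if cfg["make_figures"]:
        _write_figures(df, winner_maps, out_dir, int(cfg["max_figure_cells"]))

    bundle.update(
        fits=fits_json,
        summaries=summaries,
        winner_map=winners,
        trend_tests=pd.DataFrame(trend_rows),
        verdicts=verdicts,
        out_dir=str(out_dir),
    )
    return bundle


def _write_figures(
    df: pd.DataFrame,
    winner_maps: Mapping[str, WinnerMap],
    out_dir: Path,
    max_cells: int,
) -> None:
    """Histogram overlays (4-degree bins) and winner-map heatmaps."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    bins = np.arange(-180, 184, 4)
    n_done = 0
    fig_dir = out_dir / "figures"
    fig_dir.mkdir(exist_ok=True)
    for experiment, wm in winner_maps.items():
        for key, cmp_ in wm.comparisons.items():
            if n_done >= max_cells:
                break
            sel = df["experiment"] == experiment
            sel &= df["subject_id"] == key[0]
            for col, val in zip(wm.grouping, key[1:]):
                sel &= df[col] == val
            errs = df.loc[sel, "error_deg"].to_numpy()
            fig, ax = plt.subplots(figsize=(5, 3.2))
            ax.hist(errs, bins=bins, density=True, color="0.8", label="data")
            xs = np.linspace(-180, 180, 721)
            best = cmp_.results[cmp_.winner].spec
            ax.plot(xs, mixture_pdf(best, xs), "r-", lw=1.5,
                    label=f"best (n={cmp_.winner})")
            ax.set_xlabel("error (deg)")
            ax.set_ylabel("density")
            ax.legend(frameon=False, fontsize=8)
            name = "_".join(str(k) for k in (experiment, *key))
            fig.savefig(fig_dir / f"cell_{name}.png", dpi=100)
            plt.close(fig)
            n_done += 1

        cells = wm.cells[~wm.cells["failed"]]
        if len(cells):
            pivot = cells.pivot_table(
                index="subject_id", columns=wm.grouping[-1], values="winner",
                aggfunc="first",
            )
            fig, ax = plt.subplots(figsize=(5, 3.2))
            im = ax.imshow(pivot.to_numpy(), cmap="viridis", vmin=1, vmax=5)
            ax.set_xticks(range(pivot.shape[1]), pivot.columns)
            ax.set_yticks(range(pivot.shape[0]), pivot.index)
            ax.set_xlabel(wm.grouping[-1])
            fig.colorbar(im, label="winning n")
            fig.savefig(fig_dir / f"winner_map_{experiment}.png", dpi=100)
            plt.close(fig)
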