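# reportmix

Mixture-model analysis of continuous-report memory errors.

## The problem

In continuous-report psychophysics an observer reproduces an analogue
stimulus feature — here, the direction of motion of briefly tracked disks —
and the datum of interest is the signed report error ε ∈ (−180°, 180°].
The distribution of ε across trials separates *how much* information was
stored from *how well* it was stored:

```
PDF(ε) = Σᵢ ωᵢ · G(ε; μᵢ, σᵢ)  +  (1 − Σᵢ ωᵢ) · U(−180°, 180°)
```

Each Gaussian component is a report driven by stored information (mean μ =
accuracy, 1/σ = precision, weight ω = intake); the uniform component is
guessing.  A single-trial performance score, TP = 1 − |ε|/180, anchors the
scale: 1 for a perfect report, 0.5 on average under pure guessing.

The package is built around block-diagram models of how such mixtures
arise from memory architecture.  Noisy processing stages in series
convolve — and the convolution of Gaussians is a Gaussian with summed
means and variances — so each architecture reduces to an n-Gaussian +
uniform mixture:

* **Model A/B** — one lumped memory stage, or sensory memory (SM) feeding
  short-term memory (STM) in series: one Gaussian + uniform.
* **Model C** — an attention pathway in parallel with pre-attentive SM,
  both feeding STM: two Gaussians + uniform with weights ω₁ω₂, ω₁(1−ω₂)
  and guessing 1−ω₁.  Only the SM-routed component inherits the
  delay-dependent SM noise σ_SM(t), so **exactly one** component SD grows
  with cue delay.
* **Model D** — two parallel SM→STM routes (nonselective vs selective
  transfer), weights ω₁ and ω₂: two Gaussians + uniform in which **both**
  component SDs grow with delay.

The analysis pipeline fits mixtures with n = 1…5 components per subject ×
condition by maximum likelihood (multi-start Nelder–Mead on truncated,
renormalized Gaussians), ranks them by BIC = k·ln N − 2·ln L, extracts
intake/precision curves against set size and cue delay, and tests whether
each sigma-sorted component SD (Sigma1 = narrower, Sigma2 = wider)
depends on cue delay — repeated-measures ANOVA across delay levels plus a
within-subject permutation test of linear trend.  The verdict rule:
exactly one delay-dependent SD → "C-consistent"; both → "D-consistent";
neither → "indeterminate".

Because such behavioural datasets are rarely deposited, the package ships
a generative simulator that produces per-trial errors by sampling the
block-diagram stages sequentially (route choice → stage noises → wrap),
with per-subject heterogeneity and set-size effects, for use in parameter
recovery, model recovery, and power analyses.

## Worked example

```python
import numpy as np
from reportmix import (
    DecayLaw, ModelCParams, reduce_model_c, sample_mixture,
    FitOptions, compare_models,
)

params = ModelCParams(
    omega1=0.75,           # intake: 75% of trials are informed responses
    omega2=0.50,           # half of those route through sensory memory
    sm_decay=DecayLaw("exponential_approach", sigma0=19, sigma_inf=40, tau=500),
    sigma_attention=8.0,
    sigma_stm=6.0,
)
truth = reduce_model_c(params, t_ms=800)   # -> 2 Gaussians + uniform

rng = np.random.default_rng(0)
errors = sample_mixture(truth, 5000, rng)

cmp_ = compare_models(
    errors,
    FitOptions(n_starts=10, seed=0, fix_means_at_zero=True),
    n_list=(1, 2, 3),
)
```

This prints (exact output of the run above):

```
BIC winner: n = 2  runner-up: n = 3
  n=1: BIC=  52259.9  dBIC=  322.6
  n=2: BIC=  51937.3  dBIC=    0.0
  n=3: BIC=  51951.8  dBIC=   14.5
fitted intake: 0.753  guess rate: 0.247
  component: sigma= 10.1 deg  weight=0.374  precision=0.0987/deg
  component: sigma= 37.4 deg  weight=0.379  precision=0.0268/deg
```

BIC correctly picks two components, and the fit recovers the generative
truth: intake 0.75, a narrow attention+STM component (true σ = 10.0°,
weight 0.375) and a wide SM+STM component at 800 ms delay (true σ =
36.3°, weight 0.375).

## Command line

```bash
reportmix simulate --seed 1 trials.csv          # synthetic trial table
reportmix fit trials.csv fits.json              # per-cell mixture fits
reportmix compare trials.csv winners.csv        # BIC winner map
reportmix trend --condition SR trials.csv t.json  # SD trend tests + verdict
reportmix run config.yaml                       # full pipeline
```

`run` consumes a YAML/JSON config (input CSV or the packaged generator,
candidate model list, seed, output directory) and writes fit JSON,
summary/winner/trend CSV tables, a verdict record, a run log, and figures
(4°-binned error histograms with fitted densities; winner-map heatmaps).

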