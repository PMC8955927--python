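# Methods

## Model

A continuous-report trial yields a signed error ε on the half-open
interval (−180°, 180°] (−180° is mapped to +180° so the maximal deviation
has one representation).  The descriptive model is a finite mixture

PDF(ε) = Σᵢ ωᵢ G(ε; μᵢ, σᵢ) + (1 − Σᵢ ωᵢ) U(−180°, 180°),  n = 1…5,

with intake Σωᵢ (proportion of informed responses), precision 1/σ per
component, and guess rate = the uniform weight.  The single-trial score
TP = 1 − |ε|/180 has anchors TP(0) = 1 and E[TP] = 0.5 under guessing.

Block-diagram memory architectures generate these mixtures.  Stages in
series add independent Gaussian noise, and a Gaussian convolution is
Gaussian with summed mean and variance, so:

* serial SM→STM (Models A/B): one Gaussian + uniform;
* an attention pathway parallel to pre-attentive SM, both feeding STM
  (Model C): components with weights ω₁ω₂ (SM route) and ω₁(1−ω₂)
  (attention route), uniform 1−ω₁ — only the SM component inherits
  σ_SM(t);
* two parallel SM→STM routes (Model D): weights ω₁, ω₂, uniform
  1−ω₁−ω₂ — both components inherit σ_SM(t).

On a bounded domain Gaussianity is approximate; the error committed by
the convolution reduction equals the clipped tail mass and is negligible
for component SDs ≤ ~30° (measured directly in the test suite, which also
quantifies the growing discrepancy as SDs approach 90°).

Sensory-memory decay is a nondecreasing SD law σ_SM(t) with selectable
form; the default, σ(t) = σ∞ − (σ∞ − σ0)·exp(−t/τ), is a saturating
approach consistent with decay curves that flatten by ~1 s.  `constant`
and `linear_saturating` forms are available.  The form matters only to
the generator; fits are per-delay and make no assumption about it.

## Likelihood and fitting

Two density conventions are implemented.  The default truncates each
Gaussian to [−180°, 180°] and renormalizes by its mass there, so the
mixture integrates to exactly 1 and log-likelihoods (hence BIC) are
proper.  A `plain` mode evaluates unnormalized Gaussians, matching
analyses that ignore clipping; it differs measurably only for very wide
components.

Fits run derivative-free Nelder–Mead in an unconstrained space: log-σ
passed through a logistic map between bounds (default 0.5°–180°; the
lower bound blocks spike components on repeated values), weights through
a softmax with the uniform logit pinned at 0, and means free or fixed at
0.  An optional minimum component weight (`min_component_weight`)
re-maps the simplex to w ← floor + (1 − (n+1)·floor)·softmax; the
pipeline's trend fits use floor = 0.05 because unconstrained small-N ML
occasionally produces a degenerate spike (tiny weight, σ at the lower
bound) or a support-wide component that absorbs the uniform term, either
of which corrupts the sigma-sorted component labels.

Mixture likelihoods are multimodal, so every fit is multi-start (default
20): one deterministic moment-based start (an SD ladder around the sample
SD, equal weights, 20% guess rate) plus stratified random starts — σ
log-uniform on [2°, 90°], weights Dirichlet(1), means N(0°, 10°) when
free — all drawn from the fit seed, making results bit-reproducible.
Model comparison additionally warm-starts each n from the best (n−1) fit
embedded with a 10⁻³-weight extra component, which makes the in-sample
likelihood nondecreasing in n.

The alternative objective minimises Σ(F̂(ε₍ᵢ₎) − F(ε₍ᵢ₎))² at the sorted
sample with Hazen plotting positions (i − ½)/N; the log-likelihood is
still evaluated at its optimum so results stay BIC-comparable.  On large
simulated samples the two objectives agree to a few percent.

BIC = k·ln N − 2·ln L with k = 3 per Gaussian (μ, σ, ω; the uniform
weight is implied), or 2 per Gaussian with means fixed.  The smallest BIC
wins; ties break toward smaller n (parsimony).

Components are always reported sorted by σ ascending (Sigma1 =
narrowest), which resolves mixture label switching.

## Trend tests and the C/D verdict

For each report condition, two-Gaussian fits per subject × delay give a
subjects × delays matrix of each component SD.  Two tests of delay
dependence are computed:

* one-way repeated-measures ANOVA across delay levels with subjects as
  blocks, df = (L−1, (L−1)(S−1)) (e.g. (5, 20) for 6 delays × 5
  subjects), sphericity uncorrected;
* a seeded permutation test of linear trend: the statistic is the
  covariance of SDs with delay rank summed over subjects, delay labels
  permuted within subject, two-sided, 999 permutations by default.

Both default to operating on log SDs: subject heterogeneity and memory
load act multiplicatively on SDs, SD estimates are positive and
heavy-tailed to the right, and the additive block structure the F test
assumes then holds on the log scale.  Raw-scale testing is available
(`log_scale=False`).  With 5 subjects the permutation test is the
preferred inference and is what the verdict uses by default; the F test
is reported for comparability with the ANOVA convention.

Verdict, at configurable α (default 0.05): exactly one of
(Sigma1, Sigma2) delay-dependent → "C-consistent"; both →
"D-consistent"; neither → "indeterminate".

## The synthetic-data generator

The generator emulates two designs: a set-size experiment (1–4 disks,
cue delay 0) and a cue-delay experiment (set size 3; delays 0, 100, 200,
400, 800, 1600 ms), with single-report (SR) and first-item-of-full-report
(FR1) conditions, 5 subjects, and 300 trials per cell by default.
Sampling is stage-wise — route chosen by the mixture weights, stage
noises drawn sequentially, summed and wrapped — so it exercises the
convolution reduction rather than assuming it; the route behind every
trial is retained as hidden ground truth.

Packaged defaults (one fixed configuration, chosen to sit in the
empirically plausible range for motion-direction reports): attention SD
8°, STM SD 6° (narrow component ≈ 10°), SM decay 19° → 40° with τ =
500 ms (wide component ≈ 20° at 0 ms to ≈ 40° at 1600 ms); SR routes
ω₁ = 0.75, ω₂ = 0.5; FR1 — the best-remembered, already-transferred item
— has ω₁ = 0.85 and only ω₂ = 0.25 through decaying SM.  Set-size
effects are explicit per-size maps (intake 0.95 → 0.62, SD scale 0.8 →
1.15 from 1 to 4 items).  Subject heterogeneity is log-normal
(SD 10%) on stage SDs and additive N(0, 0.2) jitter on weight logits.

What the generator does not emulate: misbinding/swap errors,
event segmentation and pre-deviation reports, sequential-order effects,
response times, feedback, and any non-Gaussian stage noise.  Passing
recovery tests on these data therefore validates the estimation and
inference machinery under the model's own assumptions, not the model's
adequacy for any particular real dataset.

## Validation sizes and numerical choices

The test suite validates, at sizes chosen to balance statistical
resolution against a desktop run time of a few minutes: density
normalisation to 1e−6 over 100 random mixtures; sampling/reduction
agreement by KS test at n = 10⁵ per architecture; parameter recovery
from the two-component truth at N = 5000 over 20 replicates (measured
median errors ≈ 0.01 on weights, ≈ 4% on SDs); BIC order recovery at
N = 2000, candidates {1, 2, 3}, over 20 replicates per truth; and
decay-signature recovery on full synthetic experiments (5 subjects × 6
delays × 300 trials) over 20 replicates, with two-decaying-route data
checked over 8 replicates.  Trend-test calibration (null F ≈ its
expectation, uniform permutation p) and power (detection of a strong
monotone SD increase) are simulated on 200 matrices each.

Numerical details: likelihoods in log space; plain-mode densities floored
at 1e−300 before the log; truncation masses via the normal CDF (`ndtr`);
Nelder–Mead with fatol 1e−8, at most 4000 iterations; quantiles by
bracketed root search to 1e−10; quadrature of narrow mixtures uses the
component means as break points.  All randomness flows from explicit
integer seeds through `numpy.random.Generator`/`SeedSequence`; identical
seeds give byte-identical JSON outputs.

## Limitations

Per-cell fits are independent (no sharing of σ across delays), matching
per-condition analysis conventions but discarding the efficiency a joint
decay-law fit would give.  The sigma-sorted labelling can still swap
components in regimes where the two SDs cross or nearly coincide.  The
repeated-measures F test is sphericity-uncorrected.  Wrapped-normal (von
Mises) circular densities, misbinding components, and more than five
Gaussian components are out of scope.
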