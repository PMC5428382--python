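# Methods

## The measurement being modeled

A pulse-chase with a self-labeling protein tag marks the insulin granules
synthesized during a short labeling window. Sections are imaged in a
fluorescence frame (SIM) and an EM frame; after landmark registration each
labeled spot is matched to its EM granule, and per cell the labeled and
total granule counts give a labeled fraction. Aggregated over cells and
replicate experiments this yields one observation per cohort age
`t`: a fraction `y`, its between-experiment SEM, and the sample sizes.
The 5–8 h age group is encoded as `t = 0.27` days (midpoint 6.5 h); the
other ages are 1–5 days.

## Decay models and fitting

Three nested models describe the labeled fraction (all continuous in `t`,
`y(0) = a`):

1. `y = a·exp(−t/τ)`
2. `y = a` for `t ≤ Δ`, `a·exp(−(t−Δ)/τ)` after
3. `y = a·exp(−t/τ₁)` for `t ≤ Δ`, `a·exp(−Δ/τ₁)·exp(−(t−Δ)/τ₂)` after

**Noise model.** Observations are treated as Gaussian with the reported
per-point SEM as standard deviation. The objective is the weighted
residual form `logL = −½ Σ ((yᵢ − f(tᵢ))/semᵢ)²` without the Gaussian
normalization constant: the constant is shared by all models fitted to the
same data, so likelihood *differences* — the only quantity used by model
comparison — are unaffected, and absolute values are not comparable across
noise conventions.

**Parameter box.** `a ∈ (0, 0.2]`, `Δ ∈ [0, 10]` d, `τ, τ₁ ∈ (0.05, 50]`
d — generous physical ranges around any plausible fit. The box is at once
the optimizer's search region and the uniform prior for the Bayesian
pieces (uncertainties, Laplace evidence).

**Optimization.** Bounded Nelder–Mead from scrambled-Sobol starts
(`n_starts`, default 8, seed-controlled) plus deterministic data-driven
starts: plateau from the earliest points, decay time from a log-linear fit
to the tail, one lag candidate per interior observed age, and a slow-limit
start for model 3. The best optimum wins; optima resting on a box edge are
flagged `at_boundary`. Fits fail loudly when observations ≤ free
parameters.

**Uncertainties.** The lag models are only piecewise smooth in `Δ`: the
likelihood has slope kinks wherever the lag crosses an observed age, and
optima often sit exactly on a kink. Curvature measured there (an observed
information/Hessian) is badly anti-conservative — in simulation the
empirical spread of the lag estimate is nearly twice the Hessian SE and
2-SE intervals cover the truth only ~77% of the time. Reported
uncertainties are therefore the posterior moments under the uniform prior
box, computed by seeded importance sampling with a Gaussian proposal
centered at the optimum (a coarse finite-difference Hessian, 5% relative
step, sets the proposal scale and is the fallback when the effective
sample size is too small). These posterior SEs restore ≥ 90% two-SE
coverage in simulation and agree with the error scale a Bayesian
uniform-prior analysis of such data reports. For a smooth (quadratic)
likelihood they coincide with the classical inverse-information errors.

**Model comparison.** `likelihood_ratio` scores each model by its maximum
log-likelihood (pairwise ratios `exp(logLᵢ − logLⱼ)`).
`laplace_evidence` forms the Laplace approximation of the marginal
likelihood over the prior box,
`log Z ≈ logL* + Σ log(√(2π)·sᵢ) + ½·log det(corr) − Σ log wᵢ`,
with one box-awareness refinement: each marginal sigma is truncated at
`wᵢ/√(2π)` so that a direction the data leave flat (e.g. the slow time
constant τ₁ pinned at the box edge) contributes at most the prior mass,
never a spurious Occam factor above one. Without truncation this is
exactly standard Laplace, and on a one-parameter Gaussian toy likelihood
it matches the closed-form integral to better than 1%. Posterior model
probabilities use a uniform model prior; ties prefer the simpler model.

**Half-life.** Model 1: `ln 2·τ`; model 2: `Δ + ln 2·τ`. Model 3 is
solved piecewise: if `τ₁·ln 2 ≤ Δ` the half-life lies in the slow branch
at `τ₁·ln 2`, otherwise in the fast branch at `Δ + τ₂·(ln 2 − Δ/τ₁)`.

## Registration

Coordinates are 0-based, pixel-center, `x` = column, `y` = row, physical
units nm (EM acquisition pixel size 1.8844194 nm/px is the constant
`EM_PIXEL_SIZE_NM`; synthetic scenes default to desk-scale 10 nm/px EM and
40 nm/px FLM rasters over the same field).

* **Affine** — least squares on ≥ 3 non-collinear landmark pairs.
* **Thin-plate spline** — Bookstein formulation with kernel
  `U(r) = r² log r`; regularization 0 interpolates the landmarks exactly,
  large regularization approaches the affine fit. The bending
  (kernel) coefficients vanish identically for affine-consistent
  landmarks.
* **Images** are resampled bilinearly through the inverse map
  (closed-form for affine; for a TPS the inverse is approximated by a TPS
  fitted in the reverse direction on the control points, accurate for the
  gentle distortions fiducial correlation deals with).
* **Accuracy statistic** — granules are outlined by moment-based ellipse
  fits (centroid and second central moments of the thresholded footprint,
  the deterministic reading of "fit an ellipse and project its radii");
  the per-granule FLM→EM center distance is summarized as mean ± sample
  SD. Under isotropic per-axis Gaussian measurement error σ the distances
  are Rayleigh with mean `σ·√(π/2)`, which the synthetic loop reproduces;
  with exact landmarks and no jitter the residual is numerically zero.

## Granule quantification

Detection: global threshold (Otsu by default, absolute override),
8-connected components, minimum-area filter, per-component moment ellipse.
The size metric is the equivalent-circle diameter `d = 2√(area/π)` —
deterministic and faithful for near-circular granules. Blank or flat
images return no detections; heavily overlapping spots merge into one
component (documented behavior, the same ambiguity a human counter
faces). Otsu makes detection invariant to intensity rescaling.

Pool classification matches 505 and TMR detections greedily,
closest-first, within a radius defaulting to 121.5 nm (the mean granule
radius); matched spots are double-labeled. Double-labeled granules are
age-ambiguous and excluded from the labeled-fraction numerator:
`labeled % = 100·n_505_only / n_total`. MGB co-occurrence tests whether a
granule centroid lies in a positive pixel of an MGB label image;
membership is half-open with boundary pixels inside. Diameter summaries
are arithmetic mean ± sample SD (ddof = 1).

## Group statistics

* One-way fixed-effects ANOVA with `(k−1, N−k)` degrees of freedom.
* The sequential post-hoc procedure mirrors how age groups are compared
  in practice: starting from the youngest group, each next group is
  t-tested pairwise against every group already pooled; pooling stops at
  the first significant difference, then the pooled young group is tested
  against each remaining older group. t-tests default to Welch's
  unequal-variance variant (the variance structure across experiments is
  unknown); p-values are raw, with an optional Bonferroni factor on the
  final comparisons.
* MGB counts across age classes are compared with independent
  Beta(1,1)–Binomial posteriors. `P(rate_b > rate_a)` is computed by
  midpoint-rule quadrature of `pdf_b·cdf_a` on a shared grid, normalized
  against its mirror so the comparison and its reverse sum to one by
  construction (identical inputs give bitwise 0.5); a seeded Monte-Carlo
  mode cross-checks the quadrature and supplies the 95% credible interval
  for the rate difference. This formulation is a re-specification: it
  stands in for an original count comparison whose exact likelihood and
  decision rule are not published, so only its internal calibration — not
  any printed significance call — is testable.

## Synthetic data: what it emulates, and what it does not

`generate_fraction_data` reproduces the counting hierarchy of the real
study: per age, 3 experiments × 38 cells, Poisson(800) granules per cell,
each labeled independently with probability `y(t)`, fractions pooled per
experiment, mean ± SEM across experiments. A per-experiment labeling
efficiency `Normal(1, 0.10)` models the between-experiment biological
variability that dominates real replicate SEMs; with it the simulated
SEMs sit at the few-per-mille scale (median ≈ 0.0011) typical of such
data, whereas pure counting noise alone would be 3–7× smaller. The
efficiency factors are drawn independently per age and experiment — real
experiments would correlate ages within an experiment, a structure the
generator (like the aggregate fit) ignores.

`generate_observations` instead draws Gaussian observations with *stated*
per-age SEMs (defaults 0.0016–0.0026 early, 0.0010 late). It exists for
estimator-calibration studies — coverage and model-selection rates are
only interpretable when the generating noise matches the noise model the
fit assumes.

`generate_clem_scene` places granules (diameter Normal(265, 53) nm
truncated below 80 nm) by rejection sampling with centers at least
1.1×(rᵢ+rⱼ) apart so footprints never touch; MGB members are exempt and
pack inside their MGB body. The EM image renders granules as dark cores
with a darker membrane rim on a bright background; fluorescence channels
render only pool members as Gaussian-PSF spots (σ = 60 nm) at positions
pushed through the spec's EM→FLM distortion (affine, default ~1.7°
rotation with 1% scale, plus an optional smooth sinusoidal residual
field); fiducial beads appear in both frames, kept clear of granule
footprints and of labeled granules' PSF spots so detections never merge.
Noise is Gaussian (EM) and Poisson-plus-read (FLM); both default on and
are set to zero in the exact-recovery loops. One root seed spawns
per-component child streams (placement, labeling, beads, noise), recorded
in the scene metadata. The renderer makes no attempt at realistic EM
texture, section compression, or SIM reconstruction artifacts — passing
loops therefore demonstrate the correctness of the measurement chain
(registration → detection → classification → counting), not robustness to
real micrograph pathology, where thresholds and manual judgment dominate.

## Problem sizes and numerical choices

Calibration studies use 100 seeded replicates for parameter
recovery/model selection, 10,000 simulated six-group studies for the
ANOVA type-I rate, six scenes for the registration loop and three for the
detection loop — sizes at which every Monte-Carlo check has a comfortable
margin to its threshold. Optimizer tolerances are `xatol 1e-10`,
`fatol 1e-12`, ≤ 4000 iterations. The grid oracle for two-parameter fits
uses a 1e-3 step. Degenerate inputs raise informative errors rather than
returning silent defaults: too few observations, zero SEMs, collinear or
duplicate landmarks, empty ellipse masks, zero-granule cells, non-2-D
masks, invalid rates.

## Known limitations

* Absolute log-likelihood values are convention-dependent and not
  comparable to analyses using a different noise normalization; only
  differences between models on the same data are meaningful here.
* Model 3's slow time constant is frequently unidentifiable at realistic
  noise (flat likelihood up to the box edge); its fits are flagged
  `at_boundary` and its evidence relies on the box-aware truncation.
* The per-cell fit uses aggregate per-age observations with SEM weights,
  not a hierarchical cell-within-experiment model; no mixed effects, no
  MCMC.
* Automated spot calling stands in for manual counting; it is validated
  on synthetic scenes only.
* Double-labeled granule kinetics are out of scope (age-ambiguous pool,
  discarded from analysis).
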