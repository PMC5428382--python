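# clemq

Quantitative analysis of age-defined insulin secretory granules (SGs) in
correlative light/electron microscopy (CLEM) experiments.

Pancreatic beta cells store insulin in dense-core secretory granules and
preferentially release the newly made ones. Pulse-chase labeling with a
self-labeling protein tag (insulin-SNAP plus the 505-Star / TMR-Star
substrates) marks a cohort of granules born in a short time window; imaging
ultrathin sections by structured illumination microscopy (SIM) and
transmission EM, registering the two modalities on fiducial landmarks, and
counting labeled versus total granules yields the labeled fraction *y(t)*
as the cohort ages. `clemq` implements the full quantitative track of such
a study for researchers analyzing (or simulating) these experiments:

* **Kinetic decay models** (`clemq.decay_models`) — three nested models of
  the labeled fraction:

  1. exponential decay, `y(t) = a·exp(−t/τ)`
  2. lag then exponential decay, `y(t) = a` for `t ≤ Δ`, else
     `a·exp(−(t−Δ)/τ)`
  3. slow then fast biphasic decay with time constants `τ₁`, `τ₂` and
     breakpoint `Δ`

  fitted by SEM-weighted maximum likelihood with multi-start bounded
  optimization; uncertainties are posterior moments under a uniform prior
  box; models are compared by likelihood ratios or a Laplace-approximated
  Bayesian evidence with uniform model prior. The granule half-life under
  the lag model is `Δ + ln(2)·τ`.
* **Registration** (`clemq.registration`) — landmark-based affine and
  thin-plate-spline warps between the fluorescence and EM frames, point
  and image warping, moment-based ellipse fits and the center-shift
  accuracy statistic.
* **Granule quantification** (`clemq.granule_quant`) — spot detection
  (Otsu threshold + connected components), greedy colocalization of the
  two label channels, labeled-fraction, multi-granular-body (MGB)
  co-occurrence and diameter statistics.
* **Group statistics** (`clemq.group_stats`) — one-way ANOVA across age
  groups, the sequential pooling post-hoc t-test procedure, and a
  Beta–Binomial comparison of MGB counts.
* **Synthetic data** (`clemq.synthetic_data`) — ground-truth generators
  for labeled-fraction time courses (per-cell binomial counting in
  3 experiments × ~38 cells per age), paired FLM/EM scenes (granules
  265 ± 53 nm, Gaussian-PSF spots, affine + smooth distortion, fiducial
  beads) and MGB count tables.
* **Pipeline and CLI** (`clemq.io`, `clemq.cli`) — CSV/JSON/TIFF/YAML I/O
  and the `clemq` command (`simulate`, `register`, `quantify`, `stats`,
  `fit`, `compare`, `run`).

## Worked example

Simulate a full study (6 cohort ages from 6.5 h to 5 days, 3 experiments,
38 cells per age) from the lag model, fit all three models, and select:

```sh
clemq run --config demo.yaml
```

with `demo.yaml`:

```yaml
schema_version: 1
seed: 1
out_dir: demo_out
simulate: {cells_per_group: 38, granules_per_cell_mean: 800}
scene: {n_granules: 60, n_mgbs: 0}
fit: {models: [1, 2, 3]}
compare: {method: laplace_evidence}
```

prints

```
selected model 2; half-life 5.02 days; outputs in demo_out
```

and `demo_out/report.txt` contains

```
clemq pipeline report
seed: 1
observations: 6 timepoints
selected model: 2 (laplace_evidence)
half-life: 5.02 days
registration mean shift: 0.0 +/- 0.0 nm (n=60)
ANOVA: F = 10.76, p = 0.000418
```

The lag model (model 2) wins the Bayesian comparison, the ANOVA confirms
an age effect on the labeled fraction, and the noise-free scene registers
with sub-nanometer residual. Fitting the lag model to the simulated
observations directly:

```sh
$ clemq fit --model 2 --obs demo_out/observations.csv --seed 1
a = 0.02574 +/- 0.00068
delta = 3 +/- 0.11
tau = 2.908 +/- 0.22
log-likelihood = -0.33 (converged: True)
half-life = 5.02 days
```

Here `a` is the plateau labeled fraction (~2.6% of granules carry the
cohort label), `delta` the lag before degradation sets in (days), `tau`
the decay time constant (days), and the half-life `Δ + ln(2)·τ` the age at
which half of the cohort is gone.

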