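# Methods

## Model

`diaquant` treats protein quantification as posterior inference on a
uniform grid over log10 abundance. The observation model for one peptide
record with identification posterior error probability `pep` is the
two-component mixture given in the README: with probability `1 − pep` the
record reflects the protein's abundance *x* through Gaussian noise
(σ_noise, log10 units) and an intensity-dependent censoring curve
Φ((μ_m − x)/σ_m); with probability `pep` it is an incorrect identification,
modeled as a uniform draw over the grid range (the least informative
documented choice — incorrect IDs carry no information about the assigned
protein). Missing (peptide, run) slots contribute the censoring probability
itself, so absence of evidence is evidence of low abundance, weighted by
how confidently the peptide was identified elsewhere.

Per (protein, run) the peptide likelihoods multiply with a Normal(μ_y, σ_y)
prior; per condition the independent per-run posteriors are combined into
the distribution of the condition mean by exact discrete convolution; the
log2 fold-change posterior is the lattice distribution of the difference of
the two condition means (log10 → log2 by the factor log2(10) ≈ 3.32). The
differential PEP is the posterior mass on |log2 fc| ≤ τ with boundary cells
counted by their overlapping fraction; MAP point estimates are grid
argmaxes (ties to the smaller abscissa); q-values are running means of
ascending PEPs mapped back to input order.

### Relative (profile) space

Peptides of one protein differ by a fixed ionization efficiency: they
disagree — by far more than σ_noise — about the protein's absolute
abundance while agreeing about its profile across runs. The engine
therefore centers each peptide by the mean of its observed log10
intensities (an estimate of its ionization constant, which cancels exactly
in fold changes), shifts the censoring anchor μ_m by the same constant, and
inflates the likelihood width by the plug-in factor √(1 + 1/n_obs). Without
this, missingness and identification-error asymmetries between conditions
leak the ionization spread into the fold-change estimates (measured on
synthetic data: fold-change IQR ≈ 0.9 log2 versus ≈ 0.2 after). Reported
per-run MAP abundances add the protein's mean peptide level back, so they
stay on the data's log10 scale.

### Identification error probabilities

PEPs come from the target/decoy score distributions: decoy/target count
ratios in score quantile bins (divided by the decoy-to-target database
ratio), made non-increasing in score by isotonic regression and clipped to
[0, 1]. PSMs are first reduced to the best record per (peptide, charge,
run) — highest score, ties by intensity.

## Hyperparameter estimation

All fits operate on log10 intensities. When decoys are present,
`fit_hyperparameters` first removes PSMs with PEP > 0.2 — estimation wants
a high-purity subset, while the engine itself always consumes every PSM.
Slots whose only records were removed are excluded from the missingness
accounting entirely: they are neither trustworthy observations nor evidence
of censoring.

* **σ_noise** — pooled within-(peptide, condition) replicate variance,
  estimated as the median of per-group variances within each
  degrees-of-freedom class, corrected by the χ² median so it is unbiased
  under Gaussian noise. The median makes the estimate insensitive to the
  small fraction of groups contaminated by incorrect identifications, which
  inflate a mean-pooled variance several-fold.
* **μ_y, σ_y** — from per-protein mean log10 relative intensities (runs
  median-centered first, switchable). The naive between-protein standard
  deviation also contains peptide-sampling noise (ionization spread divided
  by peptide count) and, in engineered mixtures, the known species ×
  condition design offsets; σ_y is therefore estimated by variance
  decomposition — between-protein variance minus the mean within-protein
  sampling variance — after centering protein means per species whenever
  UniProt-style suffixes are parseable for essentially all proteins. On
  data without species structure the centering step is a no-op.
* **μ_m, σ_m (DIA mode, default)** — for the low-missingness regime
  typical of DIA data, where a censored fit over all XIC values is poorly
  identified.
  Missing events are anchored at the mean observed log10 intensity of their
  (peptide, condition) group; the anchor is per condition because abundance
  differs between conditions in a two-proteome design. Each group
  contributes a binomial probit likelihood for its missing/observed slot
  pattern, with three refinements that each removed a measured 10–20% bias
  in σ_m on data simulated from the stated generative model: (1) the group
  likelihood is conditioned on the group being visible at all (≥ 1 observed
  slot), because fully censored groups leave no record and would otherwise
  flatten the curve; (2) the replicate noise σ_noise is deconvolved from
  the fitted scale, since the anchor is a group mean rather than the
  per-slot value the censoring acts on; (3) a 1% outlier mixture over slot
  patterns caps the leverage of groups whose anchor is corrupted by a
  residual incorrect identification.
* **μ_m, σ_m (DDA mode)** — classic censored-normal maximum likelihood:
  underlying values Normal(μ_x, σ_x), observed with probability
  1 − Φ((μ_m − x)/σ_m), the total missing count entering through the
  marginal missing probability; multi-start Nelder–Mead over the four
  parameters.
* **τ (fold_change_eval)** — the smallest log2 threshold containing the
  central 99% of the null fold-change distribution. Under the protein
  prior the difference of two independent condition means of N samples is
  Normal with sd σ_y·√(2/N) (log10), giving
  τ = Φ⁻¹(0.995)·σ_y·√(2/N)·log2(10). The √(2/N) and log2(10) factors are
  isolated in code. τ is strictly increasing in σ_y, halves when N
  quadruples, and is printed when `quantify(..., fold_change_eval="auto")`
  is used.

A multiplicative-noise diagnostic (`noise_structure_diagnostic`) regresses
within-group raw-intensity standard deviations on group means; a clearly
positive slope with a good fit supports the log-space noise model.

## Synthetic benchmark generator

The generator emulates the HYE124 two-proteome design and embodies exactly
the model's assumptions, so that every estimator above is testable without
downloads. Per protein: base log10 abundance ~ Normal(μ_y, σ_y) plus the
log10 w/w fraction of its species in each condition. Per peptide: a fixed
ionization offset ~ Normal(0, 0.5). Per (peptide, run): log10 intensity =
level + offset + Normal(0, σ_noise), censored to missing with probability
Φ((μ_m − x)/σ_m); the record then simply never appears, as with an
upstream search tool. A fraction `id_error_rate` of surviving PSMs is
replaced by incorrect identifications whose intensities are resampled from
the global pool and whose scores follow the decoy law; decoy PSMs are
appended at `decoy_multiplier` × the expected incorrect count.

Defaults (the study conditions): 500/350/150 human/yeast/E. coli proteins,
fractions A = 65/30/5 and B = 65/15/20 w/w (true log2 fold changes 0, +1,
−2), triplicates, peptides per protein ~ Poisson(6) clipped to ≥ 1,
μ_y = 6.0 (a realistic XIC scale), σ_y = 0.4, σ_noise = 0.1, peptide offset
sd 0.5, μ_m = 4.0 and σ_m = 0.4 (overall missingness ≈ 1–2%, the low-DIA
regime), id_error_rate = 0.05, correct/incorrect score laws N(3,1)/N(1,1),
decoy_multiplier = 1. Everything is reproducible from the seed.

What the generator does *not* emulate: chromatographic or spectral
structure, retention-time alignment errors, run-level loading differences,
shared peptides between proteins, correlated peptide interference, or
instrument-specific intensity response. Tests passing on this generator
show that the engine is correct under its own distributional assumptions
and calibrated when those hold — not that real DIA data satisfy them.

## Benchmark harness

`run_synthetic_benchmark` runs one replicate end to end: engine (τ = 0.51
by default — the evaluation threshold used with triplicate two-proteome
data; the auto Eq.-style bound at σ_y = 0.4 would exceed the largest true
fold change and is meant as a lower bound on τ, not as the benchmark
setting) versus Top3 after 1% PSM-level FDR filtering with Welch + BH and
the same |log2 fc| ≥ τ rule. Metrics: per-species median MAP fold change,
the background-species fraction among proteins at q ≤ 0.05 (the realized
false-call rate), and discrimination-curve foreground counts at 50
background proteins.

Run-level normalization in `quantify` defaults to off: in two-proteome
mixtures the condition compositions differ, so run medians are not
comparable and median-centering shifts every fold change (measured:
≈ 0.19 log2 on the default design). `normalize="median"` is available for
data with loading differences.

## Numerical choices

Grid spacing 0.01 log10 units; range: data center ± max(5σ_y, 5σ_noise, 2),
widened to cover [data min − 0.5, data max + 0.5] so no likelihood is
clipped at an edge. All posterior accumulation is in log space with
max-subtraction; `peptide_log_likelihood` keeps the whole chain in log
space, which matters when observations sit many noise widths apart and
linear-space densities underflow to exactly zero. Per-run posteriors are
trimmed at 1e−12 tail mass before convolution. Fold-change lattices for
unequal group sizes are built on the common refinement of spacing
h/lcm(N_a, N_b), keeping the convolution exact. Ties in MAP estimates go
to the smaller abscissa; ties in best-PSM selection to the higher
intensity, then input order. σ estimates are floored at 1e−3 with a
warning; a table without missing values raises an explicit error directing
the user to supply a default missing-value prior, and fewer than 10
missing observations trigger a wide-σ_m fallback (σ_m = 2.0, μ_m at the
1st percentile of observed log10 intensities).

## Problem sizes

The test suite and the acceptance script use the default 1000-protein
configuration (≈ 36,000 PSMs across 6 runs) for parameter recovery and the
ten-replicate benchmark, 5000 peptides for the censored-fit recovery test,
and 15-point grids for the exhaustive convolution oracle; a full benchmark
replicate takes a few seconds on one CPU.

## Known limitations

The engine models peptides as conditionally independent given the protein
profile; shared peptides are discarded rather than apportioned, matching
the harmonized-database setting it targets. Per-run posteriors are combined
assuming independence across runs, so run-correlated effects (batch,
acquisition order) are not modeled. The peptide ionization constant is
plugged in from the observed mean rather than marginalized, which slightly
understates uncertainty for peptides observed in few runs. The DDA-mode
censored fit assumes an approximately normal underlying intensity
distribution. Absolute quantification, protein grouping and posterior
sampling are out of scope.
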