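# Methods

## Data model and assumptions

The unit of observation is a *fibre-type pool* (several single fibres of
one type from one biopsy), not an individual fibre. Reporter intensities
are treated as lognormal; all effects — fibre type, training response,
batch, loading, mitochondrial content — are additive on the log2 scale.
This is the standard working model for TMT reporter data and is exactly
what sample-loading scaling, TMM and ComBat assume. Reporter-ion
co-isolation interference is not modelled; the pipeline starts from the
exported protein-level intensity matrix.

Mitochondrial content enters the model as a *single multiplier per
(fibre type, timepoint, training) cell applied to every mitochondrial
protein of a sample*, with optional per-protein remodelling on top. That
multiplier is precisely the confound the mitochondrial renormalisation
targets: a sample with twice the mitochondria shows twice the intensity
for every mitochondrial protein without any compositional difference.

## Pipeline order

Filtering → log2 → kNN imputation → (back to raw) → SL → TMM → log2 →
ComBat → models. Two ordering decisions were genuinely open:

* **Imputation before normalisation.** The clean-up text order (impute,
  then normalise) is adopted. Imputation runs on log2 data even though
  the subsequent SL/TMM steps are raw-scale, because Euclidean distances
  on raw intensities are dominated by the most abundant proteins; the
  imputed log2 values are exponentiated back before SL.
* **SL → TMM → log2 → ComBat.** The three normalisation methods are
  listed without an order in the workflow this package re-implements;
  this order follows the TMT convention (within-plex loading first, a
  single robust between-sample factor second, batch adjustment on the
  log scale last) and is recorded in the run manifest.

## Stage notes

**Missingness filter.** A protein is dropped iff missing in *strictly
more than* `max_missing_fraction` (default 0.30) of all samples, counted
across the full matrix rather than per group; 30% exactly is retained.

**kNN imputation** (default k = 10). Distance between proteins is the
RMS difference over samples observed in both (Euclidean rescaled by the
number of shared samples), neighbours must be observed at the target
sample, the imputed value is their unweighted mean, and distance ties
break by ascending protein id. Fewer than k eligible neighbours → use
all; none → the protein's own observed mean, with a warning. Observed
values are never altered. This neighbour definition is protein-wise
(like the classic expression-matrix imputers), which is why it is
implemented here rather than delegated to feature-wise imputers from
general ML libraries.

**TMM** (trims: 0.30 on M, 0.05 on A, the canonical defaults). M and A
are computed on column-total-relative abundances with pairwise exclusion
of zeros/missing; the factor is the inverse-asymptotic-variance-weighted
mean of the doubly rank-trimmed M, and factors are rescaled to product 1.
The `auto` reference is the sample whose upper-quartile relative
abundance is closest to the mean of upper quartiles. `min_retained`
(default 10) guards against over-trimming tiny matrices; the brute-force
oracle test lowers it for an 8-gene toy.

**ComBat.** Parametric empirical Bayes exactly as in the standard
location/scale algorithm: per-gene standardisation by the fitted mean
(including declared biological covariates) and pooled variance (divisor
n); per-batch location/scale estimates (scale with divisor n_b − 1);
normal / inverse-gamma priors with method-of-moments hyperparameters;
joint posterior by iteration to relative tolerance 1e-4. The test suite
pins the implementation to frozen `sva::ComBat` reference outputs (agrees
to ~1e-14). Two consequences worth knowing:

* with identical batches the output is *not* the identity — the n_b/(n_b−1)
  variance-convention mismatch rescales residuals by √((n_b−1)/n_b),
  exactly as the reference does;
* a single batch is returned unchanged, and a batch confounded with the
  covariates is rejected by a rank check.

By default ComBat sees fibre type, timepoint and training as covariates
so the adjustment cannot absorb biology; a covariate-free mode exists
because plexes mix all conditions by construction.

**Moderated t.** Hyperparameters (d₀, s₀²) by moment matching of log s²
against the scaled-F log-moments (digamma/trigamma, Newton inversion of
the trigamma). d₀ = 0 reproduces the ordinary t; a degenerate variance
distribution yields d₀ = ∞ (complete pooling) rather than an error.
Significance uses `p_adj < alpha` alone; the 0.2 log2FC bound is a
display label, not a significance gate. BH is applied per contrast
family. p-values are floored at the smallest positive double before
log10 in the fusion score.

**Fusion scheme.** π = |log2FC|·(−log10 p) with p from an ordinary
paired t-test. The null is built by sign-flipping within-pair
differences — all 2ⁿ patterns when n ≤ 12 pairs, otherwise `n_perm`
seeded draws — and the fusion significance is the fraction of null π at
least as large as observed. The sign-flip construction is this package's
explicit definition of the permutation null; the identity pattern is
included, so the smallest attainable significance is 2·2⁻ⁿ.

**MPE** is computed on SL-normalised intensities: SL removes loading
artefacts while preserving within-sample composition, and MPE is in any
case invariant to per-sample scaling. Mean mitochondrial protein
expression comparisons default to normalised log2 values.

**Mitochondrial renormalisation** re-runs the full chain on the raw-scale
mitochondrial subset (not a log-scale mean subtraction): equalising
per-channel mitochondrial totals removes a global content multiplier *by
construction*, which is the cleanest statement of what the correction
does and does not do — genuine per-protein remodelling survives it,
shared content does not.

**Profiles.** z-scores are computed within each comparison's own sample
set (one training group × one fibre type, PRE + POST), because the
Δ mean z panels are per-cell; the tested trace is the per-sample mean
over group members (participant as pairing unit), not averaged
per-protein tests. BH runs across the displayed family. Cells with < 3
pairs or zero-variance differences report `p = NA` instead of failing.

## Synthetic cohorts

Defaults emulate the target study geometry: 16 participants (8 MICT,
8 SIT), 64 pool samples in four 16-channel plexes (each plex holds 4
participants with all four of their condition pools, so batches mix
conditions), 2000 proteins of which 25% are mitochondrial (≈ the observed
391/1600). Baseline log2 intensity ~ N(16, 2²); residual variances from a
scaled inverse-χ² (s₀ = 0.3, d₀ = 4), the same family the moderation
model assumes; 15% of proteins carry a fibre-type effect ~ N(0, 0.6²);
5% per cell carry a training effect ~ N(0, 0.4²); default mitochondrial
content ratio 1.5 (type I : type II). Batch effects (γ ~ N(0, 0.3),
log δ ~ N(0, 0.1)) and channel loading (log2 ℓ ~ N(0, 0.2)) are
generator fixtures chosen at realistic magnitudes, not estimates of any
study. Missingness is logistic on log2 intensity (intercept 5, slope
−0.5 → ~5–8% missing, concentrated at low abundance) plus a 0.5% uniform
rate.

One seeded generator drives each cohort; identical (params, seed) give a
bit-identical cohort, and the realised truth (every β, γ, δ, ℓ, σ, the
content multipliers and the mitochondrial flags) is returned and written
alongside the data for recovery tests.

What the generator does **not** emulate: fibre-level pooling variance
(pools are the sampling unit), reporter-ion interference, peptide-to-
protein roll-up, correlated protein modules beyond the planted group
effects, and missingness mechanisms other than intensity censoring plus
uniform dropout. Passing recovery tests therefore demonstrate that the
pipeline removes the artefacts it models — not that real single-fibre
data contain no others.

## Problem sizes in tests and the acceptance script

Power-style simulations in the unit suite are scaled-down versions of
the package's own experiments (typically 10–20 replicates, 250–2000
proteins), chosen to keep the default test run fast while leaving the
assertions comfortably inside the simulated power; the FDR calibration
study uses 100 cohorts of 2000 proteins and 8 pairs, and the
content-recovery experiment 1000-protein cohorts with the full 64-sample
design. The acceptance script runs 3 recovery cohorts and reports means.

## Known limitations

* Non-parametric ComBat and reference-channel (bridge) normalisation are
  not implemented.
* The fusion scheme's null is defined here by sign-flipping; other
  published fusion constructions differ in the null and the constant.
* Enrichment is a generic Fisher test over user-supplied term maps; no
  ontology is bundled and no network queries are made.
* With ~16 channels per plex the ComBat location estimates carry a
  standard error of roughly σ_g/4, which bounds how well small batch
  effects can be recovered regardless of protein count.
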