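# Methods

This note documents the statistical model behind `reprotraj`, the choices
made where the design was genuinely open, and what the synthetic-data
validation does and does not demonstrate.

## Data model and preprocessing

The unit of data is a single cell's panel of qPCR cycle-threshold (Ct)
values over ~48 genes including the GAPDH normalizer. Ct = 40 encodes an
undetected transcript; values above 40 in instrument exports are clamped to
40 with a warning. Cells with GAPDH Ct ≥ 25 are removed as technical
failures. Quantitative expression is the inverted normalized value
40 − ΔCt = 40 − (Ct_gene − Ct_GAPDH), defined only for detected entries;
quantitative analyses that need a complete matrix fill undetected entries
with level 0 (`undetected_level_policy="zero"`). Qualitative analyses use
the binary detection matrix (1 iff Ct < 40).

## Progression axis

Reprogramming progress is estimated per cell from its binary profile's
relation to two anchor populations — untransduced fibroblasts (FIB) and
hESCs (PLURI):

* d_fib, d_pluri: mean Euclidean distance from the cell to every member of
  the anchor group, self-comparisons excluded;
* d_fp: mean distance over all FIB×PLURI profile pairs; d_self: mean over
  distinct within-group pairs;
* similarity to a group: (d_fp − d_cell)/(d_fp − d_self) — 1 when the cell
  sits inside the group's own dispersion, 0 when it is as far away as the
  opposite anchor (not clamped: extreme cells may exceed [0, 1]);
* progression: (sim_pluri + (1 − sim_fib))/2;
* off-trajectory distance: perpendicular distance of (sim_fib, sim_pluri)
  to the diagonal sim_fib + sim_pluri = 1, i.e. |sim_fib + sim_pluri − 1|/√2.
  The diagonal reading of "distance off the trajectory" is one of several
  possible projections; it is isolated in `off_trajectory_distance` and
  trivially replaceable.

The ceil(0.10·n) cells with the largest off-trajectory distance are flagged
as outliers (ties broken by stable cell-id order) and excluded from model
fitting. Alternate-trajectory (Alt) cells — identified by the SOM partition
— are additionally excluded from productive-trajectory analyses
(regression, correlation). Progression is clamped to [0, 1] for binning
only; the raw coordinate is preserved and the number of clamped cells
reported.

## Grouping

PCA is column-centered with no unit-variance scaling (scaling is a config
switch), on filled (40 − ΔCt) levels. The 5-unit, one-dimensional
self-organizing map is batch-trained on (PC1, PC2) with a Gaussian
neighborhood whose radius decays linearly over 500 epochs from half the
chain length, initialized from evenly spaced PC1 quantiles — deterministic
given the data; an exact k-means fallback (`method="kmeans"`) is provided
because a 5×1 SOM on 2-D scores behaves like constrained k-means. Units are
relabeled after training: the unit whose members have the largest mean
off-trajectory distance becomes Alt, and the rest are labeled Fib, Early,
Late, Pluri in order of mean progression (so the group-progression
monotonicity holds by construction; what is tested end-to-end is whether
the partition recovers the true branch structure). Ward clustering runs on
unscaled levels via scipy's linkage and is exported as Newick.
Between-group differential expression uses Tukey–Kramer
(unequal-n honest-significant-difference) contrasts per gene at α = 0.05;
groups with fewer than two cells are skipped with a warning.

## Activation-curve models

For each gene, detection frequency along the progression axis is estimated
in `n_bins = 25` overlapping bins of width 0.08 whose centers span [0, 1]
(bins truncated at the range ends; empty bins are skipped). Three nested
models predict frequency f(x):

* uniform (null, k = 2): a straight line between a baseline value at x = 0
  and an endpoint value at x = 1. Each anchor is the line through the
  count-weighted (x, frequency) centroids of the bins within 0.15 of the
  two ends, evaluated at the end and clipped to [0, 1]. This estimator is
  exact for linear frequency curves and pools a window of bins, which
  matters: a single-bin anchor is noisy enough that truly linear genes
  would spuriously prefer the Gaussian model.
* gauss1 (k = 4): f(x) = baseline + amplitude·Φ((x − μ)/σ), the cumulative
  of a Gaussian "activation window"; amplitude < 0 describes inactivating
  genes.
* gauss2 (k = 7): two cumulative-normal components, for transient
  (up-then-down) dynamics.

Gaussian models are fitted by Nelder–Mead minimisation of the unweighted
MSE over non-empty bins (count-weighted MSE is a config option), with σ
parameterized on the log scale, a quadratic penalty keeping f within
[0, 1] on a 41-point grid and amplitudes within [−1, 1], and multi-start:
9 starts (μ ∈ {0.25, 0.5, 0.75} × σ ∈ {0.05, 0.15, 0.4}) for gauss1, 8
two-component starts for gauss2 plus the gauss1 optimum with a zero second
amplitude — which preserves the nesting mse(gauss2) ≤ mse(gauss1) up to
optimizer tolerance. Tolerances: xatol 1e-6, fatol 1e-10, maxfev 2000
(gauss1) / 4000 (gauss2).

Model comparison uses the least-squares small-sample Akaike score
AICc = n_eff·ln(MSE) + 2k + 2k(k+1)/(n_eff − k − 1), selecting the minimum.
n_eff is the *effective* number of independent sample points: overlapping
bins share cells, so n_eff defaults to range/bin_width = 12.5, the
non-overlapping-equivalent bin count, not the raw bin count. The binning
defaults were chosen together with this rule: n_eff must exceed k + 1 = 8
for the seven-parameter model to be scorable at all, and sensitivity
simulations at 1,000-cell scale show the (25, 0.08) layout selects the
generating class reliably (sigmoidal → gauss1, linear → uniform retained
within ΔAICc ≤ 2, transient → gauss2) where wider bins (e.g. width 0.15)
either leave gauss2 unscorable or let the flexible models absorb the
strongly autocorrelated bin noise. A `n_eff_policy="bins"` option restores
the raw count. The activation window reported for gauss1 fits is μ with
central 50% (μ ± 0.6745σ) and 95% (μ ± 1.96σ) intervals, unclipped.

### Lack-of-fit testing

Two related tests are provided, and the distinction matters:

* `lack_of_fit_ftest` — single-shot. Cells are grouped into 10
  non-overlapping progression bins; with N_i cells, observed frequency
  p̂_i and mean model prediction m_i in bin i, the statistic is
  F = Σ_i (p̂_i − m_i)²/(m_i(1 − m_i)/N_i) / B against the
  F(B, Σ(N_i − 1)) critical value. Standardizing each bin by the binomial
  variance the model implies handles the strong frequency dependence of the
  pure error; the numerator dof is B (not B − k) because the model is held
  fixed, not refit, when the test is applied. Under data generated from the
  fitted model the rejection rate is the nominal α (measured 0.045–0.056 at
  α = 0.05 over 1,000–2,000 replicate datasets).
* `bootstrap_ftest` — the resampling percentage: cells are repeatedly
  resampled with replacement within each bin (equivalent to binomial draws,
  which is how it is vectorized; per-bin variance gains a second sampling
  layer, 1/N_i + 1/n_i) and the fraction of replicates rejecting is
  reported per gene. Because all replicates share the one observed
  dataset's noise realization, this percentage is a *stability summary*:
  conditional on an unlucky sample it sits far from α even when the model
  is true. It ranks genes usefully (a step-shaped gene rejects the linear
  null in >95% of replicates) but calibration statements must use the
  single-shot test on independent datasets.

## Co-expression against the independence null

Observed correlations are Pearson r between detection indicators over the
analyzed cells (non-outlier, non-Alt), excluding genes detected in <5% or
>95% of cells (in the default panel this removes NR0B1 and REST, which are
simulated as low-detection genes). The background each pair owes to the
shared axis is estimated by simulation: progression values resampled with
replacement from the observed set, each gene drawn independently from its
fitted frequency curve — using each gene's AICc-*selected* model, because a
monotone gauss1 curve mis-states the background of a transient gene — and
r averaged over runs (default 1,000; the convergence is ~1/√runs). The
corrected value is r_obs − r_null.

Significance is the one place the implementation departs from the field's
standard recipe, for calibration reasons established empirically:

* the classical Fisher z two-sample test (kept as `method="fisher"`) is
  ~4× conservative here — detection indicators are Bernoulli mixtures over
  the shared axis, and 1/(n − 3) overstates the sampling variance of r;
* even the Monte-Carlo spread of the model-simulated null is conservative,
  because curves fitted to the same data absorb the marginal component of
  each pair's correlation noise;
* the calibrated reference is a *stratified permutation*: each gene's
  detections are permuted among cells within 20 narrow progression strata,
  preserving the gene's realized profile along the axis exactly while
  destroying any dependence beyond it. z = (r_obs − mean_perm)/sd_perm is
  approximately standard normal under independence-given-progression
  (measured type-I 0.043–0.053 at α = 0.05).

Pairs are flagged after Benjamini–Hochberg control across pairs (`--no-mtc`
reproduces uncorrected calls).

## Synthetic data: what it emulates, and what it does not

The generator emulates the structure of a real OSKM single-cell qPCR
study: ~170 cells
(20 FIB, 100 intermediates with latent progression p ~ U(0, 1) by default —
an arbitrary progression distribution can be supplied — 30 alternate-branch
cells, 20 PLURI), a 48-gene four-category panel (10 fibroblast-associated
inactivating genes, 20 pluripotency-associated activating genes including
two simulated low-detection genes, 8 intermediate markers of which 2 are
transient, 9 chromatin modifiers activating early, plus GAPDH), detection
probabilities following baseline + amplitude·Φ((p − μ)/σ) curves (a second
component for transient genes), quantitative levels Gaussian in (40 − ΔCt)
around 21–28 with SD 1.5, GAPDH Ct ~ N(18, 1) and a 5% injected QC-failure
fraction. Alternate-branch cells use flat per-gene probabilities — low for
pluripotency and chromatin genes (0.05) and reduced for fibroblast genes
(0.25), placing them away from both anchors as the alternate trajectory is
described. Conditional on p, genes are independent Bernoulli draws — the
independence null — unless a co-regulated module is configured, in which
case member genes share a per-cell latent switch (flip probability 0.05),
the positive control. Generation is bit-reproducible under a fixed seed.

Validation studies place 1/7 of cells at each axis end (the anchor masses
real training data always has) and 5/7 spanning the axis; the correlation
calibration and module-detection studies use 600 cells so that
transient-gene curve shapes are resolvable.

What passing tests do *not* show about real data:

* Real progression is estimated, not latent. When the axis is built from
  the same detection matrix, residual latent progression induces extra
  same-sign dependence beyond the independent-given-axis null, so at the
  real study's scale (~120 analyzed cells) the corrected-correlation
  analysis over-flags pairs of steep same-direction genes; transient genes
  are also liable to receive monotone curves at that scale, mis-stating
  their background. These are limitations of the design itself, shared
  with any analysis that conditions on an axis estimated from the data
  being tested; the calibration results here are conditional on the true
  progression.
* The generator draws levels unimodally given detection; real intermediate
  populations show richer level structure (the detected/undetected mixture
  reproduces bimodality, but not multi-modal detected levels).
* No cell-cycle structure, amplification-efficiency variation, or
  multi-plate batch effects are simulated.

## Degenerate inputs and numerical edges

Anchors closer to each other than their internal dispersion raise a
degenerate-anchor error; groups emptied by self-exclusion raise; constant
expression matrices are rejected by PCA; genes whose fitted model predicts
exactly 0 or 1 in a bin contribute zero (if the data agree) or infinite
(if not) lack-of-fit; r = ±1 is clamped at 1 − 1e−12 before the Fisher
transform; empty SOM units are reported and skipped in labeling; all bins
empty raises. Every stochastic stage takes an explicit seed and the
pipeline manifest records a configuration hash plus every filter count
(loaded = QC-passed + QC-rejected, outliers, Alt-excluded, correlation
cells), so a run is reproducible from the manifest alone.

## Problem sizes used in the validation suite

Per-gene model studies use 1,000 cells; selection accuracy uses 30 genes
per class; F-test calibration uses 1,000 replicate datasets; correlation
calibration uses two 600-cell replicates (2,070 pairs) plus one
module-injected replicate; trajectory fidelity uses 740 cells (500
productive intermediates, 200 alternate); the outlier-rule check uses the
170-cell default configuration.
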