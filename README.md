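# reprotraj

Single-cell qPCR analysis of somatic-cell reprogramming to pluripotency.

When human fibroblasts are transduced with the Yamanaka factors (OCT4, SOX2,
KLF4, c-MYC), single cells pass through a prolonged "stochastic" phase in
which pluripotency genes appear to switch on at random. `reprotraj`
implements a quantitative framework for asking whether that phase is truly
random: it orders partially reprogrammed cells on a fibroblast→hESC
progression axis built from binary transcript-detection profiles, models
each gene's detection probability along that axis, and tests whether any
gene pair is co-expressed beyond what the shared axis explains.

The core pieces:

* **Progression axis.** Each cell's 0/1 detection profile (Ct < 40) is
  compared with fibroblast (FIB) and hESC (PLURI) anchor groups. With
  `d_fp` the mean FIB↔PLURI profile distance and `d_self` a group's mean
  within-group distance, the similarity of a cell at distance `d` to a group
  is `(d_fp − d)/(d_fp − d_self)`; its progression is
  `(sim_PLURI + (1 − sim_FIB))/2` and its off-trajectory coordinate is
  `|sim_FIB + sim_PLURI − 1|/√2`. The top 10% by off-trajectory distance are
  flagged as outliers; a 5×1 self-organizing map on (PC1, PC2) partitions
  cells into Fib/Early/Late/Pluri plus an alternate-trajectory (Alt) group.
* **Activation-curve models.** A gene's detection frequency f(x) along the
  axis is estimated in overlapping bins and fitted with three nested models:
  a straight line anchored at the axis ends (random gradual change — the
  null), `f(x) = b + a·Φ((x − μ)/σ)` (a Gaussian activation window centered
  on the point of greatest change; a < 0 for inactivating genes), and a
  two-component version for transient genes. Models are compared by
  small-sample corrected Akaike score
  `AICc = n·ln(MSE) + 2k + 2k(k+1)/(n−k−1)` and checked with a
  lack-of-fit F-test against binomial pure error.
* **Independence-null co-expression.** Simulated populations in which every
  gene follows its fitted curve but genes are otherwise independent give
  the background correlation each pair owes to the shared axis; the
  background-corrected excess `r_obs − r_null` is tested against a
  stratified-permutation reference and flagged after Benjamini–Hochberg
  control.
* **Synthetic data.** A generator produces qPCR-like Ct tables (~170 cells,
  48-gene panel in four marker classes, GAPDH normalizer, injected QC
  failures, a productive and an alternate branch) with known latent
  progression and per-gene dynamics, so every stage is verifiable against
  ground truth — including an optional co-regulated gene module that
  violates the independence null on purpose.

## Worked example

```python
from reprotraj import simulate, io
from reprotraj.trajectory import ReprogrammingTrajectory

cfg = simulate.default_config(seed=11)          # ~170 cells, 48-gene panel
ct, ann, truth = simulate.generate_dataset(cfg)
m, rejected = io.qc_filter(io.ExpressionMatrix(ct, ann))
res = ReprogrammingTrajectory.from_expression(m).fit(outlier_fraction=0.10)
print(f"QC rejected {len(rejected)} cells")
print(res.summary())
```

```
QC rejected 6 cells
Reprogramming trajectory fit
  cells: 164   genes: 47
  anchor separation d_fp = 5.913 (within-FIB 2.696, within-PLURI 2.502)
  progression range: -0.092 .. 1.100 (37 outside [0,1])
  outliers flagged: 17 (top 10% by off-trajectory distance)
```

Six of the 170 simulated cells failed the GAPDH quality cut (Ct ≥ 25). The
anchor groups are much farther from each other (5.91) than internally
dispersed (≈2.6), so the similarity ratios are well defined; cell
progressions span slightly beyond [0, 1] (extreme cells are not clamped)
and 17 of the 164 analyzed cells — the 10% farthest off the FIB→PLURI
diagonal — are flagged as outliers before model fitting.

Fitting one gene's activation curve along the axis:

```python
from reprotraj.activation import ActivationCurveModel, bin_frequencies, select_model

prog = res.clamped_progression()[~res.coords["outlier"]]
det = m.binary().loc[prog.index, "CDH1"]
fits = ActivationCurveModel(bin_frequencies(det, prog, gene="CDH1")).fit_all()
print(fits["gauss1"].summary())
print("chosen:", select_model(fits)[0])
```

```
CDH1: gauss1 model  (k=4, MSE=0.00867, AICc=-46.02)
  baseline frequency 0.075
  component: amplitude +0.925, midpoint 0.580, spread 0.116
chosen: gauss1
```

CDH1 is read as an activating gene whose detection probability rises from
~8% to ~100% in a window centered at progression 0.58 — the
single-Gaussian model beats both the linear null and the two-component
model on AICc. (The generator's true midpoint for CDH1 is 0.50; at ~150
analyzed cells the estimate carries that much sampling error.)

The full pipeline (`reprotraj run-all --seed 1 --outdir out/`, or
`reprotraj.pipeline.run_pipeline`) chains QC → trajectory → PCA/SOM/Ward
grouping → activation models → correlation analysis and writes per-stage
CSVs plus a JSON manifest with every filter count.

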