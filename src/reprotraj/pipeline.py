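"""End-to-end orchestration: QC -> trajectory -> grouping -> activation
models -> correlation null, with per-stage CSV outputs and a JSON manifest.

Every filter step's counts are reported (loaded, QC-passed, outliers,
Alt-excluded) and every stochastic stage takes an explicit seed; a hash of
the configuration is stamped into the manifest so a run can be reproduced
from the manifest alone.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import activation, correlation, grouping, io, simulate, trajectory

log = logging.getLogger("reprotraj")


@dataclasses.dataclass
class PipelineConfig:
    """Configuration of one full analysis run."""

    # input: either a Ct table on disk or a synthetic-data config
    ct_table: str | None = None
    panel_csv: str | None = None
    sim: simulate.SimConfig | None = None

    outdir: str = "reprotraj_out"
    gapdh_ct_max: float = 25.0
    outlier_fraction: float = 0.10
    fib_group: str = "FIB"
    pluri_group: str = "PLURI"
    undetected_level_policy: str = "zero"

    n_bins: int = 25
    bin_width: float = 0.08
    ftest_reps: int = 200
    ftest_bins: int = 10
    null_runs: int = 1000
    alpha: float = 0.05
    mtc: str = "bh"
    min_detect_frac: float = 0.05
    som_units: int = 5
    seed: int = 0

    def config_hash(self) -> str:
        payload = {k: v for k, v in dataclasses.asdict(self).items()
                   if k != "sim"}
        if self.sim is not None:
            payload["sim"] = {
                "seed": self.sim.seed,
                "n_cells_per_group": self.sim.n_cells_per_group,
                "genes": [g.name for g in self.sim.genes],
                "qc_fail_fraction": self.sim.qc_fail_fraction,
            }
        return hashlib.sha256(
            json.dumps(payload, sort_keys=True, default=str).encode()
        ).hexdigest()[:16]


def run_pipeline(cfg: PipelineConfig) -> dict:
    """Run every stage; returns the manifest dict (also written to disk)."""
    outdir = Path(cfg.outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    manifest: dict = {"config_hash": cfg.config_hash(), "seed": cfg.seed,
                      "counts": {}, "outputs": {}}

    def save(df: pd.DataFrame, name: str, **kw):
        path = outdir / name
        df.to_csv(path, **kw)
        manifest["outputs"][name] = str(path)

    # ---- stage 1: load or simulate -------------------------------------
    if cfg.sim is not None:
        ct, ann, truth = simulate.generate_dataset(cfg.sim)
        simulate.write_dataset(ct, ann, truth, outdir)
        m = io.ExpressionMatrix(ct, ann, normalizer=cfg.sim.normalizer)
        panel = cfg.sim.panel()
    elif cfg.ct_table is not None:
        panel = (None if cfg.panel_csv is None
                 else io.GenePanel.from_csv(cfg.panel_csv))
        m = io.load_ct_table(cfg.ct_table, panel)
    else:
        raise ValueError("config needs either ct_table or sim")
    manifest["counts"]["loaded"] = len(m)
    log.info("loaded %d cells x %d genes", len(m), len(m.gene_ids))

    # ---- stage 2: QC + normalization -----------------------------------
    m, rejected = io.qc_filter(m, cfg.gapdh_ct_max)
    manifest["counts"]["qc_rejected"] = len(rejected)
    manifest["counts"]["qc_passed"] = len(m)
    log.info("QC: %d passed, %d rejected (GAPDH Ct >= %g)",
             len(m), len(rejected), cfg.gapdh_ct_max)
    io.qc_report(m, rejected, outdir / "qc_report.json")
    manifest["outputs"]["qc_report.json"] = str(outdir / "qc_report.json")
    levels = m.level_filled(cfg.undetected_level_policy)[m.analysis_genes]
    binary = m.binary()[m.analysis_genes]
    save(m.annotations.join(m.ct), "cleaned_ct.csv")

    # ---- stage 3: trajectory -------------------------------------------
    traj = trajectory.ReprogrammingTrajectory.from_expression(
        m, cfg.fib_group, cfg.pluri_group).fit(cfg.outlier_fraction)
    save(traj.coords, "trajectory.csv")
    manifest["counts"]["outliers"] = int(traj.coords["outlier"].sum())
    manifest["counts"]["progression_clamped"] = traj.n_clamped
    log.info("%s", traj.summary())

    # ---- stage 4: grouping ---------------------------------------------
    ord_res = grouping.run_pca(levels)
    save(ord_res.scores, "pca_scores.csv")
    pd.DataFrame({"variance_fraction": ord_res.variance_fractions}).to_csv(
        outdir / "pca_variance.csv", index_label="component")
    manifest["outputs"]["pca_variance.csv"] = str(outdir / "pca_variance.csv")
    som = grouping.som_partition(
        ord_res.scores, traj.progression, traj.coords["off_distance"],
        n_units=cfg.som_units, seed=cfg.seed)
    save(som.to_frame(), "som_groups.csv")
    manifest["counts"]["som_groups"] = som.value_counts().to_dict()

    Z = grouping.ward_cluster(levels)
    (outdir / "ward_dendrogram.nwk").write_text(
        grouping.linkage_to_newick(Z, levels.index))
    manifest["outputs"]["ward_dendrogram.nwk"] = str(outdir / "ward_dendrogram.nwk")

    productive = som.index[som != "Alt"]
    slope, intercept, r2 = grouping.productive_regression(
        ord_res.scores, productive)
    manifest["productive_regression"] = {
        "slope": slope, "intercept": intercept, "r_squared": r2}
    manifest["pc12_variance_fraction"] = ord_res.pc12_variance()

    tukey = grouping.tukey_gene_ranking(levels, som, alpha=cfg.alpha)
    save(tukey, "tukey_ranking.csv")
    edges = grouping.top_correlation_edges(levels.loc[traj.non_outliers()])
    save(edges, "network_edges.csv", index=False)

    # ---- stage 5: activation models ------------------------------------
    # model fitting excludes outliers; productive-trajectory analyses
    # exclude Alt cells
    fit_cells = [c for c in traj.non_outliers()]
    prog = traj.clamped_progression().loc[fit_cells]
    curves = {
        g: activation.bin_frequencies(
            binary.loc[fit_cells, g], prog, gene=g,
            bin_width=cfg.bin_width, n_bins=cfg.n_bins)
        for g in binary.columns
    }
    all_fits = activation.fit_all_genes(curves, seed=cfg.seed)
    models = activation.fit_gene_table(
        curves, seed=cfg.seed, detections=binary.loc[fit_cells],
        progressions=prog.to_numpy(), ftest_reps=cfg.ftest_reps,
        ftest_bins=cfg.ftest_bins, alpha=cfg.alpha, all_fits=all_fits)
    save(models, "activation_models.csv")
    manifest["counts"]["model_cells"] = len(fit_cells)
    manifest["model_selection"] = models["chosen"].value_counts().to_dict()

    windows = []
    for g, row in models.iterrows():
        mu, (l50, h50), (l95, h95) = activation.activation_window(
            activation.ActivationFit(
                gene=g, kind="gauss1", baseline=row["baseline"],
                components=[(row["amplitude"], row["mu"], row["sigma"])],
                endpoint=None, mse=row["mse_gauss1"], k=4, n_eff=1e9))
        windows.append({"gene": g, "mean": mu, "lo50": l50, "hi50": h50,
                        "lo95": l95, "hi95": h95,
                        "direction": "activating" if row["amplitude"] > 0
                        else "inactivating"})
    save(pd.DataFrame(windows).set_index("gene").sort_values("mean"),
         "activation_windows.csv")

    # ---- stage 6: correlation vs independence null ---------------------
    corr_cells = [c for c in traj.non_outliers() if som.get(c) != "Alt"]
    manifest["counts"]["correlation_cells"] = len(corr_cells)
    obs, excluded = correlation.observed_correlation(
        binary.loc[corr_cells], cfg.min_detect_frac)
    # null curves from each gene's AICc-selected model (a gauss1 curve
    # cannot represent transient genes; using the selected model keeps the
    # simulated background faithful)
    fits = {g: all_fits[g][models.loc[g, "chosen"]] for g in obs.columns}
    corr_prog = traj.clamped_progression().loc[corr_cells]
    null = correlation.null_correlation(
        corr_prog, fits, runs=cfg.null_runs, seed=cfg.seed + 1)
    # significance reference: stratified permutation (conditional null given
    # each gene's realized profile along the axis)
    perm_mean, perm_sd = correlation.permutation_null(
        binary.loc[corr_cells, null.columns], corr_prog,
        perms=min(cfg.null_runs, 400), seed=cfg.seed + 2)
    res = correlation.corrected_correlation(
        obs, null, n_obs=len(corr_cells), runs=cfg.null_runs,
        sig_mean=perm_mean, sig_sd=perm_sd, alpha=cfg.alpha, mtc=cfg.mtc,
        excluded=excluded)
    save(res.table, "correlation_pairs.csv", index=False)
    save(res.corrected, "correlation_corrected_matrix.csv")
    manifest["counts"]["correlation_genes_excluded"] = excluded
    manifest["counts"]["significant_pairs"] = int(
        res.table["significant"].sum())

    (outdir / "manifest.json").write_text(json.dumps(manifest, indent=1,
                                                     default=str))
    log.info("pipeline complete; manifest at %s", outdir / "manifest.json")
    return manifest
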