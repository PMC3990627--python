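"""Synthetic single-cell qPCR data with known latent reprogramming progression.

Each simulated cell carries a latent progression value ``p`` on the
fibroblast -> hESC axis (0 = fibroblast, 1 = pluripotent). Every gene has a
detection-probability curve along that axis,

    f(p) = baseline + (end - baseline) * Phi((p - mu) / sigma)
           [+ amp2 * Phi((p - mu2) / sigma2)   for transient genes]

with ``Phi`` the standard normal CDF: detection probability changes
sigmoidally around a gene-specific midpoint ``mu`` with spread ``sigma``.
Conditional on ``p``, gene detections are independent Bernoulli draws, which
is exactly the independence null of the downstream co-expression analysis.
An optional co-regulated module (genes sharing a per-cell latent switch)
provides the positive control that violates it.

Cells on the "alternate" branch ignore ``p`` and use a flat per-gene
detection probability (``alt_freq``), emulating cells moving away from both
the fibroblast and the pluripotent profile.

Detected transcripts get a quantitative level in (40 - dCt) units drawn
around ``expr_mean_on``; the generator then back-computes raw Ct values so
the emitted table looks like an instrument export (Ct = 40 encodes
"undetected"). GAPDH is always detected; a configurable fraction of cells is
emitted with GAPDH Ct >= 25 to exercise the QC filter.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd
import yaml
from scipy.stats import norm

from .panel import GenePanel

__all__ = [
    "GeneSimParams",
    "SimConfig",
    "LatentTruth",
    "true_frequency",
    "generate_dataset",
    "default_gene_params",
    "default_config",
]


@dataclasses.dataclass
class GeneSimParams:
    """Ground-truth dynamics of one gene along the progression axis.

    ``baseline_freq``/``end_freq`` are detection probabilities at progression
    0 and 1; ``mu``/``sigma`` locate and scale the sigmoidal transition.
    ``amp2``/``mu2``/``sigma2`` add an optional second cumulative-normal
    component for transient (up-then-down) dynamics. ``alt_freq`` is the flat
    detection probability on the alternate branch.
    """

    name: str
    category: str
    baseline_freq: float
    end_freq: float
    mu: float
    sigma: float
    expr_mean_on: float = 24.0
    expr_sd: float = 1.5
    alt_freq: float = 0.1
    amp2: float = 0.0
    mu2: float = 0.7
    sigma2: float = 0.1

    def __post_init__(self):
        for attr in ("baseline_freq", "end_freq", "alt_freq"):
            v = getattr(self, attr)
            if not 0.0 <= v <= 1.0:
                raise ValueError(f"{self.name}: {attr}={v} outside [0, 1]")
        if self.sigma <= 0 or self.sigma2 <= 0:
            raise ValueError(f"{self.name}: sigma must be > 0")
        if self.expr_sd < 0:
            raise ValueError(f"{self.name}: expr_sd must be >= 0")
        grid = np.linspace(0.0, 1.0, 201)
        f = true_frequency(self, grid)
        if f.min() < -1e-9 or f.max() > 1 + 1e-9:
            raise ValueError(
                f"{self.name}: implied frequency curve leaves [0, 1] "
                f"(range {f.min():.3f}..{f.max():.3f})"
            )


def true_frequency(g: GeneSimParams, p):
    """Detection probability of gene ``g`` at progression ``p`` (closed form)."""
    p = np.asarray(p, dtype=float)
    if np.any(p < 0) or np.any(p > 1):
        raise ValueError("progression must lie in [0, 1]")
    if g.sigma <= 0:
        raise ValueError("sigma must be > 0")
    f = g.baseline_freq + (g.end_freq - g.baseline_freq) * norm.cdf(
        (p - g.mu) / g.sigma
    )
    if g.amp2 != 0.0:
        f = f + g.amp2 * norm.cdf((p - g.mu2) / g.sigma2)
    return f if f.ndim else float(f)


@dataclasses.dataclass
class SimConfig:
    """Configuration of one synthetic dataset.

    ``n_cells_per_group`` gives counts for the four harvest groups:
    untransduced fibroblasts (FIB), productive intermediates (INT),
    alternate-branch cells (ALT) and pluripotent anchors (PLURI).
    """

    genes: list[GeneSimParams]
    n_cells_per_group: dict[str, int] = dataclasses.field(
        default_factory=lambda: {"FIB": 20, "INT": 100, "ALT": 30, "PLURI": 20}
    )
    gapdh_ct_mean: float = 18.0
    gapdh_ct_sd: float = 1.0
    qc_fail_fraction: float = 0.0
    seed: int = 0
    normalizer: str = "GAPDH"
    # genes sharing a per-cell latent on/off switch (co-expression positive
    # control); empty under the independence null
    coregulated_module: list[str] = dataclasses.field(default_factory=list)
    module_flip_prob: float = 0.05
    # progression distribution for INT cells: "uniform" or an explicit callable
    # rng -> array (used for sensitivity analyses)
    progression_sampler: object = "uniform"

    def __post_init__(self):
        if not self.genes:
            raise ValueError("gene list must not be empty")
        if any(n < 0 for n in self.n_cells_per_group.values()):
            raise ValueError("group counts must be >= 0")
        if not 0.0 <= self.qc_fail_fraction <= 1.0:
            raise ValueError("qc_fail_fraction must lie in [0, 1]")
        names = [g.name for g in self.genes]
        if len(set(names)) != len(names):
            raise ValueError("duplicate gene names in panel")
        unknown = set(self.coregulated_module) - set(names)
        if unknown:
            raise ValueError(f"coregulated_module genes not in panel: {sorted(unknown)}")

    def panel(self) -> GenePanel:
        return GenePanel(
            {g.name: g.category for g in self.genes}, normalizer=self.normalizer
        )


@dataclasses.dataclass
class LatentTruth:
    """Ground truth per simulated cell: latent progression, branch label and
    the per-gene detection probabilities actually used."""

    cell_ids: list[str]
    progression: np.ndarray  # latent p in [0, 1]
    branch: list[str]  # "productive" | "alternate"
    detect_prob: pd.DataFrame  # cells x genes

    def to_json(self, path) -> None:
        obj = {
            "cell_ids": self.cell_ids,
            "progression": self.progression.tolist(),
            "branch": self.branch,
            "detect_prob": {
                g: self.detect_prob[g].tolist() for g in self.detect_prob.columns
            },
        }
        Path(path).write_text(json.dumps(obj))

    @classmethod
    def from_json(cls, path) -> "LatentTruth":
        obj = json.loads(Path(path).read_text())
        dp = pd.DataFrame(obj["detect_prob"], index=obj["cell_ids"])
        return cls(
            cell_ids=obj["cell_ids"],
            progression=np.asarray(obj["progression"], dtype=float),
            branch=obj["branch"],
            detect_prob=dp,
        )


def _sample_progressions(cfg: SimConfig, n: int, rng: np.random.Generator):
    if n == 0:
        return np.empty(0)
    if callable(cfg.progression_sampler):
        p = np.asarray(cfg.progression_sampler(rng, n), dtype=float)
        if p.shape != (n,) or p.min() < 0 or p.max() > 1:
            raise ValueError("progression_sampler must return n values in [0, 1]")
        return p
    if cfg.progression_sampler == "uniform":
        return rng.uniform(0.0, 1.0, size=n)
    raise ValueError(f"unknown progression sampler {cfg.progression_sampler!r}")


def generate_dataset(cfg: SimConfig):
    """Simulate one dataset.

    Returns
    -------
    (ct, annotations, truth)
        ``ct`` is a cells x genes DataFrame of Ct values (40 = undetected,
        normalizer column included), ``annotations`` a per-cell DataFrame with
        columns ``group``, ``day``, ``facs``, and ``truth`` a
        :class:`LatentTruth`. Deterministic under ``cfg.seed``.
    """
    rng = np.random.default_rng(cfg.seed)
    genes = cfg.genes
    gene_names = [g.name for g in genes]

    cells, progs, branches, groups = [], [], [], []
    for group in ("FIB", "INT", "ALT", "PLURI"):
        n = cfg.n_cells_per_group.get(group, 0)
        if group == "FIB":
            p = np.zeros(n)
        elif group == "PLURI":
            p = np.ones(n)
        elif group == "INT":
            p = _sample_progressions(cfg, n, rng)
        else:  # ALT: p recorded but unused by the flat alt_freq profile
            p = _sample_progressions(cfg, n, rng)
        for i in range(n):
            cells.append(f"{group}_{i:03d}")
            groups.append(group)
        progs.append(p)
        branches += ["alternate" if group == "ALT" else "productive"] * n
    prog = np.concatenate(progs) if progs else np.empty(0)
    n_cells = len(cells)

    # per-cell, per-gene detection probabilities
    probs = np.empty((n_cells, len(genes)))
    alt_mask = np.array([b == "alternate" for b in branches])
    for j, g in enumerate(genes):
        probs[:, j] = true_frequency(g, prog)
        probs[alt_mask, j] = g.alt_freq

    detected = rng.random(probs.shape) < probs

    # co-regulated module: a shared latent switch per cell overrides the
    # independent draws for member genes (with a small flip probability)
    if cfg.coregulated_module:
        idx = [gene_names.index(g) for g in cfg.coregulated_module]
        lead = genes[idx[0]]
        switch_p = true_frequency(lead, prog)
        switch_p[alt_mask] = lead.alt_freq
        switch = rng.random(n_cells) < switch_p
        for j in idx:
            flips = rng.random(n_cells) < cfg.module_flip_prob
            detected[:, j] = np.where(flips, ~switch, switch)

    gapdh_ct = rng.normal(cfg.gapdh_ct_mean, cfg.gapdh_ct_sd, size=n_cells)
    gapdh_ct = np.clip(gapdh_ct, 5.0, 24.5)
    fail = rng.random(n_cells) < cfg.qc_fail_fraction
    gapdh_ct[fail] = rng.uniform(25.0, 35.0, size=int(fail.sum()))

    # level (40 - dCt) -> raw Ct: ct = 40 + gapdh_ct - level, clamped into
    # the detectable range so "detected" entries always satisfy Ct < 40
    levels = np.empty_like(probs)
    for j, g in enumerate(genes):
        levels[:, j] = rng.normal(g.expr_mean_on, g.expr_sd, size=n_cells)
    ct = 40.0 + gapdh_ct[:, None] - levels
    ct = np.clip(ct, 5.0, 39.5)
    ct[~detected] = 40.0

    ct_df = pd.DataFrame(ct, index=cells, columns=gene_names)
    ct_df.insert(0, cfg.normalizer, gapdh_ct)
    ct_df.index.name = "cell_id"

    day = np.select(
        [np.array(groups) == "FIB", prog < 0.4, prog < 0.75],
        [0, 4, 8],
        default=14,
    )
    facs = np.select(
        [np.array(groups) == "FIB", np.array(groups) == "PLURI", prog < 0.6],
        ["none", "none", "SSEA4"],
        default="TRA-1-60",
    )
    ann = pd.DataFrame({"group": groups, "day": day, "facs": facs}, index=cells)
    ann.index.name = "cell_id"

    truth = LatentTruth(
        cell_ids=cells,
        progression=prog,
        branch=branches,
        detect_prob=pd.DataFrame(probs, index=cells, columns=gene_names),
    )
    return ct_df, ann, truth


def write_dataset(ct: pd.DataFrame, ann: pd.DataFrame, truth: LatentTruth, outdir):
    """Write the wide Ct CSV (annotations merged) and the ground-truth JSON."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    wide = ann.join(ct)
    wide.to_csv(outdir / "ct_table.csv")
    truth.to_json(outdir / "truth.json")
    return outdir / "ct_table.csv"


# --------------------------------------------------------------------------
# Default panel: a synthetic 48-gene, four-category marker panel (incl. the
# GAPDH normalizer) shaped like the published 48-gene qPCR panel. Dynamics
# parameters are invented but realistic: fibroblast genes inactivate,
# pluripotency genes activate at gene-specific midpoints, chromatin modifiers
# activate early and are lost on the alternate branch, and two intermediate
# markers are transient.
# --------------------------------------------------------------------------

_FIBROBLAST = [
    # name, baseline, end, mu, sigma
    ("COL1A1", 1.00, 0.02, 0.30, 0.10),
    ("COL1A2", 0.98, 0.02, 0.35, 0.12),
    ("COL5A2", 0.95, 0.05, 0.40, 0.15),
    ("FN1", 1.00, 0.10, 0.55, 0.20),
    ("THY1", 0.90, 0.02, 0.25, 0.08),
    ("S100A4", 0.92, 0.05, 0.45, 0.18),
    ("PRRX1", 0.88, 0.02, 0.30, 0.12),
    ("TWIST1", 0.85, 0.03, 0.20, 0.10),
    ("SNAI2", 0.90, 0.05, 0.50, 0.22),
    ("POSTN", 0.95, 0.02, 0.35, 0.10),
]

_PLURIPOTENCY = [
    ("POU5F1", 0.05, 0.98, 0.45, 0.15),
    ("SOX2", 0.02, 0.95, 0.60, 0.12),
    ("NANOG", 0.02, 0.95, 0.70, 0.06),
    ("LIN28A", 0.05, 0.98, 0.50, 0.15),
    ("ZFP42", 0.01, 0.92, 0.75, 0.05),
    ("DNMT3B", 0.05, 0.95, 0.40, 0.12),
    ("DPPA4", 0.02, 0.90, 0.65, 0.10),
    ("TDGF1", 0.05, 0.95, 0.55, 0.18),
    ("GDF3", 0.02, 0.88, 0.60, 0.15),
    ("SALL4", 0.10, 0.95, 0.35, 0.15),
    ("UTF1", 0.02, 0.90, 0.70, 0.12),
    ("TERT", 0.05, 0.90, 0.50, 0.20),
    ("ZIC3", 0.03, 0.92, 0.55, 0.06),
    ("OTX2", 0.02, 0.90, 0.40, 0.06),
    ("FOXD3", 0.02, 0.85, 0.65, 0.15),
    ("NR0B1", 0.00, 0.12, 0.80, 0.10),  # low detection overall
    ("NODAL", 0.05, 0.90, 0.60, 0.20),
    ("LEFTY2", 0.02, 0.92, 0.70, 0.10),
    ("TERF1", 0.10, 0.95, 0.45, 0.18),
    ("PRDM14", 0.02, 0.88, 0.75, 0.08),
]

_INTERMEDIATE = [
    ("CDH1", 0.05, 0.98, 0.50, 0.07),
    ("EPCAM", 0.05, 0.95, 0.45, 0.10),
    ("KRT8", 0.10, 0.90, 0.40, 0.15),
    ("KRT18", 0.10, 0.92, 0.35, 0.12),
    ("STAT3", 0.30, 0.90, 0.50, 0.25),
    ("LIN28B", 0.05, 0.85, 0.55, 0.15),
]
# transient intermediates: up then back down (second, negative component)
_TRANSIENT = [
    # name, baseline, peak rise, mu_up, sigma_up, drop, mu_down, sigma_down
    ("CRABP2", 0.05, 0.85, 0.30, 0.08, -0.80, 0.70, 0.08),
    ("FGF4", 0.02, 0.80, 0.35, 0.10, -0.70, 0.75, 0.08),
]

_CHROMATIN = [
    ("EZH2", 0.40, 0.98, 0.15, 0.08),
    ("SUZ12", 0.45, 0.95, 0.20, 0.10),
    ("EED", 0.40, 0.95, 0.15, 0.10),
    ("JARID2", 0.35, 0.92, 0.20, 0.12),
    ("DNMT1", 0.60, 0.98, 0.15, 0.10),
    ("SETDB1", 0.50, 0.95, 0.20, 0.12),
    ("KDM2B", 0.35, 0.90, 0.25, 0.10),
    ("SMARCA4", 0.55, 0.95, 0.15, 0.10),
    ("REST", 0.02, 0.10, 0.50, 0.20),  # low detection overall
]


def default_gene_params() -> list[GeneSimParams]:
    """The packaged 47-gene default panel (plus GAPDH as normalizer)."""
    rng = np.random.default_rng(20140417)  # fixed: part of the default config
    genes: list[GeneSimParams] = []

    def lvl():
        return float(rng.uniform(21.0, 28.0))

    # alternate-branch cells move away from both anchors: fibroblast genes
    # largely lost, pluripotency and chromatin-modifier genes near-silent
    for name, b, e, mu, s in _FIBROBLAST:
        genes.append(
            GeneSimParams(name, "fibroblast", b, e, mu, s, expr_mean_on=lvl(),
                          alt_freq=0.25)
        )
    for name, b, e, mu, s in _PLURIPOTENCY:
        genes.append(
            GeneSimParams(name, "pluripotency", b, e, mu, s, expr_mean_on=lvl(),
                          alt_freq=0.05)
        )
    for name, b, e, mu, s in _INTERMEDIATE:
        genes.append(
            GeneSimParams(name, "intermediate", b, e, mu, s, expr_mean_on=lvl(),
                          alt_freq=0.15)
        )
    for name, b, rise, mu, s, drop, mu2, s2 in _TRANSIENT:
        genes.append(
            GeneSimParams(name, "intermediate", b, b + rise, mu, s,
                          expr_mean_on=lvl(), alt_freq=0.15,
                          amp2=drop, mu2=mu2, sigma2=s2)
        )
    for name, b, e, mu, s in _CHROMATIN:
        genes.append(
            GeneSimParams(name, "chromatin", b, e, mu, s, expr_mean_on=lvl(),
                          alt_freq=0.05)
        )
    return genes


def default_config(seed: int = 0, **overrides) -> SimConfig:
    """A ~170-cell dataset shaped like the published one: fibroblast and hESC
    anchors, productive intermediates spanning the axis, and an alternate
    branch."""
    kwargs = dict(
        genes=default_gene_params(),
        n_cells_per_group={"FIB": 20, "INT": 100, "ALT": 30, "PLURI": 20},
        qc_fail_fraction=0.05,
        seed=seed,
    )
    kwargs.update(overrides)
    return SimConfig(**kwargs)


def config_from_yaml(path) -> SimConfig:
    """Load a SimConfig from YAML/JSON; omitted gene fields take defaults."""
    obj = yaml.safe_load(Path(path).read_text())
    genes = [GeneSimParams(**g) for g in obj.pop("genes")]
    return SimConfig(genes=genes, **obj)
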