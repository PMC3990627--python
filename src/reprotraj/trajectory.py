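"""Reprogramming progression axis from binary detection profiles.

Each cell's binary (detected / undetected) profile is compared to two anchor
populations: untransduced fibroblasts (FIB) and hESCs (PLURI). With

* ``d_cell`` — mean Euclidean distance from the cell to the anchor group
  (self-comparisons excluded),
* ``d_fp`` — mean distance between FIB and PLURI profiles, and
* ``d_self`` — mean within-group distance of the anchor,

the similarity to an anchor is ``(d_fp - d_cell) / (d_fp - d_self)``: 1 when
the cell is as close to the group as its members are to each other, 0 when it
is as far as the opposite anchor. The progression coordinate is the average
of the similarity to PLURI and the complement of the similarity to FIB, and
the off-trajectory coordinate is the perpendicular distance of
``(sim_fib, sim_pluri)`` to the diagonal ``sim_fib + sim_pluri = 1``.
Cells in the top fraction (default 10%) of off-trajectory distance are
flagged as outliers.
"""

from __future__ import annotations

import math

import numpy as np
import pandas as pd
from scipy.spatial.distance import cdist, pdist

__all__ = [
    "mean_group_distance",
    "group_similarity",
    "progression_score",
    "off_trajectory_distance",
    "flag_outliers",
    "ReprogrammingTrajectory",
    "TrajectoryResults",
]


def mean_group_distance(binary: pd.DataFrame, cell_id, group_ids) -> float:
    """Mean Euclidean distance from one cell's binary profile to a group,
    ignoring the self-comparison."""
    others = [c for c in group_ids if c != cell_id]
    if not others:
        raise ValueError(f"group empty after excluding {cell_id!r}")
    x = binary.loc[[cell_id]].to_numpy(dtype=float)
    g = binary.loc[others].to_numpy(dtype=float)
    return float(cdist(x, g).mean())


def group_similarity(d_cell: float, d_fp: float, d_self: float) -> float:
    """Similarity ratio (d_fp - d_cell) / (d_fp - d_self); not clamped."""
    if d_fp <= d_self:
        raise ValueError(
            f"degenerate anchors: between-group distance {d_fp:.3f} <= "
            f"within-group distance {d_self:.3f}"
        )
    return (d_fp - d_cell) / (d_fp - d_self)


def progression_score(sim_fib: float, sim_pluri: float) -> float:
    """Average of the PLURI similarity and the complement of the FIB one."""
    return (sim_pluri + (1.0 - sim_fib)) / 2.0


def off_trajectory_distance(sim_fib: float, sim_pluri: float) -> float:
    """Perpendicular distance of (sim_fib, sim_pluri) to the FIB->PLURI
    diagonal sim_fib + sim_pluri = 1."""
    return abs(sim_fib + sim_pluri - 1.0) / math.sqrt(2.0)


def flag_outliers(coords: pd.DataFrame, fraction: float = 0.10) -> pd.Series:
    """Flag the ceil(fraction * n) cells with largest off-trajectory distance.

    Ties are broken by stable cell-id order (first ids flagged first).
    """
    if not 0.0 < fraction < 1.0:
        raise ValueError("outlier fraction must lie in (0, 1)")
    n = len(coords)
    k = math.ceil(fraction * n)
    order = coords["off_distance"].sort_values(ascending=False, kind="stable")
    flagged = set(order.index[:k])
    return pd.Series([c in flagged for c in coords.index], index=coords.index,
                     name="outlier")


class ReprogrammingTrajectory:
    """Progression-axis model over a binary detection matrix.

    Parameters
    ----------
    binary : DataFrame
        Cells x genes 0/1 detection matrix (normalizer column excluded).
    fib_ids, pluri_ids : sequence of cell ids
        Anchor populations defining the two ends of the axis.
    """

    def __init__(self, binary: pd.DataFrame, fib_ids, pluri_ids):
        self.binary = binary.astype(float)
        self.fib_ids = list(fib_ids)
        self.pluri_ids = list(pluri_ids)
        if len(self.fib_ids) < 2 or len(self.pluri_ids) < 2:
            raise ValueError("each anchor group needs at least 2 cells")

    @classmethod
    def from_expression(cls, m, fib_group: str = "FIB", pluri_group: str = "PLURI"):
        """Build from an :class:`~reprotraj.io.ExpressionMatrix` using its
        ``group`` annotations for the anchors."""
        b = m.binary()[m.analysis_genes]
        return cls(b, m.group_cells(fib_group), m.group_cells(pluri_group))

    def fit(self, outlier_fraction: float = 0.10) -> "TrajectoryResults":
        b = self.binary
        fib = b.loc[self.fib_ids].to_numpy()
        pluri = b.loc[self.pluri_ids].to_numpy()
        d_fp = float(cdist(fib, pluri).mean())
        d_self_fib = float(pdist(fib).mean())
        d_self_pluri = float(pdist(pluri).mean())

        rows = {}
        for cell in b.index:
            d_fib = mean_group_distance(b, cell, self.fib_ids)
            d_pluri = mean_group_distance(b, cell, self.pluri_ids)
            s_f = group_similarity(d_fib, d_fp, d_self_fib)
            s_p = group_similarity(d_pluri, d_fp, d_self_pluri)
            rows[cell] = (d_fib, d_pluri, s_f, s_p,
                          progression_score(s_f, s_p),
                          off_trajectory_distance(s_f, s_p))
        coords = pd.DataFrame.from_dict(
            rows, orient="index",
            columns=["d_fib", "d_pluri", "sim_fib", "sim_pluri",
                     "progression", "off_distance"],
        )
        coords.index.name = "cell_id"
        coords["outlier"] = flag_outliers(coords, outlier_fraction)
        return TrajectoryResults(coords, d_fp=d_fp, d_self_fib=d_self_fib,
                                 d_self_pluri=d_self_pluri,
                                 outlier_fraction=outlier_fraction,
                                 n_genes=b.shape[1])


class TrajectoryResults:
    """Per-cell trajectory coordinates plus anchor geometry."""

    def __init__(self, coords: pd.DataFrame, *, d_fp, d_self_fib, d_self_pluri,
                 outlier_fraction, n_genes=None):
        self.coords = coords
        self.n_genes = n_genes
        self.d_fp = d_fp
        self.d_self_fib = d_self_fib
        self.d_self_pluri = d_self_pluri
        self.outlier_fraction = outlier_fraction
        self.n_clamped = int(((coords["progression"] < 0)
                              | (coords["progression"] > 1)).sum())

    @property
    def progression(self) -> pd.Series:
        return self.coords["progression"]

    def clamped_progression(self) -> pd.Series:
        """Progression clipped to [0, 1] for binning; the raw coordinate is
        kept in ``coords``."""
        return self.coords["progression"].clip(0.0, 1.0)

    def non_outliers(self) -> list[str]:
        return list(self.coords.index[~self.coords["outlier"]])

    def summary(self) -> str:
        c = self.coords
        lines = [
            "Reprogramming trajectory fit",
            f"  cells: {len(c)}   genes: {self.n_genes or '?'}",
            f"  anchor separation d_fp = {self.d_fp:.3f} "
            f"(within-FIB {self.d_self_fib:.3f}, within-PLURI {self.d_self_pluri:.3f})",
            f"  progression range: {c['progression'].min():.3f} .. "
            f"{c['progression'].max():.3f} ({self.n_clamped} outside [0,1])",
            f"  outliers flagged: {int(c['outlier'].sum())} "
            f"(top {self.outlier_fraction:.0%} by off-trajectory distance)",
        ]
        return "\n".join(lines)

    def to_csv(self, path) -> None:
        self.coords.to_csv(path)
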