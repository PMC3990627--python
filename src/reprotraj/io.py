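"""Loading, quality control, normalization and binarization of Ct tables.

Rules applied here:

* Ct = 40 encodes "undetected"; any Ct >= 40 is clamped to 40 with a warning.
* Cells with a GAPDH Ct of 25 or greater are excluded (technical QC).
* Expression level = 40 - dCt = 40 - (Ct_gene - Ct_GAPDH), defined only where
  the gene is detected; larger means more transcript.
* Binary detection: 1 where Ct < 40, else 0.

Quantitative analyses need a number for undetected entries; the
``undetected_level_policy`` ("zero" by default) fills them with level 0.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path

import numpy as np
import pandas as pd

from .panel import GenePanel

ANNOTATION_COLUMNS = ("group", "day", "facs")
UNDETECTED_CT = 40.0
QC_GAPDH_CT_MAX = 25.0


class ExpressionMatrix:
    """Cells x genes Ct matrix with per-cell annotations.

    Parameters
    ----------
    ct : DataFrame
        Raw Ct values in (0, 40], indexed by cell id, one column per gene
        including the normalizer. 40 means undetected.
    annotations : DataFrame, optional
        Per-cell ``group`` / ``day`` / ``facs`` labels; missing cells get
        group "unknown".
    normalizer : str
        Housekeeping gene used for delta-Ct.
    """

    def __init__(self, ct: pd.DataFrame, annotations: pd.DataFrame | None = None,
                 normalizer: str = "GAPDH"):
        if normalizer not in ct.columns:
            raise ValueError(f"no {normalizer} column in Ct table")
        ct = ct.astype(float)
        if (ct > UNDETECTED_CT).any().any():
            warnings.warn("Ct values above 40 clamped to 40 (undetected)")
            ct = ct.clip(upper=UNDETECTED_CT)
        if (ct <= 0).any().any():
            raise ValueError("Ct values must be positive")
        self.ct = ct
        self.normalizer = normalizer
        if annotations is None:
            annotations = pd.DataFrame(index=ct.index)
        annotations = annotations.reindex(ct.index)
        if "group" not in annotations.columns:
            annotations["group"] = "unknown"
        annotations["group"] = annotations["group"].fillna("unknown")
        self.annotations = annotations

    # -- derived views ----------------------------------------------------
    @property
    def cell_ids(self) -> list[str]:
        return list(self.ct.index)

    @property
    def gene_ids(self) -> list[str]:
        return list(self.ct.columns)

    @property
    def analysis_genes(self) -> list[str]:
        """All genes except the normalizer."""
        return [g for g in self.ct.columns if g != self.normalizer]

    @property
    def detected(self) -> pd.DataFrame:
        return self.ct < UNDETECTED_CT

    @property
    def level(self) -> pd.DataFrame:
        """(40 - dCt) levels, NaN where undetected."""
        dct = self.ct.sub(self.ct[self.normalizer], axis=0)
        lvl = 40.0 - dct
        return lvl.where(self.detected)

    def level_filled(self, policy: str = "zero") -> pd.DataFrame:
        """Levels with undetected entries filled per policy ('zero' only)."""
        if policy != "zero":
            raise ValueError(f"unknown undetected_level_policy {policy!r}")
        return self.level.fillna(0.0)

    def binary(self) -> pd.DataFrame:
        return binarize(self)

    def group_cells(self, group: str) -> list[str]:
        return list(self.annotations.index[self.annotations["group"] == group])

    def subset(self, cell_ids) -> "ExpressionMatrix":
        return ExpressionMatrix(
            self.ct.loc[cell_ids], self.annotations.loc[cell_ids],
            normalizer=self.normalizer,
        )

    def __len__(self) -> int:
        return len(self.ct)

    def to_csv(self, path) -> None:
        self.annotations.join(self.ct).to_csv(path)


def load_ct_table(path, panel: GenePanel | None = None, *,
                  normalizer: str = "GAPDH",
                  strict_panel: bool = False) -> ExpressionMatrix:
    """Read a wide cells x genes Ct table (CSV/TSV/XLSX).

    The first column is the cell id; annotation columns (``group``, ``day``,
    ``facs``) are split off; the rest are gene Ct values. Missing entries are
    treated as undetected (Ct = 40). Genes absent from ``panel`` raise (if
    ``strict_panel``) or warn.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix.lower() in (".xlsx", ".xls"):
        df = pd.read_excel(path, index_col=0)
    else:
        sep = "\t" if path.suffix.lower() in (".tsv", ".txt") else ","
        df = pd.read_csv(path, index_col=0, sep=sep)

    ann_cols = [c for c in ANNOTATION_COLUMNS if c in df.columns]
    ann = df[ann_cols].copy() if ann_cols else None
    ct = df.drop(columns=ann_cols)

    if normalizer not in ct.columns:
        raise ValueError(f"Ct table has no {normalizer} column")
    bad = ct.apply(lambda col: pd.to_numeric(col, errors="coerce"))
    nonnum = bad.isna() & ct.notna()
    if nonnum.any().any():
        cells = list(ct.index[nonnum.any(axis=1)])
        raise ValueError(f"non-numeric Ct values for cells {cells}")
    ct = bad.fillna(UNDETECTED_CT)

    if panel is not None:
        extra = [g for g in ct.columns if g not in panel]
        if extra:
            msg = f"genes not in panel: {extra}"
            if strict_panel:
                raise ValueError(msg)
            warnings.warn(msg)
    return ExpressionMatrix(ct, ann, normalizer=normalizer)


def qc_filter(m: ExpressionMatrix, gapdh_ct_max: float = QC_GAPDH_CT_MAX):
    """Drop cells with normalizer Ct >= threshold (default 25).

    Returns (filtered matrix, list of rejected cell ids).
    """
    ok = m.ct[m.normalizer] < gapdh_ct_max
    rejected = list(m.ct.index[~ok])
    return m.subset(list(m.ct.index[ok])), rejected


def normalize(m: ExpressionMatrix) -> pd.DataFrame:
    """(40 - dCt) levels for detected entries (NaN elsewhere)."""
    return m.level


def binarize(m: ExpressionMatrix | pd.DataFrame) -> pd.DataFrame:
    """Reduce expression to 0 (undetected) / 1 (detected, Ct < 40)."""
    ct = m.ct if isinstance(m, ExpressionMatrix) else m
    return (ct < UNDETECTED_CT).astype(int)


def qc_report(m: ExpressionMatrix, rejected: list[str], path=None) -> dict:
    """JSON-able QC summary: counts and per-cell normalizer Ct."""
    rep = {
        "n_loaded": len(m) + len(rejected),
        "n_retained": len(m),
        "n_rejected": len(rejected),
        "rejected_cells": rejected,
        "gapdh_ct": {c: float(v) for c, v in m.ct[m.normalizer].items()},
    }
    if path is not None:
        Path(path).write_text(json.dumps(rep, indent=1))
    return rep
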