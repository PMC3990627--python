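"""Gene panel handling: gene -> category assignments for the qPCR marker panel.

A panel maps each assayed gene to one of four marker classes used throughout
the analysis: genes expressed in the starting fibroblasts, genes of the
pluripotency network, predicted intermediate markers of reprogramming, and
chromatin-modifying enzymes. The normalizer gene (GAPDH) is carried alongside
but belongs to no class.
"""

from __future__ import annotations

import pandas as pd

CATEGORIES = ("fibroblast", "pluripotency", "intermediate", "chromatin")


class GenePanel:
    """Mapping of gene name to marker category.

    Parameters
    ----------
    mapping : dict[str, str]
        Gene name -> category; categories restricted to
        ``{"fibroblast", "pluripotency", "intermediate", "chromatin"}``.
    normalizer : str
        Housekeeping gene used for delta-Ct normalization (not categorized).
    """

    def __init__(self, mapping: dict[str, str], normalizer: str = "GAPDH"):
        bad = {c for c in mapping.values() if c not in CATEGORIES}
        if bad:
            raise ValueError(f"unknown panel categories: {sorted(bad)}")
        if normalizer in mapping:
            raise ValueError("normalizer gene must not carry a marker category")
        self.mapping = dict(mapping)
        self.normalizer = normalizer

    @property
    def genes(self) -> list[str]:
        """Categorized genes (normalizer excluded), in insertion order."""
        return list(self.mapping)

    def category(self, gene: str) -> str:
        return self.mapping[gene]

    def genes_in(self, category: str) -> list[str]:
        if category not in CATEGORIES:
            raise ValueError(f"unknown category {category!r}")
        return [g for g, c in self.mapping.items() if c == category]

    def __len__(self) -> int:
        return len(self.mapping)

    def __contains__(self, gene: str) -> bool:
        return gene in self.mapping or gene == self.normalizer

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"gene": self.genes, "category": [self.mapping[g] for g in self.genes]}
        )

    def to_csv(self, path) -> None:
        self.to_frame().to_csv(path, index=False)

    @classmethod
    def from_csv(cls, path, normalizer: str = "GAPDH") -> "GenePanel":
        """Read a two-column (gene, category) CSV."""
        df = pd.read_csv(path)
        if not {"gene", "category"} <= set(df.columns):
            raise ValueError("panel file needs 'gene' and 'category' columns")
        df = df[df["gene"] != normalizer]
        return cls(dict(zip(df["gene"], df["category"])), normalizer=normalizer)
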