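"""Transcriptome / promoter-H3K27ac concordance (a-DEGs).

A gene is an accordant DEG (a-DEG) for one comparison in one lobe when its
significance-gated change is nonzero in BOTH the bulk RNA result and the
promoter H3K27ac result AND the two changes share a sign. Concordance is
therefore defined on gated changes (both assays significant), with no
magnitude-agreement threshold.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Mapping

import numpy as np
import pandas as pd

from .diff import ComparisonResult


@dataclass
class ADEGRecord:
    gene_id: str
    comparison: str
    lobe: str
    rna_g: float
    prom_g: float

    def __post_init__(self) -> None:
        if self.rna_g == 0 or self.prom_g == 0:
            raise ValueError("a-DEG requires nonzero gated changes in both assays")
        if np.sign(self.rna_g) != np.sign(self.prom_g):
            raise ValueError("a-DEG requires sign agreement")

    @property
    def direction(self) -> str:
        return "up" if self.rna_g > 0 else "down"


def find_adegs(rna: ComparisonResult, prom: ComparisonResult) -> list[ADEGRecord]:
    """Accordant genes between an RNA and a promoter comparison result."""
    if (rna.comparison, rna.lobe) != (prom.comparison, prom.lobe):
        raise ValueError(
            f"mismatched comparisons: RNA ({rna.comparison}, {rna.lobe}) vs "
            f"promoter ({prom.comparison}, {prom.lobe})"
        )
    common = rna.table.index.intersection(prom.table.index)
    rg = rna.table.loc[common, "g"]
    pg = prom.table.loc[common, "g"]
    mask = (rg != 0) & (pg != 0) & (np.sign(rg) == np.sign(pg))
    return [
        ADEGRecord(gene, rna.comparison, rna.lobe, float(rg[gene]), float(pg[gene]))
        for gene in common[mask]
    ]


def adegs_to_frame(adegs: Iterable[ADEGRecord]) -> pd.DataFrame:
    rows = [
        {
            "gene_id": a.gene_id,
            "comparison": a.comparison,
            "lobe": a.lobe,
            "rna_g": a.rna_g,
            "prom_g": a.prom_g,
            "direction": a.direction,
        }
        for a in adegs
    ]
    cols = ["gene_id", "comparison", "lobe", "rna_g", "prom_g", "direction"]
    return pd.DataFrame(rows, columns=cols)


def overlap_with_labels(
    adegs: Iterable[ADEGRecord],
    label_sets: Mapping[str, set[str] | Iterable[str]],
) -> pd.DataFrame:
    """Overlap of the a-DEG gene list with named gene sets.

    ``label_sets`` typically holds the shared trend set and each lobe's
    specific set (e.g. {"shared_Rein02": ..., "H_specific": ...}). A gene
    is counted once per set it belongs to. Returns one row per set with
    the overlap count and the sorted overlapping genes.
    """
    adeg_genes = {a.gene_id for a in adegs}
    rows = []
    for name, genes in label_sets.items():
        inter = adeg_genes & set(genes)
        rows.append(
            {
                "set_name": name,
                "set_size": len(set(genes)),
                "n_adegs": len(adeg_genes),
                "overlap": len(inter),
                "genes": ",".join(sorted(inter)),
            }
        )
    return pd.DataFrame(rows, columns=["set_name", "set_size", "n_adegs", "overlap", "genes"])
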