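"""Microbiota-gene correlation integration.

Correlates immune-gene expression (DEMs/DELs of a chosen pathway) with gut
bacterial genus abundances by Pearson correlation and annotates each cell
with significance stars: *** p < 0.001, ** p < 0.01, * p < 0.05.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats


def stars(p: float) -> str:
    """Significance stars: the thresholds partition (0, 1] exactly."""
    if p < 0.001:
        return "***"
    if p < 0.01:
        return "**"
    if p < 0.05:
        return "*"
    return ""


@dataclass(frozen=True)
class CorrelationCell:
    gene_id: str
    genus: str
    r: float
    p: float
    stars: str


def gene_microbe_matrix(
    gene_expr: pd.DataFrame,
    abundance: pd.DataFrame,
    clr_transform: bool = False,
) -> list[CorrelationCell]:
    """All gene x genus Pearson correlations with two-sided p and stars.

    Both tables are features x samples and must share sample columns.
    Relative abundances are used as-is by default; ``clr_transform`` applies
    a centred log-ratio first (compositional data caveat: raw-abundance
    Pearson correlations can be induced by the closure constraint).
    Zero-variance profiles yield a flagged cell with r = p = NaN.
    """
    missing = set(gene_expr.columns) ^ set(abundance.columns)
    if missing:
        raise ValueError(f"sample mismatch between tables: {sorted(missing)}")
    abundance = abundance[gene_expr.columns]
    if gene_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples")
    if clr_transform:
        logged = np.log(abundance.replace(0, np.nan))
        abundance = logged.sub(logged.mean(axis=0), axis=1)

    cells = []
    for gid, x in gene_expr.iterrows():
        for genus, y in abundance.iterrows():
            if x.std() == 0 or y.std() == 0:
                warnings.warn(f"zero-variance profile in ({gid}, {genus}): "
                              "correlation undefined")
                cells.append(CorrelationCell(gid, genus, float("nan"),
                                             float("nan"), ""))
                continue
            res = stats.pearsonr(x, y)
            cells.append(CorrelationCell(gid, genus, float(res.statistic),
                                         float(res.pvalue), stars(res.pvalue)))
    return cells


def select_features(
    de_directions: dict[str, str],
    pathway_ids: set[str],
    abundance: pd.DataFrame,
    groups: dict[str, str],
    top_k: int,
    group_a: str = "A",
    group_c: str = "C",
) -> tuple[list[str], pd.DataFrame]:
    """Restrict genes to the pathway's DE set and genera to the top_k most
    changed (absolute difference of group-mean abundance)."""
    if top_k > len(abundance.index):
        raise ValueError("top_k exceeds number of genera")
    genes = sorted(g for g in pathway_ids
                   if de_directions.get(g, "ns") != "ns")
    if not genes:
        warnings.warn("no differentially expressed pathway genes selected")
    a = [s for s in abundance.columns if groups.get(s) == group_a]
    c = [s for s in abundance.columns if groups.get(s) == group_c]
    change = (abundance[a].mean(axis=1) - abundance[c].mean(axis=1)).abs()
    keep = change.sort_values(ascending=False, kind="stable").index[:top_k]
    return genes, abundance.loc[keep]


def cells_to_frame(cells: list[CorrelationCell]) -> pd.DataFrame:
    """Long-format table (gene, genus, r, p, stars) for heatmap tools."""
    return pd.DataFrame([{
        "gene_id": c.gene_id, "genus": c.genus,
        "r": c.r, "p": c.p, "stars": c.stars,
    } for c in cells])
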