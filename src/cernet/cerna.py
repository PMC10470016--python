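"""ceRNA (lncRNA-miRNA-mRNA) network inference.

Under the competing-endogenous-RNA model a lncRNA sponges a miRNA and
thereby de-represses the miRNA's mRNA targets, so in a valid triad the
lncRNA and mRNA share a differential-expression direction opposite to the
miRNA's, and the miRNA's expression profile anti-correlates with both.
A triad (lncRNA, miRNA, mRNA) is emitted iff:

* direction(lncRNA) == direction(mRNA) != direction(miRNA), all DE;
* Pearson r(lncRNA, miRNA) <= -0.6 with p < 0.05;
* Pearson r(miRNA, mRNA)  <= -0.6 with p < 0.05;

with ``signed=False`` the two correlation rules relax to |r| >= 0.6.
miRNA targeting evidence comes from input maps (miRNA -> mRNAs and
miRNA -> lncRNAs); seed-match prediction is out of scope.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass
from pathlib import Path

import numpy as np
import pandas as pd
from scipy import stats

R_THRESHOLD = 0.6
P_THRESHOLD = 0.05


@dataclass(frozen=True)
class CeRNATriad:
    lncrna_id: str
    mirna_id: str
    mrna_id: str
    r_lnc_mir: float
    p_lnc_mir: float
    r_mir_mrna: float
    p_mir_mrna: float
    dir_lnc: str
    dir_mir: str
    dir_mrna: str


def correlation_with_p(x: np.ndarray | pd.Series,
                       y: np.ndarray | pd.Series) -> tuple[float, float]:
    """Pearson r with two-sided p from the t approximation
    (t = r * sqrt((n-2)/(1-r^2)) on n-2 degrees of freedom)."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if len(x) < 3 or len(x) != len(y):
        raise ValueError("need matched profiles with n >= 3")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("profiles must be finite")
    if x.std() == 0 or y.std() == 0:
        raise ValueError("zero-variance profile: correlation undefined")
    res = stats.pearsonr(x, y)
    return float(res.statistic), float(res.pvalue)


def build_triads(
    de_directions: dict[str, str],
    expr: pd.DataFrame,
    mirna_mrna_map: dict[str, list[str]],
    mirna_lnc_map: dict[str, list[str]],
    mrna_subset: set[str] | None = None,
    r_threshold: float = R_THRESHOLD,
    p_threshold: float = P_THRESHOLD,
    signed: bool = True,
) -> list[CeRNATriad]:
    """Enumerate all triads satisfying the ceRNA rules.

    ``de_directions`` maps any id (lncRNA, miRNA or mRNA) to up/down/ns;
    ``expr`` holds one expression profile per row for every id involved
    (shared sample columns); ``mrna_subset`` restricts mRNAs to a chosen
    gene set (e.g. the Toll/Imd pathway members).  Ids present in the maps
    but absent from ``expr`` are skipped with a warning.
    """
    triads = []
    for mir, mrnas in mirna_mrna_map.items():
        d_mir = de_directions.get(mir, "ns")
        if d_mir == "ns":
            continue
        if mir not in expr.index:
            warnings.warn(f"{mir} missing from expression: triads skipped")
            continue
        for lnc in mirna_lnc_map.get(mir, []):
            d_lnc = de_directions.get(lnc, "ns")
            if d_lnc == "ns" or d_lnc == d_mir:
                continue
            if lnc not in expr.index:
                warnings.warn(f"{lnc} missing from expression: triads skipped")
                continue
            try:
                r1, p1 = correlation_with_p(expr.loc[lnc], expr.loc[mir])
            except ValueError:
                continue
            if not _passes(r1, p1, r_threshold, p_threshold, signed):
                continue
            for mrna in mrnas:
                if mrna_subset is not None and mrna not in mrna_subset:
                    continue
                if de_directions.get(mrna, "ns") != d_lnc:
                    continue
                if mrna not in expr.index:
                    warnings.warn(f"{mrna} missing from expression: triad skipped")
                    continue
                try:
                    r2, p2 = correlation_with_p(expr.loc[mir], expr.loc[mrna])
                except ValueError:
                    continue
                if not _passes(r2, p2, r_threshold, p_threshold, signed):
                    continue
                triads.append(CeRNATriad(lnc, mir, mrna, r1, p1, r2, p2,
                                         d_lnc, d_mir, d_lnc))
    return triads


def _passes(r: float, p: float, r_thr: float, p_thr: float, signed: bool) -> bool:
    magnitude_ok = (r <= -r_thr) if signed else (abs(r) >= r_thr)
    return magnitude_ok and p < p_thr


def network_summary(triads: list[CeRNATriad]) -> dict[str, int]:
    """Distinct pair and node counts of the triad network."""
    return {
        "mirna_mrna_pairs": len({(t.mirna_id, t.mrna_id) for t in triads}),
        "lncrna_mirna_pairs": len({(t.lncrna_id, t.mirna_id) for t in triads}),
        "lncrnas": len({t.lncrna_id for t in triads}),
        "mirnas": len({t.mirna_id for t in triads}),
        "mrnas": len({t.mrna_id for t in triads}),
        "triads": len(triads),
    }


def export_network(triads: list[CeRNATriad], outdir: str | Path,
                   write_sif: bool = True) -> tuple[Path, Path]:
    """Write Cytoscape-importable edge and node attribute tables.

    ``edges.tsv``: source, target, interaction (lncRNA-miRNA | miRNA-mRNA);
    ``nodes.tsv``: id, type, direction.  Optionally a ``network.sif``.
    Returns the (edges, nodes) paths.
    """
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    edges: list[tuple[str, str, str]] = []
    nodes: dict[str, tuple[str, str]] = {}
    for t in triads:
        edges.append((t.lncrna_id, t.mirna_id, "lncRNA-miRNA"))
        edges.append((t.mirna_id, t.mrna_id, "miRNA-mRNA"))
        nodes[t.lncrna_id] = ("lncRNA", t.dir_lnc)
        nodes[t.mirna_id] = ("miRNA", t.dir_mir)
        nodes[t.mrna_id] = ("mRNA", t.dir_mrna)
    edge_path = outdir / "edges.tsv"
    node_path = outdir / "nodes.tsv"
    pd.DataFrame(sorted(set(edges)), columns=["source", "target", "interaction"]) \
        .to_csv(edge_path, sep="\t", index=False)
    pd.DataFrame([(n, t, d) for n, (t, d) in sorted(nodes.items())],
                 columns=["id", "type", "direction"]) \
        .to_csv(node_path, sep="\t", index=False)
    if write_sif:
        with open(outdir / "network.sif", "w") as fh:
            for s, tgt, kind in sorted(set(edges)):
                fh.write(f"{s}\t{kind}\t{tgt}\n")
    return edge_path, node_path


def read_network(outdir: str | Path) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read back exported edge/node tables (round-trip helper)."""
    outdir = Path(outdir)
    edges = pd.read_csv(outdir / "edges.tsv", sep="\t")
    nodes = pd.read_csv(outdir / "nodes.tsv", sep="\t")
    return edges, nodes
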