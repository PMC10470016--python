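"""Pathway-level DE summaries, annotation coverage, and enrichment.

Produces per-pathway counts of differentially expressed lncRNAs (DELs) and
mRNAs (DEMs) with their ratios to the study-wide DE totals, per-database
annotation-coverage percentages, and a generic one-sided hypergeometric
over-representation test on user-supplied term -> gene maps.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import pandas as pd
from scipy import stats


@dataclass(frozen=True)
class PathwayRow:
    pathway_id: str
    pathway_name: str
    del_count: int
    del_ratio: float
    dem_count: int
    dem_ratio: float


def pathway_de_table(
    del_ids: set[str],
    dem_ids: set[str],
    pathway_map: dict[str, tuple[str, set[str]]],
    total_dels: int,
    total_dems: int,
) -> list[PathwayRow]:
    """One row per pathway: distinct DE ids annotated to it and their ratios.

    ``pathway_map`` maps pathway_id -> (name, annotated gene ids);
    ratios are count / study-wide total, rounded to 8 decimals.
    """
    rows = []
    for pid, (name, members) in pathway_map.items():
        dels = len(del_ids & members)
        dems = len(dem_ids & members)
        if (dels and total_dels == 0) or (dems and total_dems == 0):
            raise ValueError("nonzero pathway count with zero study-wide total")
        if dels > total_dels or dems > total_dems:
            raise ValueError(f"{pid}: pathway count exceeds total")
        rows.append(PathwayRow(
            pid, name, dels,
            round(dels / total_dels, 8) if total_dels else 0.0,
            dems,
            round(dems / total_dems, 8) if total_dems else 0.0,
        ))
    return rows


def ratio(count: int, total: int) -> float:
    """Share of a study-wide DE total, to 8 decimals (the table convention)."""
    if total <= 0:
        raise ValueError("total must be positive")
    if count > total:
        raise ValueError("count exceeds total")
    return round(count / total, 8)


def annotation_coverage(
    annotated: dict[str, set[str]], universe_size: int
) -> dict[str, float]:
    """Per-database and union annotation percentages (2 decimals).

    ``annotated`` maps database name -> set of annotated ids; the returned
    dict adds an ``"any"`` key for the union.
    """
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    out = {}
    union: set[str] = set()
    for db, ids in annotated.items():
        if len(ids) > universe_size:
            raise ValueError(f"{db}: annotated set larger than universe")
        out[db] = round(100.0 * len(ids) / universe_size, 2)
        union |= ids
    if len(union) > universe_size:
        raise ValueError("union of annotated sets larger than universe")
    out["any"] = round(100.0 * len(union) / universe_size, 2)
    return out


def coverage_percent(count: int, universe_size: int) -> float:
    """Annotation percentage for a printed count, to 2 decimals."""
    if universe_size <= 0:
        raise ValueError("universe size must be positive")
    if count > universe_size:
        raise ValueError("count exceeds universe")
    return round(100.0 * count / universe_size, 2)


def hypergeometric_enrichment(
    study: set[str],
    term_map: dict[str, set[str]],
    universe: set[str],
    alpha: float = 0.01,
) -> pd.DataFrame:
    """One-sided hypergeometric over-representation test per term.

    For a term with m genes in a universe of N, and a study set of n genes
    of which k hit the term, p = P(X >= k) for X ~ Hypergeom(N, m, n).
    Term genes outside the universe are clipped with a warning.  Returns a
    DataFrame (term, k, m, n, N, p, enriched) sorted by p; ``enriched``
    flags p < alpha.
    """
    if not study <= universe:
        raise ValueError("study set must be a subset of the universe")
    n = len(study)
    big_n = len(universe)
    rows = []
    for term, genes in term_map.items():
        outside = genes - universe
        if outside:
            warnings.warn(f"{term}: {len(outside)} gene(s) outside universe clipped")
            genes = genes & universe
        m = len(genes)
        k = len(study & genes)
        # P(X >= k); survival function is P(X > k-1)
        p = float(stats.hypergeom.sf(k - 1, big_n, m, n)) if m else 1.0
        rows.append({"term": term, "k": k, "m": m, "n": n, "N": big_n,
                     "p": min(1.0, p), "enriched": p < alpha})
    return (pd.DataFrame(rows)
            .sort_values("p", kind="stable")
            .reset_index(drop=True))
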