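"""lncRNA target-gene prediction.

Three complementary modes:

* **cis** — genes intersecting a strand-oriented genomic window around the
  lncRNA locus (default 10 kb upstream, 20 kb downstream);
* **trans** — genes outside the cis window whose transcript forms a strong
  RNA/RNA duplex with the lncRNA (minimum contiguous-stack nearest-neighbor
  free energy below a threshold, default -30 kcal/mol);
* **coexpression** — genes whose expression profile has both Pearson r and
  Spearman rho >= 0.6 (signed) with the lncRNA's profile.

Locus overlaps between a lncRNA and a gene are classified into four
categories by the strand relation x containment/partial grid:
``overlap`` (same strand, one span contains the other), ``anti-overlap``
(opposite strand, containment), ``incomplete`` (same strand, partial
intersection), ``anti-incomplete`` (opposite strand, partial).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .constants import RNA_COMPLEMENT, RNA_STACK_ENERGY
from .core import TranscriptRecord

UP_WINDOW = 10_000
DOWN_WINDOW = 20_000
ENERGY_THRESHOLD = -30.0
COEXPR_THRESHOLD = 0.6


@dataclass(frozen=True)
class TargetPair:
    """One predicted lncRNA-gene relationship with its evidence."""

    lncrna_id: str
    gene_id: str
    mode: str                      # cis | trans | coexpression
    distance: int | None = None    # bp, signed (cis); 0 when overlapping
    energy: float | None = None    # kcal/mol (trans)
    r_pearson: float | None = None
    r_spearman: float | None = None
    overlap_class: str = "none"


# ---------------------------------------------------------------------------
# cis window
# ---------------------------------------------------------------------------

def _cis_window(lnc: TranscriptRecord, up: int, down: int) -> tuple[int, int]:
    """Genomic interval of the lncRNA's cis window, oriented by its strand."""
    if lnc.strand == "+":
        return lnc.start - up, lnc.end + down
    return lnc.start - down, lnc.end + up


def _signed_distance(lnc: TranscriptRecord, gene: TranscriptRecord) -> int:
    """Signed bp distance: 0 when spans overlap, negative when the gene is
    5' (upstream) of the lncRNA in its strand orientation, else positive."""
    if gene.end < lnc.start:
        gap = lnc.start - gene.end
        return -gap if lnc.strand == "+" else gap
    if gene.start > lnc.end:
        gap = gene.start - lnc.end
        return gap if lnc.strand == "+" else -gap
    return 0


def cis_targets(
    lncrnas: list[TranscriptRecord],
    genes: list[TranscriptRecord],
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
) -> list[TargetPair]:
    """Pair each lncRNA with every gene whose span intersects its window.

    The window spans ``up_window`` bp 5' and ``down_window`` bp 3' of the
    lncRNA locus in the lncRNA's strand orientation; overlapping genes are
    included with distance 0.
    """
    pairs = []
    for lnc in lncrnas:
        lo, hi = _cis_window(lnc, up_window, down_window)
        for gene in genes:
            if gene.id == lnc.id or gene.chrom != lnc.chrom:
                continue
            if gene.start <= hi and gene.end >= lo:
                pairs.append(TargetPair(
                    lnc.id, gene.id, "cis",
                    distance=_signed_distance(lnc, gene),
                    overlap_class=classify_overlap(lnc, gene),
                ))
    return pairs


# ---------------------------------------------------------------------------
# duplex energy
# ---------------------------------------------------------------------------

def _to_rna(seq: str) -> str:
    s = seq.upper().replace("T", "U")
    bad = set(s) - set("ACGU")
    if bad:
        raise ValueError(f"non-nucleotide character(s) {sorted(bad)} in sequence")
    return s


def duplex_energy(seq_a: str, seq_b: str) -> float:
    """Minimum contiguous-stack hybridisation free energy (kcal/mol).

    Scans all antiparallel Watson-Crick perfect helices between the two
    sequences and scores each as the sum of nearest-neighbor stack energies
    over its consecutive base pairs; returns the most negative total, or 0.0
    when no two-pair helix exists.  Loops and bulges are not modelled.
    """
    a = _to_rna(seq_a)
    b = _to_rna(seq_b)
    if len(a) < 2 or len(b) < 2:
        return 0.0
    # A perfect antiparallel WC helix between a and b is a common substring
    # of a and the reverse complement of b.
    b2 = "".join(RNA_COMPLEMENT[c] for c in reversed(b))
    n, m = len(a), len(b2)
    a_arr = np.frombuffer(a.encode(), dtype=np.uint8)
    b_arr = np.frombuffer(b2.encode(), dtype=np.uint8)
    stacks = np.array([RNA_STACK_ENERGY[a[i - 1:i + 1]] for i in range(1, n)])
    best = 0.0
    prev = np.zeros(m - 1)   # accumulated stack energy ending at b2[j]
    for i in range(1, n):
        valid = (b_arr[1:] == a_arr[i]) & (b_arr[:-1] == a_arr[i - 1])
        cur = np.zeros(m - 1)
        if valid.any():
            ext = np.empty(m - 1)
            ext[0] = 0.0
            ext[1:] = prev[:-1]
            cur[valid] = ext[valid] + stacks[i - 1]
            low = cur.min()
            if low < best:
                best = low
        prev = cur
    return float(best)


def trans_targets(
    lncrnas: list[TranscriptRecord],
    genes: list[TranscriptRecord],
    sequences: dict[str, str] | None = None,
    energies: dict[tuple[str, str], float] | None = None,
    threshold: float = ENERGY_THRESHOLD,
    up_window: int = UP_WINDOW,
    down_window: int = DOWN_WINDOW,
) -> list[TargetPair]:
    """Pairs with duplex energy strictly below ``threshold`` that lie
    outside the lncRNA's cis window (cis and trans are mutually exclusive).

    Precomputed ``energies`` (e.g. from a full secondary-structure tool)
    take precedence over sequence-based scoring.
    """
    cis_keys = {(p.lncrna_id, p.gene_id)
                for p in cis_targets(lncrnas, genes, up_window, down_window)}
    pairs = []
    for lnc in lncrnas:
        for gene in genes:
            if gene.id == lnc.id or (lnc.id, gene.id) in cis_keys:
                continue
            if energies is not None and (lnc.id, gene.id) in energies:
                e = energies[(lnc.id, gene.id)]
            elif sequences is not None:
                try:
                    e = duplex_energy(sequences[lnc.id], sequences[gene.id])
                except KeyError as exc:
                    raise ValueError(f"missing sequence for {exc.args[0]}") from exc
            else:
                raise ValueError("need sequences or precomputed energies")
            if e < threshold:
                pairs.append(TargetPair(lnc.id, gene.id, "trans", energy=e))
    return pairs


# ---------------------------------------------------------------------------
# coexpression
# ---------------------------------------------------------------------------

def coexpression_targets(
    lnc_expr: pd.DataFrame,
    gene_expr: pd.DataFrame,
    threshold: float = COEXPR_THRESHOLD,
    absolute: bool = False,
) -> list[TargetPair]:
    """Pairs with Pearson r and Spearman rho >= threshold (both signed by
    default; ``absolute=True`` thresholds |r| and |rho|).  Profiles must
    share sample columns; zero-variance profiles are skipped with a warning.
    """
    if list(lnc_expr.columns) != list(gene_expr.columns):
        raise ValueError("lncRNA and gene expression must share sample columns")
    if lnc_expr.shape[1] < 3:
        raise ValueError("need >= 3 samples for correlation")
    pairs = []
    for lid, x in lnc_expr.iterrows():
        if x.std() == 0:
            warnings.warn(f"zero-variance profile {lid}: skipped")
            continue
        for gid, y in gene_expr.iterrows():
            if gid == lid:
                continue
            if y.std() == 0:
                warnings.warn(f"zero-variance profile {gid}: skipped")
                continue
            r = stats.pearsonr(x, y).statistic
            rho = stats.spearmanr(x, y).statistic
            rr, rrho = (abs(r), abs(rho)) if absolute else (r, rho)
            if rr >= threshold and rrho >= threshold:
                pairs.append(TargetPair(lid, gid, "coexpression",
                                        r_pearson=float(r), r_spearman=float(rho)))
    return pairs


# ---------------------------------------------------------------------------
# overlap classes
# ---------------------------------------------------------------------------

def classify_overlap(lnc: TranscriptRecord, gene: TranscriptRecord) -> str:
    """Four-way overlap class of a lncRNA and a gene locus (or "none")."""
    if lnc.chrom != gene.chrom or lnc.start > gene.end or gene.start > lnc.end:
        return "none"
    containment = ((lnc.start >= gene.start and lnc.end <= gene.end)
                   or (gene.start >= lnc.start and gene.end <= lnc.end))
    same_strand = lnc.strand == gene.strand
    if containment:
        return "overlap" if same_strand else "anti-overlap"
    return "incomplete" if same_strand else "anti-incomplete"


def pairs_to_frame(pairs: list[TargetPair]) -> pd.DataFrame:
    """Tabular view of target pairs for TSV export."""
    return pd.DataFrame([{
        "lncrna_id": p.lncrna_id, "gene_id": p.gene_id, "mode": p.mode,
        "distance": p.distance, "energy": p.energy,
        "r_pearson": p.r_pearson, "r_spearman": p.r_spearman,
        "overlap_class": p.overlap_class,
    } for p in pairs])
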