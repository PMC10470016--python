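"""mRNA/lncRNA consensus classification.

Candidate transcripts (>= 2 exons, spliced length > 200 bp) are classified
by a 3-of-4 vote over four coding-potential classifiers:

* CNCI score  > 0    -> coding vote
* CPC score   > 0    -> coding vote
* txCdsPredict score > 500 -> coding vote
* protein-family domain hit -> coding vote

A transcript is called mRNA with >= 3 coding votes, lncRNA with >= 3
noncoding votes, and ambiguous on a 2-2 split.  A score exactly at a
threshold counts as a noncoding vote (coding requires strict ">").
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .core import TranscriptRecord

#: minimum exon count and strict minimum spliced length for candidates
MIN_EXONS = 2
MIN_LENGTH = 200


@dataclass(frozen=True)
class BiotypeCall:
    """Consensus vote for one transcript."""

    transcript_id: str
    votes_coding: int
    votes_noncoding: int
    label: str  # mRNA | lncRNA | ambiguous

    def __post_init__(self) -> None:
        assert self.votes_coding + self.votes_noncoding == 4


def filter_candidates(
    records: list[TranscriptRecord],
    min_exons: int = MIN_EXONS,
    min_length: int = MIN_LENGTH,
) -> list[TranscriptRecord]:
    """Keep transcripts with >= ``min_exons`` exons and spliced length
    strictly greater than ``min_length`` bp, preserving input order."""
    return [r for r in records
            if r.exon_count >= min_exons and r.spliced_length > min_length]


def vote_biotype(transcript_id: str, cnci: float, cpc: float, txcds: float,
                 pfam_hit: bool) -> BiotypeCall:
    """Apply the four classifier thresholds and the 3-of-4 consensus."""
    for name, score in (("cnci", cnci), ("cpc", cpc), ("txcds", txcds)):
        if score is None or (isinstance(score, float) and math.isnan(score)):
            raise ValueError(f"{transcript_id}: missing {name} score")
    votes = int(cnci > 0) + int(cpc > 0) + int(txcds > 500) + int(bool(pfam_hit))
    if votes >= 3:
        label = "mRNA"
    elif votes <= 1:
        label = "lncRNA"
    else:
        label = "ambiguous"
    return BiotypeCall(transcript_id, votes, 4 - votes, label)


def classify_all(
    scores: pd.DataFrame,
    records: list[TranscriptRecord] | None = None,
    apply_candidate_filter: bool = True,
) -> tuple[list[str], list[str], list[str], list[str]]:
    """Partition transcripts into (mRNA, lncRNA, ambiguous, missing) id lists.

    ``scores`` is indexed by transcript id with columns
    ``cnci, cpc, txcds, pfam_hit``.  When ``records`` are given, the
    candidate filter is applied first (configurable) and transcripts without
    a score row are reported in ``missing`` rather than silently dropped.
    """
    if records is not None:
        cands = filter_candidates(records) if apply_candidate_filter else records
        ids = [r.id for r in cands]
    else:
        ids = list(scores.index)

    mrna, lncrna, ambiguous, missing = [], [], [], []
    for tid in ids:
        if tid not in scores.index:
            missing.append(tid)
            continue
        row = scores.loc[tid]
        call = vote_biotype(tid, float(row["cnci"]), float(row["cpc"]),
                            float(row["txcds"]), bool(row["pfam_hit"]))
        {"mRNA": mrna, "lncRNA": lncrna, "ambiguous": ambiguous}[call.label].append(tid)
    return mrna, lncrna, ambiguous, missing


def vote_audit(scores: pd.DataFrame) -> pd.DataFrame:
    """Full per-transcript vote table (for the audit TSV output)."""
    rows = []
    for tid, row in scores.iterrows():
        call = vote_biotype(str(tid), float(row["cnci"]), float(row["cpc"]),
                            float(row["txcds"]), bool(row["pfam_hit"]))
        rows.append({"transcript_id": tid, "votes_coding": call.votes_coding,
                     "votes_noncoding": call.votes_noncoding, "label": call.label})
    return pd.DataFrame(rows).set_index("transcript_id")
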