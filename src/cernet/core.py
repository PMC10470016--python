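"""Core containers shared across the pipeline.

``TranscriptRecord`` is the genomic-locus record every stage operates on;
``ExpressionMatrix`` bundles a count table with the transcript lengths and
sample group labels that normalisation and differential expression need.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd


@dataclass(frozen=True)
class TranscriptRecord:
    """One transcript locus.

    Coordinates are 1-based and inclusive, exons are non-overlapping
    intervals within ``[start, end]``, ``strand`` is ``+`` or ``-``.
    """

    id: str
    chrom: str
    strand: str
    start: int
    end: int
    exons: tuple[tuple[int, int], ...]
    biotype: str = "unknown"  # mRNA | lncRNA | unknown
    known: bool = True

    def __post_init__(self) -> None:
        if self.strand not in ("+", "-"):
            raise ValueError(f"{self.id}: strand must be '+' or '-', got {self.strand!r}")
        if self.start > self.end:
            raise ValueError(f"{self.id}: start {self.start} > end {self.end}")
        for s, e in self.exons:
            if s > e:
                raise ValueError(f"{self.id}: negative-length exon ({s}, {e})")
            if s < self.start or e > self.end:
                raise ValueError(f"{self.id}: exon ({s}, {e}) outside span")
        ordered = sorted(self.exons)
        for (s1, e1), (s2, e2) in zip(ordered, ordered[1:]):
            if s2 <= e1:
                raise ValueError(f"{self.id}: overlapping exons ({s1},{e1}) and ({s2},{e2})")

    @property
    def exon_count(self) -> int:
        return len(self.exons)

    @property
    def spliced_length(self) -> int:
        """Sum of exon lengths in bp (the transcript's effective length)."""
        return sum(e - s + 1 for s, e in self.exons)


@dataclass
class ExpressionMatrix:
    """Transcripts x samples counts with lengths and group labels.

    ``counts`` is indexed by transcript id with one column per sample;
    ``lengths`` gives effective transcript length in bp; ``groups`` maps
    sample name -> group label (the study design uses "A" antibiotic vs
    "C" control).
    """

    counts: pd.DataFrame
    lengths: pd.Series
    groups: dict[str, str]

    def __post_init__(self) -> None:
        self.counts = self.counts.astype(float)
        self.lengths = self.lengths.reindex(self.counts.index)
        if self.lengths.isna().any():
            missing = self.lengths[self.lengths.isna()].index.tolist()
            raise ValueError(f"missing lengths for transcripts: {missing[:5]}")
        if (self.lengths <= 0).any():
            raise ValueError("transcript lengths must be positive")
        if (self.counts.to_numpy() < 0).any():
            raise ValueError("counts must be nonnegative")
        unknown = [s for s in self.counts.columns if s not in self.groups]
        if unknown:
            raise ValueError(f"samples without a group label: {unknown}")

    @property
    def samples(self) -> list[str]:
        return list(self.counts.columns)

    def samples_in(self, group: str) -> list[str]:
        return [s for s in self.counts.columns if self.groups[s] == group]

    def write_tsv(self, path: str | Path) -> None:
        out = self.counts.copy()
        out.insert(0, "length", self.lengths)
        out.to_csv(path, sep="\t", index_label="transcript_id")


@dataclass(frozen=True)
class DEResult:
    """Differential-expression call for one transcript (A over C)."""

    transcript_id: str
    log2fc: float
    p_value: float
    direction: str  # up | down | ns
    known: bool = True


# ---------------------------------------------------------------------------
# GFF3 / FASTA I/O
# ---------------------------------------------------------------------------

def write_gff3(records: Iterable[TranscriptRecord], path: str | Path) -> None:
    """Write transcripts and their exons as a minimal valid GFF3 file."""
    lines = ["##gff-version 3"]
    for rec in records:
        feature = "mRNA" if rec.biotype == "mRNA" else "transcript"
        attrs = (
            f"ID={rec.id};biotype={rec.biotype};"
            f"status={'known' if rec.known else 'novel'}"
        )
        lines.append(
            "\t".join([rec.chrom, "cernet", feature, str(rec.start), str(rec.end),
                       ".", rec.strand, ".", attrs])
        )
        for i, (s, e) in enumerate(sorted(rec.exons), 1):
            lines.append(
                "\t".join([rec.chrom, "cernet", "exon", str(s), str(e),
                           ".", rec.strand, ".", f"ID={rec.id}.exon{i};Parent={rec.id}"])
            )
    Path(path).write_text("\n".join(lines) + "\n")


def read_gff3(path: str | Path) -> list[TranscriptRecord]:
    """Parse a GFF3 file into TranscriptRecords (transcript + exon features)."""
    import gffutils

    db = gffutils.create_db(str(path), ":memory:", merge_strategy="create_unique",
                            keep_order=True)
    records: list[TranscriptRecord] = []
    for ftype in ("mRNA", "transcript"):
        for feat in db.features_of_type(ftype):
            exons = tuple(sorted((c.start, c.end) for c in db.children(feat, featuretype="exon")))
            if not exons:
                exons = ((feat.start, feat.end),)
            biotype = feat.attributes.get("biotype", ["unknown"])[0]
            status = feat.attributes.get("status", ["known"])[0]
            records.append(TranscriptRecord(
                id=feat.id, chrom=feat.seqid, strand=feat.strand,
                start=feat.start, end=feat.end, exons=exons,
                biotype=biotype, known=(status == "known"),
            ))
    return records


def write_fasta(sequences: dict[str, str], path: str | Path, width: int = 60) -> None:
    """Write sequences as FASTA with fixed-width line wrapping."""
    with open(path, "w") as fh:
        for name, seq in sequences.items():
            fh.write(f">{name}\n")
            for i in range(0, len(seq), width):
                fh.write(seq[i:i + width] + "\n")


def read_counts_tsv(path: str | Path, groups: dict[str, str]) -> ExpressionMatrix:
    """Read a ``transcript_id  length  sample...`` TSV into an ExpressionMatrix."""
    df = pd.read_csv(path, sep="\t", index_col="transcript_id")
    lengths = df.pop("length")
    return ExpressionMatrix(counts=df, lengths=lengths, groups=groups)
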