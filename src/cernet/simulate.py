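"""Synthetic-data generator for the whole pipeline.

Emulates the statistical structure of a two-group (antibiotic vs control)
insect-gut RNA-seq experiment: a genome annotation with mRNA and lncRNA
loci placed so that cis-window logic is exercised, negative-binomial counts
with a planted differentially-expressed fraction, coding-potential scores
correlated with the true biotype, a miRNA layer with planted sign-consistent
ceRNA triads, and genus abundance tables with planted gene-genus
correlations.  Every generator returns ground-truth labels so downstream
stages have parameter-recovery tests.

All randomness flows from ``SimulationConfig.seed``; the same config yields
byte-identical output files.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from .core import ExpressionMatrix, TranscriptRecord, write_fasta, write_gff3

# Distinct stream tags so each generator draws an independent, reproducible
# substream of the config seed.
_TAG_ANNOT, _TAG_SEQ, _TAG_COUNTS, _TAG_SCORES, _TAG_MIRNA, _TAG_MICROBE = range(6)


@dataclass
class SimulationConfig:
    """Study-design parameters for the synthetic experiment.

    Defaults mirror the emulated design: two groups ("A" antibiotic, "C"
    control) with three biological replicates each, a moderate planted DE
    fraction with a two-fold-per-unit log2 shift, and RNA-seq-typical
    negative-binomial dispersion.
    """

    seed: int = 0
    n_mrna: int = 100
    n_lncrna: int = 100
    n_mirna: int = 20
    n_samples_per_group: int = 3
    de_fraction: float = 0.2
    lfc_location: float = 2.0
    nb_dispersion: float = 0.1
    n_genera: int = 10
    n_planted_triads: int = 5
    genome_length: int = 5_000_000
    #: fraction of lncRNAs deliberately placed within the cis window of an mRNA
    cis_fraction: float = 0.4
    #: fraction of lncRNAs deliberately overlapping an mRNA
    overlap_fraction: float = 0.2
    #: magnitude of the planted miRNA anti-correlation (log scale)
    mirna_anticorr: float = 0.9
    #: per-sample library-size factors are log-normal with this sigma
    libsize_sigma: float = 0.2
    #: baseline mean count per transcript: log-normal(base_mean, base_sigma)
    base_mean: float = 100.0
    base_sigma: float = 1.0

    def __post_init__(self) -> None:
        for name in ("n_mrna", "n_lncrna", "n_mirna", "n_samples_per_group",
                     "n_genera", "n_planted_triads", "genome_length"):
            if getattr(self, name) < 0:
                raise ValueError(f"{name} must be nonnegative")
        if not 0.0 <= self.de_fraction <= 1.0:
            raise ValueError("de_fraction must be in [0, 1]")
        if self.nb_dispersion <= 0:
            raise ValueError("nb_dispersion must be positive")
        if self.cis_fraction + self.overlap_fraction > 1.0 + 1e-9:
            raise ValueError("cis_fraction + overlap_fraction must be <= 1")
        if not 0.0 <= self.mirna_anticorr <= 1.0:
            raise ValueError("mirna_anticorr must be in [0, 1]")


@dataclass
class GroundTruth:
    """Planted truth labels returned by the generators."""

    true_biotype: dict[str, str] = field(default_factory=dict)
    true_de_direction: dict[str, str] = field(default_factory=dict)
    planted_triads: list[tuple[str, str, str]] = field(default_factory=list)
    decoy_triads: list[tuple[str, str, str]] = field(default_factory=list)
    planted_gene_genus: list[tuple[str, str, int]] = field(default_factory=list)
    lnc_placement: dict[str, str] = field(default_factory=dict)


def _rng(config: SimulationConfig, tag: int) -> np.random.Generator:
    return np.random.default_rng([config.seed, tag])


def _standardize(v: np.ndarray) -> np.ndarray:
    sd = v.std()
    return (v - v.mean()) / (sd if sd > 0 else 1.0)


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def _make_exons(rng: np.random.Generator, start: int, end: int,
                n_exons: int) -> tuple[tuple[int, int], ...]:
    """Partition [start, end] into n_exons exons separated by introns."""
    span = end - start + 1
    n_parts = 2 * n_exons - 1
    if span < n_parts:
        return ((start, end),)
    w = rng.dirichlet(np.ones(n_parts))
    sizes = np.maximum(1, np.floor(w * span).astype(int))
    sizes[-1] = span - sizes[:-1].sum()
    if sizes[-1] < 1:  # rebalance a degenerate draw
        sizes = np.full(n_parts, span // n_parts)
        sizes[-1] = span - sizes[:-1].sum()
    exons = []
    pos = start
    for i, size in enumerate(sizes):
        if i % 2 == 0:
            exons.append((pos, pos + size - 1))
        pos += size
    return tuple(exons)


def _make_passing_exons(rng: np.random.Generator, start: int, end: int,
                        n_exons: int) -> tuple[tuple[int, int], ...]:
    """Exon structure guaranteed to pass the candidate filter
    (>= 2 exons, spliced length > 200 bp); retries degenerate draws."""
    for _ in range(100):
        exons = _make_exons(rng, start, end, n_exons)
        if len(exons) >= 2 and sum(e - s + 1 for s, e in exons) > 200:
            return exons
    raise ValueError(f"span ({start}, {end}) too short for a filter-passing "
                     "multi-exon transcript")


def generate_annotation(
    config: SimulationConfig, gff_path: str | Path | None = None
) -> tuple[list[TranscriptRecord], GroundTruth]:
    """Place mRNA and lncRNA loci on a single synthetic chromosome.

    A ``cis_fraction`` of lncRNAs is placed within 5 kb of an mRNA (inside
    both the 10 kb upstream and 20 kb downstream cis windows regardless of
    strand), an ``overlap_fraction`` overlapping an mRNA (containment and
    partial, same and opposite strand), and the remainder isolated (no mRNA
    within 30 kb).  All loci have >= 2 exons and spliced length > 200 bp so
    they survive the lncRNA candidate filter.
    """
    rng = _rng(config, _TAG_ANNOT)
    needed = config.n_mrna * 10_000 + config.n_lncrna * 40_000
    if (config.n_mrna or config.n_lncrna) and config.genome_length < max(needed // 4, 50_000):
        raise ValueError(
            f"genome_length={config.genome_length} too small to place "
            f"{config.n_mrna} mRNAs and {config.n_lncrna} lncRNAs"
        )

    records: list[TranscriptRecord] = []
    truth = GroundTruth()
    mrna_spans: list[tuple[int, int]] = []

    for i in range(config.n_mrna):
        length = int(rng.integers(1_500, 8_000))
        start = int(rng.integers(1, max(2, config.genome_length - length)))
        end = start + length - 1
        strand = "+" if rng.random() < 0.5 else "-"
        exons = _make_passing_exons(rng, start, end, int(rng.integers(2, 9)))
        rec = TranscriptRecord(
            id=f"MRNA_{i:05d}", chrom="chr1", strand=strand, start=start,
            end=end, exons=exons, biotype="mRNA", known=bool(rng.random() < 0.7),
        )
        records.append(rec)
        truth.true_biotype[rec.id] = "mRNA"
        mrna_spans.append((start, end))

    n_cis = int(round(config.cis_fraction * config.n_lncrna))
    n_overlap = int(round(config.overlap_fraction * config.n_lncrna))
    if config.n_mrna == 0:
        n_cis = n_overlap = 0
    overlap_modes = ["contain_same", "contain_opp", "partial_same", "partial_opp"]

    for j in range(config.n_lncrna):
        length = int(rng.integers(400, 3_000))
        if j < n_cis:
            mode = "cis"
            k = int(rng.integers(0, len(mrna_spans)))
            ms, me = mrna_spans[k]
            gap = int(rng.integers(200, 5_000))
            if rng.random() < 0.5:
                start = me + gap
            else:
                start = ms - gap - length + 1
            start = max(1, min(start, config.genome_length - length))
            end = start + length - 1
            strand = "+" if rng.random() < 0.5 else "-"
        elif j < n_cis + n_overlap:
            k = int(rng.integers(0, len(mrna_spans)))
            ms, me = mrna_spans[k]
            host = records[k]
            mode = overlap_modes[int(rng.integers(0, 4))]
            if mode.startswith("contain") and me - ms - 2 > length:
                start = ms + 1 + int(rng.integers(0, me - ms - length))
            else:  # partial: straddle the mRNA 3' boundary
                mode = mode.replace("contain", "partial")
                start = me - length // 2
            start = max(1, min(start, config.genome_length - length))
            end = start + length - 1
            same = mode.endswith("same")
            strand = host.strand if same else ("-" if host.strand == "+" else "+")
        else:
            mode = "isolated"
            for _attempt in range(1000):
                start = int(rng.integers(1, max(2, config.genome_length - length)))
                end = start + length - 1
                if all(start - me > 30_000 or ms - end > 30_000 for ms, me in mrna_spans):
                    break
            else:
                raise ValueError("genome_length too small to place isolated lncRNAs")
            strand = "+" if rng.random() < 0.5 else "-"
            end = start + length - 1
        exons = _make_passing_exons(rng, start, end, int(rng.integers(2, 5)))
        rec = TranscriptRecord(
            id=f"LNC_{j:05d}", chrom="chr1", strand=strand, start=start,
            end=end, exons=exons, biotype="lncRNA", known=bool(rng.random() < 0.5),
        )
        records.append(rec)
        truth.true_biotype[rec.id] = "lncRNA"
        truth.lnc_placement[rec.id] = mode

    if gff_path is not None:
        write_gff3(records, gff_path)
    return records, truth


def generate_sequences(records: list[TranscriptRecord],
                       config: SimulationConfig) -> dict[str, str]:
    """Random transcript sequences (DNA alphabet) of each spliced length."""
    rng = _rng(config, _TAG_SEQ)
    bases = np.array(list("ACGT"))
    return {
        rec.id: "".join(bases[rng.integers(0, 4, rec.spliced_length)])
        for rec in records
    }


# ---------------------------------------------------------------------------
# Counts
# ---------------------------------------------------------------------------

def _nb_draw(rng: np.random.Generator, mean: np.ndarray,
             dispersion: float) -> np.ndarray:
    """NB(mean, dispersion) with Var = mean + dispersion * mean^2."""
    size = 1.0 / dispersion
    p = size / (size + mean)
    return rng.negative_binomial(size, p)


def generate_counts(
    records: list[TranscriptRecord],
    config: SimulationConfig,
    truth: GroundTruth | None = None,
) -> tuple[ExpressionMatrix, GroundTruth]:
    """Two-group negative-binomial counts with a planted DE fraction.

    A ``de_fraction`` of transcripts receives a +/- ``lfc_location`` log2
    shift of the group-A mean; per-sample library-size factors are
    log-normal to exercise normalisation.
    """
    if not records:
        raise ValueError("records must be nonempty")
    if config.n_samples_per_group < 2:
        raise ValueError("need >= 2 samples per group for differential expression")
    rng = _rng(config, _TAG_COUNTS)
    truth = truth or GroundTruth()

    ids = [r.id for r in records]
    n = len(ids)
    samples = ([f"A{i+1}" for i in range(config.n_samples_per_group)]
               + [f"C{i+1}" for i in range(config.n_samples_per_group)])
    groups = {s: s[0] for s in samples}

    base_mu = rng.lognormal(mean=np.log(config.base_mean),
                            sigma=config.base_sigma, size=n)
    n_de = int(round(config.de_fraction * n))
    de_idx = rng.choice(n, size=n_de, replace=False)
    de_sign = rng.choice([-1, 1], size=n_de)

    log2fc = np.zeros(n)
    log2fc[de_idx] = de_sign * config.lfc_location
    for i in range(n):
        tid = ids[i]
        if log2fc[i] > 0:
            truth.true_de_direction[tid] = "up"
        elif log2fc[i] < 0:
            truth.true_de_direction[tid] = "down"
        else:
            truth.true_de_direction[tid] = "ns"

    size_factors = rng.lognormal(mean=0.0, sigma=config.libsize_sigma,
                                 size=len(samples))
    counts = np.zeros((n, len(samples)))
    for j, s in enumerate(samples):
        mu = base_mu * (2.0 ** log2fc if groups[s] == "A" else 1.0)
        counts[:, j] = _nb_draw(rng, mu * size_factors[j], config.nb_dispersion)

    matrix = ExpressionMatrix(
        counts=pd.DataFrame(counts, index=ids, columns=samples),
        lengths=pd.Series({r.id: r.spliced_length for r in records}),
        groups=groups,
    )
    return matrix, truth


# ---------------------------------------------------------------------------
# Coding-potential scores
# ---------------------------------------------------------------------------

def generate_coding_scores(
    records: list[TranscriptRecord],
    config: SimulationConfig,
    noise_rate: float = 0.0,
) -> pd.DataFrame:
    """Per-transcript classifier evidence correlated with the true biotype.

    Each of the four classifiers (score > 0, score > 0, score > 500, domain
    hit) independently votes for the true class with probability
    ``1 - noise_rate``; scores are drawn uniformly on the chosen side of the
    classifier's threshold (only the side matters to the consensus vote).
    """
    if not 0.0 <= noise_rate < 1.0:
        raise ValueError("noise_rate must be in [0, 1)")
    rng = _rng(config, _TAG_SCORES)
    rows = []
    for rec in records:
        coding = rec.biotype == "mRNA"
        votes = [coding != (rng.random() < noise_rate) for _ in range(4)]
        cnci = rng.uniform(0.5, 10.0) if votes[0] else rng.uniform(-10.0, -0.5)
        cpc = rng.uniform(0.5, 10.0) if votes[1] else rng.uniform(-10.0, -0.5)
        txcds = rng.uniform(550.0, 1500.0) if votes[2] else rng.uniform(0.0, 450.0)
        rows.append({"transcript_id": rec.id, "cnci": cnci, "cpc": cpc,
                     "txcds": txcds, "pfam_hit": bool(votes[3])})
    return pd.DataFrame(rows).set_index("transcript_id")


# ---------------------------------------------------------------------------
# miRNA layer
# ---------------------------------------------------------------------------

def generate_mirna_layer(
    matrix: ExpressionMatrix,
    truth: GroundTruth,
    config: SimulationConfig,
) -> tuple[ExpressionMatrix, dict[str, list[str]], dict[str, list[str]], GroundTruth]:
    """miRNA expression, target maps, and planted sign-consistent triads.

    For each planted triad a DE lncRNA and a DE mRNA with the same direction
    are paired with a fresh miRNA whose log profile is built anti-correlated
    (target correlation ``-mirna_anticorr``) with the lncRNA profile, making
    the miRNA's DE direction opposite.  An equal number of decoy miRNAs is
    planted with the same construction but positive correlation (same DE
    direction), violating the ceRNA sign rules.  Remaining miRNAs up to
    ``n_mirna`` are random background.

    Returns (mirna_matrix, mirna->mrna map, mirna->lncrna map, truth).
    """
    rng = _rng(config, _TAG_MIRNA)
    de_lnc = [t for t, d in truth.true_de_direction.items()
              if d != "ns" and truth.true_biotype.get(t) == "lncRNA"]
    de_mrna = [t for t, d in truth.true_de_direction.items()
               if d != "ns" and truth.true_biotype.get(t) == "mRNA"]

    def _same_direction_pairs(k: int) -> list[tuple[str, str]]:
        # lncRNAs may be reused across triads when few are DE; each triad
        # still needs a same-direction DE mRNA partner.
        eligible = [l for l in de_lnc
                    if any(truth.true_de_direction[m] == truth.true_de_direction[l]
                           for m in de_mrna)]
        rng.shuffle(eligible)
        if k and not eligible:
            raise ValueError("no same-direction DE lncRNA/mRNA pairs available "
                             "to plant triads")
        pairs = []
        for j in range(k):
            lnc = eligible[j % len(eligible)]
            d = truth.true_de_direction[lnc]
            cands = [m for m in de_mrna if truth.true_de_direction[m] == d]
            pairs.append((lnc, cands[int(rng.integers(0, len(cands)))]))
        return pairs

    planted = _same_direction_pairs(config.n_planted_triads)
    decoys = _same_direction_pairs(config.n_planted_triads)

    log_expr = np.log2(matrix.counts + 1.0)
    rho = config.mirna_anticorr
    mir_rows: dict[str, np.ndarray] = {}
    mirna_mrna: dict[str, list[str]] = {}
    mirna_lnc: dict[str, list[str]] = {}

    def _mir_profile(lnc: str, mrna: str, corr_sign: int) -> np.ndarray:
        # Build a profile whose Pearson correlation with BOTH the lncRNA and
        # the mRNA log profile equals corr_sign * rho exactly (up to count
        # rounding).  With a = unit(lnc), b = unit(mrna), c = a.b, the
        # bisector u = (a+b)/|a+b| has u.a = u.b = g = sqrt((1+c)/2); mixing
        # v = s*u + sqrt(1-s^2)*w with w a unit vector orthogonal to both and
        # s = rho/g gives v.a = v.b = rho, feasible when g >= rho (otherwise
        # s clamps to 1 and the realised |r| is g, the best attainable).
        za = _standardize(log_expr.loc[lnc].to_numpy())
        zb = _standardize(log_expr.loc[mrna].to_numpy())
        n = za.shape[0]
        a = za / np.linalg.norm(za)
        b = zb / np.linalg.norm(zb)
        ab = a + b
        u = ab / np.linalg.norm(ab)
        g = float(u @ a)
        eps = rng.standard_normal(n)
        eps -= eps.mean()
        b_perp = b - (a @ b) * a
        nb = np.linalg.norm(b_perp)
        b_perp = b_perp / nb if nb > 0 else np.zeros(n)
        w = eps - (eps @ a) * a - (eps @ b_perp) * b_perp
        nw = np.linalg.norm(w)
        w = w / nw if nw > 0 else np.zeros(n)
        s = min(1.0, rho / g) if g > 0 else 1.0
        v = s * u + np.sqrt(max(0.0, 1 - s * s)) * w
        prof = corr_sign * v * np.sqrt(n)
        return np.maximum(0, np.round(2.0 ** (prof * 2.0 + np.log2(500.0)) - 1))

    idx = 0
    for lnc, mrna in planted:
        mid = f"MIR_{idx:04d}"
        idx += 1
        mir_rows[mid] = _mir_profile(lnc, mrna, -1)
        mirna_mrna[mid] = [mrna]
        mirna_lnc[mid] = [lnc]
        d = truth.true_de_direction[lnc]
        truth.true_de_direction[mid] = "down" if d == "up" else "up"
        truth.planted_triads.append((lnc, mid, mrna))
    for lnc, mrna in decoys:
        mid = f"MIR_{idx:04d}"
        idx += 1
        mir_rows[mid] = _mir_profile(lnc, mrna, +1)  # same trend: violates the sign rule
        mirna_mrna[mid] = [mrna]
        mirna_lnc[mid] = [lnc]
        truth.true_de_direction[mid] = truth.true_de_direction[lnc]
        truth.decoy_triads.append((lnc, mid, mrna))
    while idx < config.n_mirna:
        mid = f"MIR_{idx:04d}"
        idx += 1
        mir_rows[mid] = np.maximum(
            0, np.round(rng.lognormal(np.log(200.0), 1.0, len(matrix.samples))))
        truth.true_de_direction[mid] = "ns"

    mirna_matrix = ExpressionMatrix(
        counts=pd.DataFrame(mir_rows, index=matrix.samples).T,
        lengths=pd.Series(22.0, index=list(mir_rows)),
        groups=dict(matrix.groups),
    )
    return mirna_matrix, mirna_mrna, mirna_lnc, truth


# ---------------------------------------------------------------------------
# Microbiota
# ---------------------------------------------------------------------------

def generate_microbiota(
    config: SimulationConfig,
    gene_profiles: pd.DataFrame,
    planted: list[tuple[str, float]] | None = None,
) -> tuple[pd.DataFrame, GroundTruth]:
    """Genus abundance table with planted gene-genus correlations.

    ``planted`` is a list of ``(gene_id, target_r)``; each entry creates a
    genus whose abundance profile has the requested Pearson correlation (in
    expectation) with that gene's profile.  Remaining genera up to
    ``n_genera`` are independent log-normal noise.
    """
    rng = _rng(config, _TAG_MICROBE)
    planted = planted or []
    if len(planted) > config.n_genera:
        raise ValueError("more planted pairs than genera")
    truth = GroundTruth()
    samples = list(gene_profiles.columns)
    rows: dict[str, np.ndarray] = {}
    for k, (gene, r) in enumerate(planted):
        z = _standardize(gene_profiles.loc[gene].to_numpy(dtype=float))
        eps = rng.standard_normal(len(samples))
        perp = eps - (eps @ z) / (z @ z) * z
        norm = np.linalg.norm(perp)
        perp = perp / norm * np.linalg.norm(z) if norm > 0 else 0.0
        prof = r * z + np.sqrt(max(0.0, 1 - r ** 2)) * perp
        genus = f"Genus_{k:03d}"
        rows[genus] = np.round(np.exp(prof + 4.0), 3)
        truth.planted_gene_genus.append((gene, genus, 1 if r > 0 else -1))
    for k in range(len(planted), config.n_genera):
        rows[f"Genus_{k:03d}"] = np.round(
            rng.lognormal(4.0, 1.0, len(samples)), 3)
    return pd.DataFrame(rows, index=samples).T, truth


# ---------------------------------------------------------------------------
# Convenience: run every generator and optionally write all files
# ---------------------------------------------------------------------------

@dataclass
class SimulatedStudy:
    """Everything one synthetic experiment produces."""

    config: SimulationConfig
    records: list[TranscriptRecord]
    sequences: dict[str, str]
    matrix: ExpressionMatrix
    scores: pd.DataFrame
    mirna_matrix: ExpressionMatrix
    mirna_mrna_map: dict[str, list[str]]
    mirna_lnc_map: dict[str, list[str]]
    abundance: pd.DataFrame
    truth: GroundTruth


def simulate_study(
    config: SimulationConfig,
    noise_rate: float = 0.0,
    outdir: str | Path | None = None,
    n_planted_genus_pairs: int = 2,
    planted_genus_r: float = 0.95,
) -> SimulatedStudy:
    """Generate a full coherent study; optionally write all standard files."""
    records, truth = generate_annotation(config)
    sequences = generate_sequences(records, config)
    matrix, truth = generate_counts(records, config, truth)
    scores = generate_coding_scores(records, config, noise_rate)
    if config.n_planted_triads and config.n_mirna:
        mirna_matrix, m2m, m2l, truth = generate_mirna_layer(matrix, truth, config)
    else:
        mirna_matrix = ExpressionMatrix(
            counts=pd.DataFrame(index=pd.Index([], dtype=str),
                                columns=matrix.samples, dtype=float),
            lengths=pd.Series(dtype=float), groups=dict(matrix.groups))
        m2m, m2l = {}, {}
    log_expr = np.log2(matrix.counts + 1.0)
    de_genes = [t for t, d in truth.true_de_direction.items()
                if d != "ns" and truth.true_biotype.get(t) == "mRNA"]
    planted_pairs = [(g, planted_genus_r if i % 2 == 0 else -planted_genus_r)
                     for i, g in enumerate(de_genes[:n_planted_genus_pairs])]
    abundance, microbe_truth = generate_microbiota(config, log_expr, planted_pairs)
    truth.planted_gene_genus = microbe_truth.planted_gene_genus

    study = SimulatedStudy(config, records, sequences, matrix, scores,
                           mirna_matrix, m2m, m2l, abundance, truth)
    if outdir is not None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        write_gff3(records, outdir / "annotation.gff3")
        write_fasta(sequences, outdir / "transcripts.fa")
        matrix.write_tsv(outdir / "counts.tsv")
        scores.to_csv(outdir / "coding_scores.tsv", sep="\t")
        mirna_matrix.write_tsv(outdir / "mirna_counts.tsv")
        _write_map(m2m, outdir / "mirna_mrna_map.tsv")
        _write_map(m2l, outdir / "mirna_lncrna_map.tsv")
        abundance.to_csv(outdir / "genus_abundance.tsv", sep="\t",
                         index_label="genus")
        _write_truth(truth, outdir / "truth.tsv")
    return study


def _write_map(mapping: dict[str, list[str]], path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("mirna_id\ttarget_id\n")
        for mid, targets in mapping.items():
            for t in targets:
                fh.write(f"{mid}\t{t}\n")


def _write_truth(truth: GroundTruth, path: Path) -> None:
    with open(path, "w") as fh:
        fh.write("id\ttrue_biotype\ttrue_de_direction\tplacement\n")
        ids = sorted(set(truth.true_biotype) | set(truth.true_de_direction))
        for tid in ids:
            fh.write(f"{tid}\t{truth.true_biotype.get(tid, '.')}\t"
                     f"{truth.true_de_direction.get(tid, '.')}\t"
                     f"{truth.lnc_placement.get(tid, '.')}\n")
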