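"""Protein characterisation of immune-pathway genes.

ORF translation with validation, molecular weight from embedded average
residue masses, isoelectric point by bisection on the Henderson-Hasselbalch
net-charge function with an embedded pKa set, and Toll-receptor domain
architecture validation/subfamily classification.

A complete ORF of L bp (start codon through stop codon) encodes L/3 - 1
amino acids; tables that print ORF lengths without the stop codon encode
exactly L/3.
"""

from __future__ import annotations

from dataclasses import dataclass, field

from Bio.Seq import Seq

from .constants import PKA_NEGATIVE, PKA_POSITIVE, RESIDUE_MASS, WATER_MASS

STOP_CODONS = {"TAA", "TAG", "TGA"}


def translate_orf(cdna: str) -> str:
    """Translate a complete ORF (ATG ... stop) with the standard code.

    Returns the protein without the stop; raises with the offending
    position on a bad start, internal stop, missing terminal stop, or a
    length not divisible by 3.
    """
    seq = cdna.upper().replace("U", "T")
    if len(seq) % 3 != 0:
        raise ValueError(f"ORF length {len(seq)} not divisible by 3")
    if len(seq) < 6:
        raise ValueError("ORF must contain at least a start and a stop codon")
    if seq[:3] != "ATG":
        raise ValueError(f"bad start codon {seq[:3]!r} at position 1")
    if seq[-3:] not in STOP_CODONS:
        raise ValueError(f"ORF does not end in a stop codon ({seq[-3:]!r})")
    protein = str(Seq(seq[:-3]).translate(table=1))
    if "*" in protein:
        pos = protein.index("*") * 3 + 1
        raise ValueError(f"internal stop codon at nucleotide position {pos}")
    return protein


def orf_aa_length(orf_bp: int, stop_included: bool = True) -> int:
    """Amino-acid length implied by an ORF length in bp."""
    if orf_bp % 3 != 0:
        raise ValueError(f"ORF length {orf_bp} not divisible by 3")
    return orf_bp // 3 - 1 if stop_included else orf_bp // 3


def molecular_weight(protein: str, decimals: int | None = 2) -> float:
    """Average molecular weight in kDa: sum of residue masses plus one water
    for the termini.  Reported to 2 decimals by default (the table
    convention); ``decimals=None`` returns the unrounded value."""
    if not protein:
        raise ValueError("empty protein")
    try:
        total = sum(RESIDUE_MASS[a] for a in protein.upper()) + WATER_MASS
    except KeyError as exc:
        raise ValueError(f"unknown residue {exc.args[0]!r}") from exc
    kda = total / 1000.0
    return kda if decimals is None else round(kda, decimals)


def net_charge(protein: str, ph: float) -> float:
    """Net charge at a given pH (Henderson-Hasselbalch, embedded pKa set)."""
    seq = protein.upper()
    charge = 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE["nterm"]))
    charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE["cterm"] - ph))
    for aa in seq:
        if aa in PKA_POSITIVE:
            charge += 1.0 / (1.0 + 10.0 ** (ph - PKA_POSITIVE[aa]))
        elif aa in PKA_NEGATIVE:
            charge -= 1.0 / (1.0 + 10.0 ** (PKA_NEGATIVE[aa] - ph))
    return charge


def isoelectric_point(protein: str, tol: float = 0.01) -> float:
    """pH at which the net charge is zero, by bisection on [0, 14].

    The net-charge function is strictly decreasing in pH, so bisection
    converges; result within ``tol`` pH units.
    """
    if not protein:
        raise ValueError("empty protein")
    lo, hi = 0.0, 14.0
    while hi - lo > tol:
        mid = (lo + hi) / 2.0
        if net_charge(protein, mid) > 0:
            lo = mid
        else:
            hi = mid
    return round((lo + hi) / 2.0, 2)


@dataclass(frozen=True)
class ProteinCharacterization:
    """Table-row summary of one gene's protein."""

    gene: str
    orf_length: int
    aa_length: int
    molecular_weight_kda: float
    pi: float
    domains: tuple[tuple[str, int, int], ...] = ()


def characterize(gene: str, cdna: str,
                 domains: tuple[tuple[str, int, int], ...] = ()) -> ProteinCharacterization:
    """Full translate -> MW -> pI characterisation of one complete ORF."""
    protein = translate_orf(cdna)
    for name, start, end in domains:
        if not (1 <= start <= end <= len(protein)):
            raise ValueError(f"domain {name} span ({start},{end}) outside protein")
    return ProteinCharacterization(
        gene=gene, orf_length=len(cdna), aa_length=len(protein),
        molecular_weight_kda=molecular_weight(protein),
        pi=isoelectric_point(protein), domains=domains,
    )


# ---------------------------------------------------------------------------
# Toll architecture
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class TollArchitecture:
    """Domain spans (aa coordinates) of one candidate Toll receptor."""

    signal_peptide: tuple[int, int] | None
    lrr_spans: tuple[tuple[int, int], ...]
    tm_spans: tuple[tuple[int, int], ...]
    tir_spans: tuple[tuple[int, int], ...]
    aa_length: int


def validate_toll(
    arch: TollArchitecture,
    p_min_lrr: int = 15,
    p_min_length: int = 1200,
) -> tuple[bool, str]:
    """Validate a Toll domain architecture and assign a subfamily.

    Valid iff >= 1 LRR, exactly one transmembrane span, exactly one TIR
    span, and the TIR lies after (C-terminal of) the TM.  Subfamily rule
    (parameterised): P-type iff LRR count >= ``p_min_lrr`` and protein
    length >= ``p_min_length`` aa; sPP iff LRR count >= ``p_min_lrr`` but
    shorter (same LRR arrangement, truncated); sP iff fewer LRRs; invalid
    architectures are "unclassified".
    """
    if len(arch.tm_spans) == 1 and len(arch.tir_spans) == 1:
        tm, tir = arch.tm_spans[0], arch.tir_spans[0]
        if tm[0] <= tir[1] and tir[0] <= tm[1]:
            raise ValueError("TM and TIR spans overlap")
        valid = bool(arch.lrr_spans) and tir[0] > tm[1]
    else:
        valid = False
    if not valid:
        return False, "unclassified"
    n_lrr = len(arch.lrr_spans)
    if n_lrr >= p_min_lrr:
        return True, "P" if arch.aa_length >= p_min_length else "sPP"
    return True, "sP"
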