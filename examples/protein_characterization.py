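"""Characterise an immune-gene ORF: translation, MW, pI, Toll architecture.

A complete ORF (ATG ... stop) of L bp encodes L/3 - 1 residues; molecular
weight sums average residue masses plus one water; the isoelectric point
is found by bisection on the Henderson-Hasselbalch net-charge curve.
"""

from cernet import (TollArchitecture, characterize, orf_aa_length,
                    validate_toll)
from cernet.reference import TOLL_TABLE

# a small complete ORF (start + 10 codons + stop)
orf = "ATG" + "AAAGTGCTGGCCGAACAATGGCGTAACGAT" + "TAA"
c = characterize("demo_gene", orf)
print(f"ORF {c.orf_length} bp -> {c.aa_length} aa "
      f"(rule: {c.orf_length}/3 - 1 = {orf_aa_length(c.orf_length)})")
print(f"molecular weight {c.molecular_weight_kda} kDa, theoretical pI {c.pi}")

print("\npublished Toll receptors under the subfamily rule "
      "(LRR >= 15 & length >= 1200 aa -> P; LRR >= 15 shorter -> sPP; else sP):")
for gene, orf_bp, aa, mw, pi, n_lrr, tm, tir, expected in TOLL_TABLE:
    arch = TollArchitecture(
        signal_peptide=(1, 20),
        lrr_spans=tuple((50 + 25 * i, 70 + 25 * i) for i in range(n_lrr)),
        tm_spans=(tm,), tir_spans=(tir,), aa_length=aa)
    valid, subfamily = validate_toll(arch)
    print(f"  {gene}: {orf_bp} bp / {aa} aa, {n_lrr} LRRs -> "
          f"{subfamily} (published: {expected})")
# All six receptors validate (LRRs + one TM + one TIR after the TM) and
# fall into the published P / sPP / sP subfamilies.
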