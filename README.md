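# cernet

Toolkit for lncRNA-centred analysis of two-group insect-gut RNA-seq
experiments: coding-potential consensus classification, differential
expression, lncRNA target prediction, ceRNA (lncRNA–miRNA–mRNA) network
inference, pathway summaries, immune-gene protein characterisation, and
microbiota–gene correlation integration — plus a synthetic-data generator
that plants recoverable ground truth for every stage.

## The scientific problem

Insect guts defend themselves with innate-immune cascades (the Toll and Imd
pathways) whose transcription is modulated not only by signalling proteins
but by long noncoding RNAs (lncRNAs). Under the competing-endogenous-RNA
(ceRNA) model, a lncRNA sponges a miRNA and thereby de-represses that
miRNA's mRNA targets. Studies of this kind — e.g. comparing antibiotic-reared
("A") and normally reared ("C") beetle guts, three biological replicates
each — proceed through a fixed analysis chain, which this package implements
as tested, reusable functions:

1. **Classification.** Candidate transcripts need ≥ 2 exons and spliced
   length > 200 bp. Four coding-potential classifiers vote (CNCI > 0,
   CPC > 0, txCdsPredict > 500, protein-domain hit); ≥ 3 coding votes call
   mRNA, ≥ 3 noncoding votes call lncRNA, a 2–2 split is ambiguous.
2. **Expression.** TPM and FPKM views of the count matrix; transcripts with
   FPKM < 1 in every sample are dropped; DE calls require
   |log₂FC| > 1 and p < 0.001 (Welch t on log₂(FPKM+1); log₂FC from
   group-mean FPKM with pseudo-count 1). qPCR validation uses 2^−ΔΔCt.
3. **Targets.** *cis*: genes intersecting a strand-oriented window 0–10 kb
   upstream / 0–20 kb downstream of the lncRNA; *trans*: duplex free energy
   < −30 kcal/mol (contiguous-stack nearest-neighbor model) outside that
   window; *coexpression*: Pearson ≥ 0.6 AND Spearman ≥ 0.6. Locus overlaps
   classify into overlap / anti-overlap / incomplete / anti-incomplete.
4. **ceRNA network.** A triad (lncRNA, miRNA, mRNA) is kept iff the lncRNA
   and mRNA share a DE direction opposite to the miRNA's, and the miRNA
   anti-correlates with both (r ≤ −0.6, p < 0.05 per pair). Networks export
   as Cytoscape-importable edge/node tables and SIF.
5. **Pathways.** Per-pathway DEL/DEM counts with ratios to the study-wide
   totals; annotation-coverage percentages; a generic one-sided
   hypergeometric enrichment test (p < 0.01) on user-supplied term maps.
6. **Protein characterisation.** ORF translation (a complete ORF of L bp
   encodes L/3 − 1 residues), molecular weight from average residue masses,
   isoelectric point by bisection on the Henderson–Hasselbalch net-charge
   curve, and Toll-receptor domain-architecture validation (LRRs + one TM +
   one TIR after the TM) with P / sPP / sP subfamily assignment.
7. **Integration.** Pearson correlation of pathway DEM/DEL expression
   against gut genus abundances, annotated with significance stars
   (* p < 0.05, ** p < 0.01, *** p < 0.001), after keeping the top-k genera
   by absolute between-group abundance change.

## Worked example

```python
import numpy as np, pandas as pd
from cernet import SimulationConfig, simulate_study, classify_all, \
    differential_expression, build_triads, network_summary

study = simulate_study(SimulationConfig(seed=5, n_mrna=50, n_lncrna=50,
                                        n_mirna=16, n_planted_triads=5))
mrna, lnc, amb, missing = classify_all(study.scores, study.records)
de = dict(study.truth.true_de_direction)
expr = pd.concat([np.log2(study.matrix.counts + 1),
                  np.log2(study.mirna_matrix.counts + 1)])
triads = build_triads(de, expr, study.mirna_mrna_map, study.mirna_lnc_map)
print(len(mrna), len(lnc), network_summary(triads)["triads"])
```

prints `50 50 5`: all 100 transcripts classified to their true biotype
(noiseless scores) and all five planted ceRNA triads recovered, with the
five sign-rule-violating decoys rejected. The scripts in `examples/` walk
through each capability the same way and print what every number means.

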