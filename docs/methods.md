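# Methods

## Scope and data model

`cernet` implements the desk-scale analysis chain of a two-group
(antibiotic "A" vs control "C") gut RNA-seq study. Its inputs are the
standard artefacts of such a study — a GFF3 annotation, transcript FASTA,
transcript×sample count TSVs, per-transcript coding-potential score tables,
miRNA→target maps, domain-annotation tables, and genus-abundance TSVs.
Upstream read processing (QC, mapping, assembly) and the external scorers
themselves (CNCI, CPC, txCdsPredict, Pfam, SMART/TMHMM/SignalP, 16S
pipelines) are out of scope: their outputs are inputs here.

## Classification

The consensus rule is a 4-way vote with threshold semantics taken strictly:
a score *exactly at* a threshold (CNCI/CPC 0, txCdsPredict 500) counts as a
noncoding vote, because coding is defined by strict ">". A domain hit is one
coding vote and its absence one noncoding vote — the only reading that
yields a 4-way vote. 2–2 splits are reported as "ambiguous" and excluded
from both classes rather than silently dropped; transcripts without a score
row are reported as missing. The candidate filter (≥ 2 exons, spliced
length > 200 bp) is applied to all candidates by default and is
configurable, since it is ambiguous whether it should gate lncRNA
candidates only.

## Differential expression

The decision rule is |log₂FC| > 1 and p < 0.001 (both strict). The test is
a Welch two-sample t on log₂(FPKM+1); log₂FC is computed from group-mean
FPKM with pseudo-count 1. This is a deliberate, documented replacement for
an NB-GLM framework (edgeR-style): the package's claims about DE are
validated by parameter recovery on synthetic data, not by equality with any
specific tool, and the caller is pluggable. No multiple-testing correction
is applied by default (the rule thresholds raw p); Benjamini–Hochberg is
available behind `bh_correct=True`.

Two caveats the test suite quantifies rather than hides:

* **Power at 3 replicates.** At the study design of 3 replicates per group,
  a Welch t rarely reaches p < 0.001 even for 4-fold shifts; the null
  calibration test therefore checks near-nominal behaviour at 10
  replicates/group and only an upper bound (< 1%) at 3. Recovery
  experiments (sensitivity > 0.5 at a 2-unit log₂ shift, dispersion 0.1)
  run at 5 replicates/group, where the test has meaningful power.
* **Compositional bias of total-count normalisation.** FPKM divides by the
  library total, so a large planted DE fraction with strong one-sided
  shifts deflates every null transcript's FPKM in the shifted group. The
  full-pipeline closure experiment uses a 5% planted fraction so library
  composition stays stable; with 20% planted at 8-fold this bias is
  visible, which is exactly why count-based tools use median-of-ratios or
  TMM normalisation.

## Target prediction

*cis* windows (default 10 kb up / 20 kb down) are anchored on the lncRNA and
oriented by the lncRNA's strand — upstream means 5′ of the lncRNA. Signed
distances report upstream as negative; overlapping genes pair with
distance 0. *trans* pairs require duplex energy strictly below
−30 kcal/mol **and** lying outside the cis window, so cis and trans are
mutually exclusive by construction.

The duplex model scores every perfect antiparallel Watson–Crick helix
(equivalently: every common substring of one sequence and the reverse
complement of the other) as the sum of nearest-neighbor stack free energies
(Turner-style values embedded in `constants.py`), reporting the minimum.
Loops, bulges and mismatches are not modelled — this is a deliberate
simplification, and a table of externally precomputed energies (e.g. from
RNAplex/IntaRNA-class tools) is accepted in place of sequences. The −30
threshold is interpreted in kcal/mol, the convention of RNA hybridisation
tools, and is a parameter.

Coexpression thresholds (Pearson ≥ 0.6 AND Spearman ≥ 0.6) are signed by
default, per the literal "≥ 0.6"; `absolute=True` thresholds magnitudes.
Overlap classes are operationalised as the strand × containment grid: same
strand + containment → overlap, opposite strand + containment →
anti-overlap, partial intersections → incomplete / anti-incomplete.

## ceRNA rules

A triad must satisfy five conditions: direction(lncRNA) = direction(mRNA);
direction(miRNA) opposite; r(lncRNA, miRNA) ≤ −0.6 with p < 0.05;
r(miRNA, mRNA) ≤ −0.6 with p < 0.05. The sponge model implies the miRNA
*anti*-correlates with both partners, so the correlation rules are signed
negative by default (`signed=False` restores |r| ≥ 0.6). The lncRNA–mRNA
correlation is not additionally thresholded — only trend equality is
required. p comes from the two-sided t approximation
t = r·√((n−2)/(1−r²)) with n−2 df (scipy's `pearsonr`). Note that at
n = 6 samples, p < 0.05 requires |r| ≥ 0.811 — the p rule, not the 0.6
magnitude rule, is binding at this design; below ~5 samples per pair the
thresholds are near-degenerate, and correlation-based stages are intended
for n ≥ 6 profiles.

## Pathway summaries and enrichment

Pathway rows count *distinct* DE transcript ids annotated to the pathway;
ratios are count over the study-wide DEL/DEM total, rounded to 8 decimals
(the table convention). Coverage percentages round to 2 decimals.
Enrichment is the one-sided hypergeometric tail P(X ≥ k) per term against a
user-chosen universe (recommended: all transcripts surviving the FPKM
filter); no term-graph propagation or length-bias correction is performed,
and BH correction is optional since the rule thresholds raw p < 0.01.

## Protein characterisation

A complete ORF (ATG … stop, length divisible by 3, no internal stops)
of L bp encodes L/3 − 1 residues. Molecular weight sums average residue
masses plus one water (constants in `constants.py`); the isoelectric point
is the root of the strictly decreasing Henderson–Hasselbalch net-charge
function, found by bisection on [0, 14] to 0.01 pH, with a Bjellqvist-style
pKa set (N-term 7.5, C-term 3.55; K 10.0, R 12.0, H 5.98; D 4.05, E 4.45,
C 9.0, Y 10.0). These constant tables are conventional values, kept in one
file so they can be retuned for parity with any specific server; exact
parity with published MW/pI values is not claimed, since those depend on
full sequences not printed in summary tables.

Toll architectures validate iff they have ≥ 1 LRR, exactly one
transmembrane span, exactly one TIR domain, and the TIR C-terminal of the
TM. The P/sPP/sP subfamily distinction in the invertebrate Toll literature
is not operational as published; the default rule here is: LRR count ≥ 15
and length ≥ 1200 aa → P; LRR count ≥ 15 but shorter → sPP ("same LRR
arrangement but shorter"); fewer LRRs → sP. Both thresholds are
parameters. This rule reproduces the published six-receptor labelling
(four P, one sPP at 16 LRRs/1035 aa, one sP at 12 LRRs/856 aa).

## Microbiota integration

Gene×genus cells carry Pearson r, the two-sided t-approximation p, and
stars (*** p < 0.001, ** p < 0.01, * p < 0.05 — the bands partition (0, 1]
exactly). Genus relative abundances are used as-is to mirror direct-Pearson
practice; a CLR transform is available behind a flag with the standard
compositionality caveat (closure can induce spurious raw-scale
correlations). "Most changed" genera are operationalised as the top-k
absolute difference in group-mean abundance, since the selection statistic
behind such figures is rarely stated.

## Synthetic data: what it emulates and what it does not

The generator mirrors the study design: two groups × 3 replicates
(default), negative-binomial counts (Var = μ + φμ², default dispersion
φ = 0.1, log-normal baseline means, log-normal library-size factors
σ = 0.2), a planted DE fraction (default 20%) with ±2 log₂-unit group
shifts, classifier scores drawn uniformly on the correct side of each
threshold with an independent per-classifier error rate, lncRNA loci
deliberately placed inside cis windows / overlapping mRNAs / isolated, a
miRNA layer with planted sign-consistent triads and sign-violating decoys,
and genus abundances with planted gene–genus correlations. None of these
defaults are estimates from real data — the source study published no
generative parameters — they are RNA-seq conventions chosen once.

Planted correlations use an exact-correlation construction: the noise
vector is projected orthogonal to the anchor profile(s) and rescaled, so
the realised Pearson r equals the target (up to integer count rounding).
For triads the miRNA profile is built equi-correlated with the lncRNA and
mRNA via their unit bisector, feasible whenever the lncRNA–mRNA correlation
c satisfies √((1+c)/2) ≥ ρ; otherwise the construction returns the best
attainable magnitude. Genus abundances are exp-transformed (log-normal), so
raw-scale Pearson magnitudes are mildly attenuated relative to the planted
log-scale target — the measured power (~90% at |r| = 0.95, n = 6) reflects
that attenuation.

What passing synthetic tests does **not** show: robustness to real-data
features the generator omits — isoform-sharing reads, GC/length biases,
batch effects, outlier libraries, compositional microbiome structure, or
correlated (rather than independent) classifier errors.

## Problem sizes and determinism

Test and acceptance experiments run at desk scale, chosen as the smallest
sizes where the measured quantities are stable: 200–1000 transcripts,
3–10 replicates/group, 10–50 simulation replicates per Monte-Carlo
estimate. All randomness flows from explicit seeds through
`numpy.random.default_rng`; a config seed fully determines every output
file byte-for-byte. The full-pipeline closure experiment (classification →
DE → triads recovering planted truth exactly) uses noiseless scores, a 5%
planted fraction at 3 log₂ units, dispersion 0.01, well-expressed baselines
(μ ~ lognormal(500, 0.5)) and 6 replicates/group — conditions under which
exact recovery is the correct expectation; the power caveats above explain
why weaker regimes recover truth only statistically.

## Known limitations

* The DE caller is a t-test surrogate, underpowered at 3 replicates and
  subject to total-count compositional bias (quantified above).
* The duplex model has no loops/bulges, so its energies are lower bounds on
  binding specificity compared to full secondary-structure tools.
* Enrichment treats terms independently (no GO DAG propagation).
* pI/MW constants are conventional, not fitted to any particular server.
* Correlation thresholds at the 3-replicate design (6 samples total) are
  dominated by the p < 0.05 requirement; results at smaller n are reported
  but near-degenerate.
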