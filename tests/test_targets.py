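"""cis windows, duplex energy, coexpression, and overlap classes."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from cernet import (SimulationConfig, cis_targets, classify_overlap,
                    coexpression_targets, duplex_energy, generate_annotation,
                    trans_targets)
from cernet.constants import RNA_COMPLEMENT, RNA_STACK_ENERGY
from conftest import make_record


def lnc(tid="L", start=100_000, end=101_000, strand="+"):
    return make_record(tid, start=start, end=end,
                       exons=((start, start + 300), (end - 300, end)),
                       strand=strand, biotype="lncRNA")


def gene(tid, start, end, strand="+"):
    return make_record(tid, start=start, end=end,
                       exons=((start, start + 100), (end - 100, end)),
                       strand=strand, biotype="mRNA")


class TestCisTargets:
    def test_gene_5kb_upstream_paired_with_negative_distance(self):
        l = lnc()
        g = gene("G", l.start - 5_000 - 2_000, l.start - 5_000)
        pairs = cis_targets([l], [g])
        assert len(pairs) == 1
        assert pairs[0].distance == -5_000

    def test_asymmetric_window(self):
        l = lnc()
        up15 = gene("U", l.start - 15_000 - 500, l.start - 15_000)
        down15 = gene("D", l.end + 15_000, l.end + 15_000 + 500)
        got = {p.gene_id for p in cis_targets([l], [up15, down15])}
        assert got == {"D"}  # 15 kb exceeds the 10 kb upstream window only

    def test_minus_strand_flips_orientation(self):
        l = lnc(strand="-")
        # on the minus strand, upstream (5') is to the RIGHT of the locus
        right15 = gene("R", l.end + 15_000, l.end + 15_500)   # 15 kb upstream
        left15 = gene("Le", l.start - 15_500, l.start - 15_000)  # downstream
        got = {p.gene_id: p.distance for p in cis_targets([l], [right15, left15])}
        assert set(got) == {"Le"}
        assert got["Le"] == 15_000  # downstream -> positive

    def test_overlapping_gene_distance_zero(self):
        l = lnc()
        g = gene("G", l.start + 100, l.end + 5_000)
        (pair,) = cis_targets([l], [g])
        assert pair.distance == 0
        assert pair.overlap_class != "none"

    def test_matches_brute_force_interval_scan(self):
        cfg = SimulationConfig(seed=37, n_mrna=200, n_lncrna=20,
                               genome_length=8_000_000)
        records, _ = generate_annotation(cfg)
        lncs = [r for r in records if r.biotype == "lncRNA"]
        genes = [r for r in records if r.biotype == "mRNA"]
        got = {(p.lncrna_id, p.gene_id) for p in cis_targets(lncs, genes)}
        expected = set()
        for l in lncs:  # independent O(n^2) re-derivation
            if l.strand == "+":
                lo, hi = l.start - 10_000, l.end + 20_000
            else:
                lo, hi = l.start - 20_000, l.end + 10_000
            for g in genes:
                if g.chrom == l.chrom and g.start <= hi and g.end >= lo:
                    expected.add((l.id, g.id))
        assert got == expected

    def test_window_monotonicity(self):
        cfg = SimulationConfig(seed=41, n_mrna=60, n_lncrna=15)
        records, _ = generate_annotation(cfg)
        lncs = [r for r in records if r.biotype == "lncRNA"]
        genes = [r for r in records if r.biotype == "mRNA"]
        small = {(p.lncrna_id, p.gene_id)
                 for p in cis_targets(lncs, genes, 5_000, 10_000)}
        big = {(p.lncrna_id, p.gene_id)
               for p in cis_targets(lncs, genes, 10_000, 20_000)}
        assert small <= big

    def test_one_lncrna_can_hit_many_genes(self):
        l = lnc()
        gs = [gene(f"G{i}", l.end + 1_000 * i, l.end + 1_000 * i + 400)
              for i in range(1, 6)]
        pairs = cis_targets([l], gs)
        assert len(pairs) >= len({p.lncrna_id for p in pairs})


def revcomp_rna(seq: str) -> str:
    return "".join(RNA_COMPLEMENT[c] for c in reversed(seq))


class TestDuplexEnergy:
    def test_no_complementarity_is_zero(self):
        assert duplex_energy("AAAA", "AAAA") == 0.0

    def test_perfect_gc_rich_30mer_below_minus_30(self):
        seq = "GCGGCCGCGGCGCCGGCGGCCGCGGCGCCG"
        e = duplex_energy(seq, revcomp_rna(seq))
        # oracle: full helix energy is the sum of the 29 stack terms
        expected = sum(RNA_STACK_ENERGY[seq[i:i + 2]] for i in range(len(seq) - 1))
        assert e == pytest.approx(expected)
        assert e < -30.0

    def test_partial_helix_equals_stack_sum_oracle(self):
        # flanks chosen so they cannot pair with anything and extend the helix
        helix = "GCAUGC"
        a = "AAAA" + helix + "AAAA"
        b = "CCC" + revcomp_rna(helix) + "CCCCC"
        expected = sum(RNA_STACK_ENERGY[helix[i:i + 2]] for i in range(len(helix) - 1))
        assert duplex_energy(a, b) == pytest.approx(expected)

    def test_t_accepted_as_u(self):
        assert duplex_energy("GCGC", "GCGC") == duplex_energy("GCGC", "GCGC".replace("C", "C"))
        assert duplex_energy("ATGC", "GCAT") == duplex_energy("AUGC", "GCAU")

    def test_bad_character_rejected(self):
        with pytest.raises(ValueError, match="non-nucleotide"):
            duplex_energy("ACGX", "ACGU")

    @given(st.text(alphabet="ACGU", min_size=2, max_size=25),
           st.text(alphabet="ACGU", min_size=2, max_size=25))
    @settings(max_examples=100, deadline=None)
    def test_symmetry(self, a, b):
        assert duplex_energy(a, b) == pytest.approx(duplex_energy(b, a))

    @given(st.text(alphabet="ACGU", min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_self_hybridisation_never_positive(self, a):
        assert duplex_energy(a, revcomp_rna(a)) <= 0.0


class TestTransTargets:
    @staticmethod
    def _setup():
        l = lnc("L", start=100_000, end=101_000)
        near = gene("NEAR", 105_000, 106_000)       # inside 20 kb downstream
        far = gene("FAR", 900_000, 901_000)         # well outside the window
        helix = "GCGGCCGCGGCGCCGGCGGCCGCGGCGCCGGCGGCCGCGG"  # 40 nt
        seqs = {"L": "AAAAAAAAAA" + helix,
                "NEAR": "UUUU" + revcomp_rna(helix),
                "FAR": "UUUU" + revcomp_rna(helix)}
        return l, near, far, seqs

    def test_perfect_complement_outside_window_is_trans(self):
        l, near, far, seqs = self._setup()
        pairs = trans_targets([l], [near, far], sequences=seqs)
        assert {p.gene_id for p in pairs} == {"FAR"}
        assert pairs[0].energy < -30

    def test_complement_inside_cis_window_not_trans(self):
        l, near, far, seqs = self._setup()
        cis = {p.gene_id for p in cis_targets([l], [near, far])}
        trans = {p.gene_id for p in trans_targets([l], [near, far], sequences=seqs)}
        assert "NEAR" in cis and "NEAR" not in trans
        assert cis.isdisjoint(trans)  # mutual exclusion

    def test_energy_exactly_at_threshold_excluded(self):
        l, near, far, _ = self._setup()
        at = trans_targets([l], [far], energies={("L", "FAR"): -30.0})
        below = trans_targets([l], [far], energies={("L", "FAR"): -30.0001})
        assert at == [] and len(below) == 1

    def test_missing_sequence_errors(self):
        l, near, far, seqs = self._setup()
        del seqs["FAR"]
        with pytest.raises(ValueError, match="missing sequence"):
            trans_targets([l], [far], sequences=seqs)


class TestCoexpression:
    @staticmethod
    def _frames():
        rng = np.random.default_rng(5)
        samples = [f"s{i}" for i in range(8)]
        lnc_expr = pd.DataFrame(rng.normal(size=(6, 8)),
                                index=[f"L{i}" for i in range(6)], columns=samples)
        gene_expr = pd.DataFrame(rng.normal(size=(10, 8)),
                                 index=[f"G{i}" for i in range(10)], columns=samples)
        return lnc_expr, gene_expr

    def test_identical_profile_included(self):
        lnc_expr, gene_expr = self._frames()
        gene_expr.loc["G0"] = lnc_expr.loc["L0"]
        pairs = coexpression_targets(lnc_expr, gene_expr)
        match = [p for p in pairs if (p.lncrna_id, p.gene_id) == ("L0", "G0")]
        assert match and match[0].r_pearson == pytest.approx(1.0)

    def test_anticorrelated_excluded_signed_included_absolute(self):
        lnc_expr, gene_expr = self._frames()
        gene_expr.loc["G1"] = -lnc_expr.loc["L1"]
        signed = {(p.lncrna_id, p.gene_id)
                  for p in coexpression_targets(lnc_expr, gene_expr)}
        unsigned = {(p.lncrna_id, p.gene_id)
                    for p in coexpression_targets(lnc_expr, gene_expr, absolute=True)}
        assert ("L1", "G1") not in signed
        assert ("L1", "G1") in unsigned

    def test_matches_direct_formula_oracle(self):
        from scipy import stats as ss
        lnc_expr, gene_expr = self._frames()
        gene_expr.loc["G2"] = lnc_expr.loc["L2"] + 0.1 * np.random.default_rng(1).normal(size=8)
        got = {(p.lncrna_id, p.gene_id)
               for p in coexpression_targets(lnc_expr, gene_expr)}
        expected = set()
        for lid in lnc_expr.index:
            for gid in gene_expr.index:
                r = ss.pearsonr(lnc_expr.loc[lid], gene_expr.loc[gid]).statistic
                rho = ss.spearmanr(lnc_expr.loc[lid], gene_expr.loc[gid]).statistic
                if r >= 0.6 and rho >= 0.6:
                    expected.add((lid, gid))
        assert got == expected

    def test_zero_variance_profile_skipped_with_warning(self):
        lnc_expr, gene_expr = self._frames()
        gene_expr.loc["G3"] = 1.0
        with pytest.warns(UserWarning, match="zero-variance"):
            pairs = coexpression_targets(lnc_expr, gene_expr)
        assert all(p.gene_id != "G3" for p in pairs)


class TestClassifyOverlap:
    CASES = [
        # (lnc span, lnc strand, gene span, gene strand, expected)
        ((100, 200), "+", (50, 400), "+", "overlap"),         # lnc inside gene
        ((50, 400), "+", (100, 200), "+", "overlap"),         # gene inside lnc
        ((100, 200), "+", (50, 400), "-", "anti-overlap"),
        ((100, 300), "+", (200, 500), "+", "incomplete"),     # partial, same
        ((350, 600), "-", (200, 500), "+", "anti-incomplete"),  # straddles 3' end
        ((100, 200), "+", (300, 400), "+", "none"),
    ]

    @pytest.mark.parametrize("lspan,lstrand,gspan,gstrand,expected", CASES)
    def test_truth_table(self, lspan, lstrand, gspan, gstrand, expected):
        l = make_record("L", start=lspan[0], end=lspan[1], strand=lstrand,
                        exons=((lspan[0], lspan[1]),))
        g = make_record("G", start=gspan[0], end=gspan[1], strand=gstrand,
                        exons=((gspan[0], gspan[1]),))
        assert classify_overlap(l, g) == expected

    def test_matches_exhaustive_enumeration(self):
        """All span relations x strand combinations agree with an independent
        truth-table re-derivation."""
        spans = [(100, 200), (150, 250), (100, 300), (120, 180), (400, 500)]
        for ls in spans:
            for gs in spans:
                for lst in "+-":
                    for gst in "+-":
                        l = make_record("L", start=ls[0], end=ls[1], strand=lst,
                                        exons=(ls,))
                        g = make_record("G", start=gs[0], end=gs[1], strand=gst,
                                        exons=(gs,))
                        if ls[1] < gs[0] or gs[1] < ls[0]:
                            expected = "none"
                        else:
                            contain = ((ls[0] >= gs[0] and ls[1] <= gs[1])
                                       or (gs[0] >= ls[0] and gs[1] <= ls[1]))
                            same = lst == gst
                            expected = ("overlap" if contain else "incomplete")
                            if not same:
                                expected = "anti-" + expected
                        assert classify_overlap(l, g) == expected
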