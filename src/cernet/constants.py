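"""Embedded physical-chemistry constant tables.

All thermodynamic and protein constants used by :mod:`cernet.targets` and
:mod:`cernet.genechar` live here so that they can be audited or retuned in
one place.
"""

# ---------------------------------------------------------------------------
# RNA/RNA nearest-neighbor stacking free energies (kcal/mol, 37 degC) for
# antiparallel Watson-Crick helices, Turner-style values.  Keyed by the 5'->3'
# dinucleotide on one strand; the paired strand is its reverse complement.
# Keys related by helix rotation (x1x2 / y1y2 == y2y1 / x2x1) share a value.
# ---------------------------------------------------------------------------
RNA_STACK_ENERGY: dict[str, float] = {
    "AA": -0.93, "UU": -0.93,
    "AU": -1.10,
    "UA": -1.33,
    "CU": -2.08, "AG": -2.08,
    "CA": -2.11, "UG": -2.11,
    "GU": -2.24, "AC": -2.24,
    "GA": -2.35, "UC": -2.35,
    "CG": -2.36,
    "GG": -3.26, "CC": -3.26,
    "GC": -3.42,
}

#: Watson-Crick complement on the RNA alphabet.
RNA_COMPLEMENT: dict[str, str] = {"A": "U", "U": "A", "G": "C", "C": "G"}

# ---------------------------------------------------------------------------
# Average (isotope-abundance weighted) residue masses in Daltons: the mass of
# the amino acid monomer minus one water, i.e. the mass each residue adds to a
# peptide chain.  Conventional values as used by common protein-parameter
# servers.  A free peptide adds one WATER_MASS for its termini.
# ---------------------------------------------------------------------------
RESIDUE_MASS: dict[str, float] = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS: float = 18.01524

# ---------------------------------------------------------------------------
# Side-chain and terminal pKa values (Bjellqvist-style, as popularised by the
# ExPASy pI tool family).  Basic groups are protonated (charge +1) below their
# pKa; acidic groups are deprotonated (charge -1) above theirs.
# ---------------------------------------------------------------------------
PKA_POSITIVE: dict[str, float] = {
    "nterm": 7.50,
    "K": 10.00,
    "R": 12.00,
    "H": 5.98,
}

PKA_NEGATIVE: dict[str, float] = {
    "cterm": 3.55,
    "D": 4.05,
    "E": 4.45,
    "C": 9.00,
    "Y": 10.00,
}
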