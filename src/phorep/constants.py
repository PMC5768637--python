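"""Physical and biochemical constants shared across modules.

Sources: average amino-acid residue masses and the Bjellqvist pKa set follow
the ExPASy ProtParam conventions; van der Waals radii are Bondi (1964) for
main-group elements, with commonly used extensions for metals; phosphoric
acid dissociation constants and the water ion product are 25 degC values from
standard critical compilations (NIST 46 / Smith & Martell); the
hydroxyapatite solubility product follows Fujita et al. (log Ks = -57.74).
"""

from __future__ import annotations

PROTEIN_ALPHABET = "ACDEFGHIKLMNPQRSTVWY"
PROTEIN_ALPHABET_X = PROTEIN_ALPHABET + "X"
DNA_ALPHABET = "ACGT"
DNA_ALPHABET_N = DNA_ALPHABET + "N"

DNA_COMPLEMENT = {"A": "T", "C": "G", "G": "C", "T": "A", "N": "N"}

#: Average (isotope-weighted) residue masses in Da, as used by ProtParam.
AVERAGE_RESIDUE_MASS = {
    "A": 71.0788, "R": 156.1875, "N": 114.1038, "D": 115.0886,
    "C": 103.1388, "E": 129.1155, "Q": 128.1307, "G": 57.0519,
    "H": 137.1411, "I": 113.1594, "L": 113.1594, "K": 128.1741,
    "M": 131.1926, "F": 147.1766, "P": 97.1167, "S": 87.0782,
    "T": 101.1051, "W": 186.2132, "Y": 163.1760, "V": 99.1326,
}

WATER_MASS = 18.0153  # Da

#: Bjellqvist pKa values (ProtParam's set). Side chains plus termini;
#: the N-terminal pKa depends on the first residue.
PKA_BJELLQVIST = {
    "positive": {"K": 10.0, "R": 12.0, "H": 5.98},
    "negative": {"D": 4.05, "E": 4.45, "C": 9.0, "Y": 10.0},
    "nterm": 7.5,
    "nterm_by_residue": {
        "A": 7.59, "M": 7.0, "S": 6.93, "P": 8.36,
        "T": 6.82, "V": 7.44, "E": 7.7,
    },
    "cterm": 3.55,
    "cterm_by_residue": {"D": 4.55, "E": 4.75},
}

#: EMBOSS pKa set, selectable as an alternative convention.
PKA_EMBOSS = {
    "positive": {"K": 10.8, "R": 12.5, "H": 6.5},
    "negative": {"D": 3.9, "E": 4.1, "C": 8.5, "Y": 10.1},
    "nterm": 8.6,
    "nterm_by_residue": {},
    "cterm": 3.6,
    "cterm_by_residue": {},
}

#: Van der Waals radii in Angstrom, keyed by element symbol (upper case).
VDW_RADII = {
    "H": 1.20, "C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "P": 1.80,
    "SE": 1.90, "F": 1.47, "CL": 1.75, "BR": 1.85, "I": 1.98,
    # metals commonly found as phosphatase co-factors
    "CA": 2.31, "MG": 1.73, "FE": 2.05, "ZN": 2.10, "MN": 2.05, "NA": 2.27,
    "K": 2.75, "CU": 2.00,
}

#: Robinson & Robinson (1991) amino-acid background frequencies.
ROBINSON_FREQUENCIES = {
    "A": 0.07805, "R": 0.05129, "N": 0.04487, "D": 0.05364, "C": 0.01925,
    "Q": 0.04264, "E": 0.06295, "G": 0.07377, "H": 0.02199, "I": 0.05142,
    "L": 0.09019, "K": 0.05744, "M": 0.02243, "F": 0.03856, "P": 0.05203,
    "S": 0.07120, "T": 0.05841, "W": 0.01330, "Y": 0.03216, "V": 0.06441,
}

#: Karlin-Altschul parameters for gapped Smith-Waterman with BLOSUM62 and
#: affine gap penalties 11 (open) / 1 (extend), as tabulated by NCBI BLAST.
BLOSUM62_GAPPED_LAMBDA = 0.267  # nats per score unit
BLOSUM62_GAPPED_K = 0.041

# --- geochemistry (25 degC) -------------------------------------------------

#: Orthophosphoric acid dissociation constants (negative decadic logs).
PHOSPHORIC_PKA = (2.148, 7.199, 12.35)

#: Water ion product.
LOG_KW = -14.0

#: Debye-Hueckel A coefficient for the Davies equation at 25 degC.
DAVIES_A = 0.509

#: Hydroxyapatite Ca5(PO4)3OH solubility product, log10 scale.
LOG_K_HYDROXYAPATITE = -57.74

#: Default detection limits below which a saturation index is not reported.
DETECTION_LIMIT_PI = 0.85e-6   # mol/L
DETECTION_LIMIT_CA = 50e-6     # mol/L

#: p-nitrophenol molar extinction coefficient at 405 nm.
EPSILON_PNP_405 = 18000.0      # 1/(M cm)
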