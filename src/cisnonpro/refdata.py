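"""Reference data shared across the pipeline.

Covalent backbone geometry targets (Engh & Huber style means and esds), van
der Waals radii for the heavy-atom clash approximation, the UniProtKB
background amino-acid frequencies used to normalise occurrence counts, and
the published first/second-position occurrence table with its significance
flags.  The geometry table here is the single source of truth: the synthetic
builder constructs backbones at exactly these values, so an undistorted build
scores zero on the covalent-geometry outlier filter by construction.
"""

from __future__ import annotations

AA3 = (
    "ALA", "ARG", "ASN", "ASP", "CYS", "GLN", "GLU", "GLY", "HIS", "ILE",
    "LEU", "LYS", "MET", "PHE", "PRO", "SER", "THR", "TRP", "TYR", "VAL",
)

AA3_TO_1 = {
    "ALA": "A", "ARG": "R", "ASN": "N", "ASP": "D", "CYS": "C",
    "GLN": "Q", "GLU": "E", "GLY": "G", "HIS": "H", "ILE": "I",
    "LEU": "L", "LYS": "K", "MET": "M", "PHE": "F", "PRO": "P",
    "SER": "S", "THR": "T", "TRP": "W", "TYR": "Y", "VAL": "V",
    "UNK": "X",
}
AA1_TO_3 = {v: k for k, v in AA3_TO_1.items()}

# Backbone covalent geometry: target value and esd.
# Bonds in Angstrom; "C-N+" is the peptide link to the next residue.
BOND_REFERENCE = {
    "N-CA": (1.458, 0.019),
    "CA-C": (1.525, 0.021),
    "C-O": (1.231, 0.020),
    "C-N+": (1.329, 0.014),
    "CA-CB": (1.530, 0.020),
}

# Angles in degrees; "-C" / "N+" refer to the previous / next residue.
ANGLE_REFERENCE = {
    "N-CA-C": (111.2, 2.8),
    "CA-C-N+": (116.2, 2.0),
    "-C-N-CA": (121.7, 1.8),
    "CA-C-O": (120.8, 1.7),
}

# Heavy-atom van der Waals radii (Angstrom) for the clash approximation.
VDW_RADII = {"C": 1.70, "N": 1.55, "O": 1.52, "S": 1.80, "SE": 1.90, "P": 1.80}

# Background amino-acid frequencies (fractions) from UniProtKB/TrEMBL
# statistics, the normalisation column of the published occurrence table.
UNIPROT_FREQUENCIES = {
    "LEU": 0.0985, "ALA": 0.0903, "GLY": 0.0723, "VAL": 0.0686,
    "SER": 0.0673, "GLU": 0.0616, "ILE": 0.0572, "ARG": 0.0569,
    "THR": 0.0558, "ASP": 0.0544, "LYS": 0.0503, "PRO": 0.0485,
    "PHE": 0.0393, "ASN": 0.0391, "GLN": 0.0380, "TYR": 0.0294,
    "MET": 0.0239, "HIS": 0.0220, "TRP": 0.0129, "CYS": 0.0122,
}

# Published occurrence counts of each amino acid in the first and second
# position of a cis-nonPro bond, split by CAZy membership of the chain, with
# the printed significance marks: "depleted" = italic (>= 3 sigma below
# expectation), "over" = bold (3-12 sigma above), "over12" = bold italic
# (>= 12 sigma above), "" = unmarked.  The printed column totals (144 CAZy /
# 295 non-CAZy peptides, stored below) are the sample sizes used for the
# sigma normalisation; note that the transcribed cells of two columns sum a
# couple of counts away from those totals, an inconsistency carried by the
# source table itself.
PUBLISHED_POSITION_COUNTS = {
    #        (CAZy 1st)      (CAZy 2nd)      (nonCAZy 1st)   (nonCAZy 2nd)
    "LEU": ((1, "depleted"), (2, "depleted"), (16, ""), (13, "")),
    "ALA": ((12, ""), (11, ""), (23, ""), (14, "")),
    "GLY": ((22, "over"), (6, ""), (77, "over12"), (30, "")),
    "VAL": ((1, ""), (6, ""), (12, ""), (18, "")),
    "SER": ((9, ""), (26, "over"), (12, ""), (29, "")),
    "GLU": ((13, ""), (12, ""), (15, ""), (15, "")),
    "ILE": ((0, ""), (0, ""), (5, ""), (13, "")),
    "ARG": ((2, ""), (3, ""), (6, ""), (7, "")),
    "THR": ((5, ""), (13, ""), (6, ""), (32, "over")),
    "ASP": ((2, ""), (8, ""), (28, ""), (35, "over")),
    "LYS": ((3, ""), (2, ""), (5, ""), (9, "")),
    "PRO": ((3, ""), (0, ""), (26, "over"), (0, "")),
    "PHE": ((6, ""), (20, "over"), (12, ""), (7, "")),
    "ASN": ((2, ""), (5, ""), (7, ""), (17, "")),
    "GLN": ((3, ""), (4, ""), (7, ""), (3, "")),
    "TYR": ((4, ""), (7, ""), (10, ""), (26, "over")),
    "MET": ((2, ""), (2, ""), (2, ""), (2, "")),
    "HIS": ((9, "over"), (11, "over"), (11, ""), (11, "")),
    "TRP": ((44, "over12"), (5, ""), (6, ""), (8, "")),
    "CYS": ((1, ""), (2, ""), (7, ""), (4, "")),
}

# Printed column totals of the occurrence table (peptide counts per stratum).
PUBLISHED_POSITION_TOTALS = {"cazy": 144, "non_cazy": 295}

# Reference survey scale: chains in the quality-filtered low-redundancy
# crystal-structure reference set and the fraction of them that are
# carbohydrate-active (CAZy members).
REFERENCE_CHAIN_TOTAL = 6765
REFERENCE_CAZY_FRACTION = 0.06
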