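"""Published reference numbers used as inputs by the analyses.

``H4_FAMILY_CENSUS_COUNTS`` is the published family-wide census of the
residue at the H+4 position over ~10,000 non-redundant HPt sequences
(Pfam family PF01627, redundancy removed at 98% identity, anchor-less
sequences dropped). The counts are the input; the package recomputes the
percent-of-total arithmetic from them. A live Pfam download would give
release-dependent counts and is deliberately not part of the package.

``KD_TABLE_UM`` lists the reported dissociation constants (μM, mean ± SD
over three replicate titrations) for the labelled HPt protein against its
upstream receiver domain; ``ACTIVITY_TABLE_PERCENT`` the reported
phosphorylation / phosphorelay activities (percent of wild type ± SD,
three replicates). These serve as generator design levels for synthetic
emulations — the underlying raw fluorescence and gel data were never
deposited, so the tables cannot be recomputed from primary data.
"""

H4_FAMILY_CENSUS_COUNTS: dict[str, int] = {
    "G": 8757,
    "S": 1051,
    "P": 98,
    "A": 76,
    "T": 31,
    "N": 28,
    "H": 12,
    "E": 6,
    "D": 4,
    "R": 3,
    "V": 2,
    "I": 1,
    "C": 1,
    "L": 1,
    "Q": 1,
    "Y": 1,
    "W": 0,
}

#: Kd in μM: (mean, sd) over three replicate titrations
KD_TABLE_UM: dict[str, tuple[float, float]] = {
    "WT": (0.94, 0.38),
    "G68V": (2.9, 0.08),
    "G68L": (1.3, 0.09),
    "G68E": (0.5, 0.13),
    "G68Q": (0.6, 0.27),
}

#: percent of wild type: (phosphorylation mean, sd, phosphorelay mean, sd)
ACTIVITY_TABLE_PERCENT: dict[str, tuple[float, float, float, float]] = {
    "WT": (100.0, 0.0, 100.0, 0.0),
    "G68S": (94.0, 3.6, 81.0, 18.0),
    "G68A": (82.0, 16.0, 80.0, 8.0),
    "G68V": (2.5, 3.5, 0.36, 0.6),
    "G68L": (0.4, 0.6, 0.28, 0.5),
    "G68E": (0.3, 0.5, 0.08, 0.15),
    "G68Q": (40.0, 8.3, 0.9, 1.6),
}

#: assay constants: 30 pmol labelled receptor in 1.9 mL ≈ 15.8 nM
RECEPTOR_TOTAL_M: float = 30e-12 / 1.9e-3

#: 1-based residue range of the N-terminal helix and following turn (αA)
ALPHA_A_RANGE: tuple[int, int] = (11, 21)
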