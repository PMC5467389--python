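"""Monoisotopic mass constants.

All peptide mass arithmetic in the package goes through this single table so
the numerical provenance is in one place.  Residue masses are the standard
monoisotopic values for the 20 canonical amino-acid residues (i.e. the mass of
the residue inside a chain, without the terminal water).
"""

# Monoisotopic residue masses in Da.
MONOISOTOPIC_RESIDUE_MASS: dict[str, float] = {
    "G": 57.02146,
    "A": 71.03711,
    "S": 87.03203,
    "P": 97.05276,
    "V": 99.06841,
    "T": 101.04768,
    "C": 103.00919,
    "L": 113.08406,
    "I": 113.08406,
    "N": 114.04293,
    "D": 115.02694,
    "Q": 128.05858,
    "K": 128.09496,
    "E": 129.04259,
    "M": 131.04049,
    "H": 137.05891,
    "F": 147.06841,
    "R": 156.10111,
    "Y": 163.06333,
    "W": 186.07931,
}

#: Monoisotopic mass of water (the peptide termini), Da.
WATER = 18.010565

#: Mass of a proton, Da (charge carrier for positive-mode m/z).
PROTON = 1.007276

#: Monoisotopic mass shift of one phosphorylation (HPO3), Da.
PHOSPHO = 79.966331

#: Residues that can carry a phosphate group.
PHOSPHORYLATABLE = frozenset("STY")

#: The canonical amino-acid alphabet.
CANONICAL_RESIDUES = frozenset(MONOISOTOPIC_RESIDUE_MASS)
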