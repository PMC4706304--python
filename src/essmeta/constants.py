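"""Physical constants and unit conventions.

Internal units throughout the package: length nm, time ps, energy kJ/mol,
temperature K, mass amu.  Angles are stored in radians internally and
reported in degrees at user-facing boundaries.  PDB coordinates (Å) are
converted to nm at the I/O boundary only.
"""

#: Boltzmann constant, kJ/mol/K
KB = 0.0083144621

#: Å per nm (PDB files store Å)
ANGSTROM_PER_NM = 10.0

#: Average residue masses (amu) used as per-residue Cα proxy masses.
#: Monoisotopic residue masses rounded to 0.01; used when a structure does
#: not carry explicit masses.
RESIDUE_MASSES = {
    "ALA": 71.08, "ARG": 156.19, "ASN": 114.10, "ASP": 115.09,
    "CYS": 103.14, "GLN": 128.13, "GLU": 129.12, "GLY": 57.05,
    "HIS": 137.14, "ILE": 113.16, "LEU": 113.16, "LYS": 128.17,
    "MET": 131.19, "PHE": 147.18, "PRO": 97.12, "SER": 87.08,
    "THR": 101.10, "TRP": 186.21, "TYR": 163.18, "VAL": 99.13,
}

#: Fallback proxy mass (amu) for unknown residue names (average amino acid).
DEFAULT_RESIDUE_MASS = 110.0


def residue_mass(residue_name: str) -> float:
    """Per-residue Cα proxy mass in amu for a three-letter residue name."""
    return RESIDUE_MASSES.get(residue_name.upper(), DEFAULT_RESIDUE_MASS)
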