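"""Physical constants and default analysis thresholds.

Monoisotopic residue masses are the standard values for the 20 canonical
amino acids (residue = amino acid minus water). The two iodoacetamide
adduct masses differ by six 13C substitutions worth of mass.
"""

from __future__ import annotations

#: Monoisotopic masses of amino-acid *residues* (Da).
RESIDUE_MASSES: dict[str, float] = {
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

CANONICAL_RESIDUES = frozenset(RESIDUE_MASSES)

#: Monoisotopic mass of water (Da), added once per peptide.
WATER_MASS = 18.010565

#: Light iodoacetamide-alkyne cysteine adduct (Da).
IA_LIGHT_MASS = 306.14806
#: Heavy (6x 13C) iodoacetamide-alkyne cysteine adduct (Da).
IA_HEAVY_MASS = 312.16819
#: Heavy minus light adduct mass per labeled cysteine (Da).
ADDUCT_MASS_DIFF = IA_HEAVY_MASS - IA_LIGHT_MASS  # 6.02013

#: Default light:heavy ratio cap for a missing/zero heavy channel.
DEFAULT_RATIO_CAP = 20.0

#: Sites whose total oxidized fraction reaches this value are censored
#: (not observable) in competitive-profiling simulations.
FULL_OXIDATION_CENSOR = 0.98

#: Replicate-consistency filter defaults.
DEFAULT_FOLD_THRESHOLD = 2.0
DEFAULT_CV_THRESHOLD = 0.5
DEFAULT_SD_THRESHOLD = 30.0  # percentage points

#: Sensitivity class boundaries on the top-dose mean ratio.
DEFAULT_CLASS_BOUNDS = (2.0, 5.0)

#: Minimum percentage-point difference to call a condition change.
DEFAULT_MIN_DELTA = 20.0

#: Co-elution QC defaults.
DEFAULT_APEX_LIMIT_S = 10.0
DEFAULT_CORR_LIMIT = 0.8
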