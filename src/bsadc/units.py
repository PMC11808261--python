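"""Unit conversions, centralized.

Convention used throughout the package: file I/O and user-facing series are in
minutes and mM; rate constants (kcat, kinact) are per second; enzyme
concentrations are in uM because typical loadings (~25 ug/mL of a ~14 kDa
monomer) land in the low-micromolar range, while substrate and product are mM.
"""

from __future__ import annotations

from Bio.SeqUtils import molecular_weight

UM_PER_MM = 1000.0
S_PER_MIN = 60.0


def um_to_mm(x: float) -> float:
    return x / UM_PER_MM


def mm_to_um(x: float) -> float:
    return x * UM_PER_MM


def per_min_to_per_s(x: float) -> float:
    return x / S_PER_MIN


def per_s_to_per_min(x: float) -> float:
    return x * S_PER_MIN


def protein_molar_mass(residues: str) -> float:
    """Average molar mass (g/mol) of an unmodified protein chain."""
    return molecular_weight(residues, seq_type="protein")


def enzyme_molarity_um(mass_ug_per_ml: float, molar_mass_g_mol: float) -> float:
    """Molar concentration (uM) of an enzyme loaded by mass.

    ``mass_ug_per_ml`` ug/mL equals ``mass`` mg/L; dividing by the molar mass
    gives mmol/L * 1e-3 = mol/L; expressed in uM.
    """
    if mass_ug_per_ml < 0:
        raise ValueError("enzyme mass must be >= 0")
    if molar_mass_g_mol <= 0:
        raise ValueError("molar mass must be > 0")
    return mass_ug_per_ml / molar_mass_g_mol * 1000.0
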