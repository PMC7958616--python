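"""Formulation arithmetic for sugar-protein amorphous matrices.

Samples are prepared at matched molar concentration of *monosaccharide
units* rather than of sugar molecules, so that di- and trisaccharides are
comparable: a disaccharide counts 2 units, raffinose (trisaccharide) 3.
The sugar/protein ratio S/P is therefore

    S/P = sugar_molarity * units_per_molecule / protein_molarity

with S/P = inf for protein-free (binary sugar-water) matrices. Residual
hydration after drying is expressed as the water/saccharide molar ratio
W/S, convertible to a gram-per-gram ratio through the molar masses.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from typing import Mapping

from wabkit.errors import UsageError
from wabkit.spectra_io import PROTEIN_FREE

#: Molar mass of water, g/mol.
WATER_MOLAR_MASS = 18.015

#: Molar mass assumed for horse myoglobin, g/mol (configurable constant).
MYOGLOBIN_MOLAR_MASS = 16950.0


@dataclass(frozen=True)
class SugarSpec:
    """A saccharide: monosaccharide units per molecule and molar mass (g/mol)."""

    name: str
    units_per_molecule: int
    molar_mass: float

    def __post_init__(self):
        if self.units_per_molecule not in (2, 3):
            raise UsageError("units_per_molecule must be 2 (disaccharide) or 3 (trisaccharide)")
        if self.molar_mass <= 0:
            raise UsageError("molar_mass must be positive")


#: Anhydrous molar masses; the four disaccharides are isomers (C12H22O11).
SUGAR_SPECS: dict[str, SugarSpec] = {
    "trehalose": SugarSpec("trehalose", 2, 342.30),
    "sucrose": SugarSpec("sucrose", 2, 342.30),
    "maltose": SugarSpec("maltose", 2, 342.30),
    "lactose": SugarSpec("lactose", 2, 342.30),
    "raffinose": SugarSpec("raffinose", 3, 504.42),
}


@dataclass(frozen=True)
class SampleComposition:
    """Full formulation record for one sample."""

    sugar: SugarSpec
    sugar_molarity: float  # mol/L
    protein_molarity: float = 0.0  # mol/L; 0 for binary samples
    ws_molar: float | None = None  # water molecules per sugar molecule

    def __post_init__(self):
        if self.sugar_molarity < 0 or self.protein_molarity < 0:
            raise UsageError("concentrations must be >= 0")

    @property
    def sp(self) -> float:
        return sp_ratio(self.sugar_molarity, self.protein_molarity, self.sugar)


def sp_ratio(sugar_molarity: float, protein_molarity: float, sugar: SugarSpec) -> float:
    """Monosaccharide-units-per-protein molar ratio; inf when protein-free."""
    if protein_molarity == 0:
        return PROTEIN_FREE
    if protein_molarity < 0 or sugar_molarity < 0:
        raise UsageError("concentrations must be >= 0")
    return sugar_molarity * sugar.units_per_molecule / protein_molarity


def sugar_molarity_from_units(total_unit_molarity: float, sugar: SugarSpec) -> float:
    """Sugar molarity delivering a given total monosaccharide-unit molarity."""
    if total_unit_molarity < 0:
        raise UsageError("total_unit_molarity must be >= 0")
    return total_unit_molarity / sugar.units_per_molecule


def ws_mass_ratio(ws_molar: float, sugar: SugarSpec) -> float:
    """Convert a molar W/S ratio to grams of water per gram of sugar."""
    if ws_molar < 0:
        raise UsageError("ws_molar must be >= 0")
    return ws_molar * WATER_MOLAR_MASS / sugar.molar_mass


def ws_molar_from_mass(mass_ratio: float, sugar: SugarSpec) -> float:
    """Inverse of :func:`ws_mass_ratio`."""
    if mass_ratio < 0:
        raise UsageError("mass_ratio must be >= 0")
    return mass_ratio * sugar.molar_mass / WATER_MOLAR_MASS


def ws_minimum(ws_by_sp: Mapping[float, float]) -> float:
    """S/P ratio at which the residual water content W/S is smallest.

    Only finite S/P keys participate; ties break toward the smaller S/P.
    """
    finite = {sp: ws for sp, ws in ws_by_sp.items() if math.isfinite(sp)}
    if not finite:
        raise UsageError("ws_minimum: no finite S/P entries")
    return min(sorted(finite), key=lambda sp: finite[sp])


def round_reported(x: float, decimals: int = 2) -> float:
    """Round-half-even to the precision used in printed tables."""
    return round(x, decimals)


# ---------------------------------------------------------------------------
# reference formulation and residual-water data for the five-sugar,
# myoglobin-matrix study design these tools were built around

#: Residual water/saccharide molar ratio after drying, per sugar and S/P
#: (inf = protein-free). The minimum sits at S/P = 80 for every sugar.
RESIDUAL_WATER_RATIOS: dict[str, dict[float, float]] = {
    "trehalose": {20: 3.8, 40: 1.8, 80: 0.3, 160: 1.4, 320: 2.0, 640: 2.5, math.inf: 3.0},
    "sucrose": {20: 0.8, 40: 0.4, 80: 0.3, 160: 2.2, 320: 3.3, 640: 1.1, math.inf: 0.8},
    "maltose": {20: 1.2, 40: 0.5, 80: 0.3, 160: 1.2, 320: 2.4, math.inf: 4.0},
    "lactose": {20: 2.0, 40: 0.4, 80: 0.2, 160: 2.1, 320: 3.2, math.inf: 5.3},
    "raffinose": {20: 1.2, 40: 1.0, 80: 0.3, 160: 2.1, 320: 5.6, math.inf: 6.8},
}

#: Disaccharide formulation design: nominal S/P label -> (sugar mM, protein mM).
#: Protein-free samples carry protein 0. The S/P 640 row exists only for
#: sucrose and trehalose.
DISACCHARIDE_FORMULATIONS: dict[float, tuple[float, float]] = {
    20: (80.0, 8.0),
    40: (140.0, 7.0),
    80: (200.0, 5.0),
    160: (240.0, 3.0),
    320: (320.0, 2.0),
    640: (320.0, 1.0),
    math.inf: (400.0, 0.0),
}

#: Raffinose formulation design: nominal S/P label -> (sugar mM, protein mM).
#: Nominal labels are kept as printed; the computed S/P (3 units/molecule)
#: differs slightly (e.g. label 80 computes to 78) and is reported alongside
#: the label without reconciliation.
RAFFINOSE_FORMULATIONS: dict[float, tuple[float, float]] = {
    20: (50.0, 8.0),
    40: (90.0, 7.0),
    80: (130.0, 5.0),
    160: (160.0, 3.0),
    320: (210.0, 2.0),
    math.inf: (270.0, 0.0),
}


def formulation_table(sugar_name: str) -> list[dict[str, float]]:
    """Nominal vs computed S/P for the reference formulation design."""
    sugar = SUGAR_SPECS[sugar_name]
    design = RAFFINOSE_FORMULATIONS if sugar.units_per_molecule == 3 else DISACCHARIDE_FORMULATIONS
    rows = []
    for label, (sugar_mM, protein_mM) in design.items():
        rows.append(
            {
                "sp_label": label,
                "sugar_mM": sugar_mM,
                "protein_mM": protein_mM,
                "sp_computed": sp_ratio(sugar_mM, protein_mM, sugar),
            }
        )
    return rows
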