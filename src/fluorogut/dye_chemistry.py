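"""Fluorophore-labelling stoichiometry for FITC-Dextran conjugates.

Dextran is a glucose polymer; its degree of labelling is quantified either
per dextran chain (FITC:dextran molar ratio) or per anhydroglucose residue
(mol FITC per mol glucose).  The chain-level ratio is obtained from
absorbance via the Beer-Lambert law using the FITC extinction coefficient
at 494 nm, and the per-residue ratio follows by dividing by the number of
residues per chain.  The *effective FITC dose* of an oral FITC-Dextran
dose is the mass of FITC it carries — the number that determines whether
the conjugate is transcutaneously detectable.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np

__all__ = [
    "FITC_MW_G_PER_MOL",
    "GLUCOSE_RESIDUE_MW_G_PER_MOL",
    "FITC_EPSILON_494_M_CM",
    "LabelledDextran",
    "AbsorbanceMeasurement",
    "beer_lambert_concentration",
    "fitc_per_dextran_from_absorbance",
    "per_glucose_ratio",
    "effective_fitc_dose",
    "commercial_ratio_fold_change",
]

#: Molecular weight of fluorescein isothiocyanate.
FITC_MW_G_PER_MOL = 389.0

#: Anhydroglucose residue mass: each glucose in the polymer has lost one
#: water (162.14 = 180.16 - 18.02) per glycosidic bond.
GLUCOSE_RESIDUE_MW_G_PER_MOL = 162.14

#: Molar extinction coefficient of FITC at 494 nm.
FITC_EPSILON_494_M_CM = 77_000.0


@dataclass(frozen=True)
class LabelledDextran:
    """A FITC-labelled dextran conjugate."""

    dextran_mw_g_per_mol: float
    fitc_per_dextran: float
    fitc_mw_g_per_mol: float = FITC_MW_G_PER_MOL
    glucose_residue_mw_g_per_mol: float = GLUCOSE_RESIDUE_MW_G_PER_MOL

    def __post_init__(self) -> None:
        if self.dextran_mw_g_per_mol <= 0 or self.fitc_mw_g_per_mol <= 0:
            raise ValueError("molecular weights must be positive")
        if self.glucose_residue_mw_g_per_mol <= 0:
            raise ValueError("glucose residue mass must be positive")
        if self.fitc_per_dextran < 0:
            raise ValueError("fitc_per_dextran must be non-negative")

    @property
    def glucose_per_dextran(self) -> float:
        return self.dextran_mw_g_per_mol / self.glucose_residue_mw_g_per_mol

    @property
    def fitc_per_glucose(self) -> float:
        return per_glucose_ratio(
            self.fitc_per_dextran,
            self.dextran_mw_g_per_mol,
            self.glucose_residue_mw_g_per_mol,
        )


@dataclass(frozen=True)
class AbsorbanceMeasurement:
    """Absorbance at 494 nm of a conjugate solution of known concentration."""

    absorbance_494: float
    mass_concentration_mg_per_ml: float
    path_length_cm: float = 1.0

    def __post_init__(self) -> None:
        if not np.isfinite(self.absorbance_494) or self.absorbance_494 < 0:
            raise ValueError("absorbance must be finite and non-negative")
        if self.mass_concentration_mg_per_ml <= 0:
            raise ValueError("mass concentration must be positive")
        if self.path_length_cm <= 0:
            raise ValueError("path length must be positive")


def beer_lambert_concentration(
    absorbance: float,
    epsilon_M_cm: float = FITC_EPSILON_494_M_CM,
    path_cm: float = 1.0,
) -> float:
    """Molar concentration from absorbance: c = A / (epsilon * l)."""
    if absorbance < 0:
        raise ValueError(f"absorbance must be non-negative, got {absorbance:g}")
    if epsilon_M_cm <= 0 or path_cm <= 0:
        raise ValueError("epsilon and path length must be positive")
    return absorbance / (epsilon_M_cm * path_cm)


def fitc_per_dextran_from_absorbance(
    measurements: Sequence[AbsorbanceMeasurement],
    dextran_mw_g_per_mol: float,
    epsilon_M_cm: float = FITC_EPSILON_494_M_CM,
) -> float:
    """FITC:dextran molar ratio averaged over absorbance measurements.

    Per measurement, FITC molarity comes from Beer-Lambert and dextran
    molarity from the known mass concentration divided by the (unlabelled)
    dextran molecular weight; the reported ratio is the mean over
    measurements.  Under exact linearity all measurements agree, so the
    mean equals a line fit through the concentration series.
    """
    if len(measurements) == 0:
        raise ValueError("need at least one absorbance measurement")
    if dextran_mw_g_per_mol <= 0:
        raise ValueError("dextran molecular weight must be positive")
    ratios = []
    for m in measurements:
        fitc_M = beer_lambert_concentration(
            m.absorbance_494, epsilon_M_cm, m.path_length_cm
        )
        dextran_M = (m.mass_concentration_mg_per_ml) / dextran_mw_g_per_mol
        # mg/ml == g/L, so mass concentration divides directly by MW in g/mol
        ratios.append(fitc_M / dextran_M)
    return float(np.mean(ratios))


def per_glucose_ratio(
    fitc_per_dextran: float,
    dextran_mw_g_per_mol: float,
    glucose_residue_mw_g_per_mol: float = GLUCOSE_RESIDUE_MW_G_PER_MOL,
) -> float:
    """Convert a per-chain labelling ratio to mol FITC per mol glucose."""
    if dextran_mw_g_per_mol <= 0 or glucose_residue_mw_g_per_mol <= 0:
        raise ValueError("masses must be positive")
    if fitc_per_dextran < 0:
        raise ValueError("fitc_per_dextran must be non-negative")
    return fitc_per_dextran / (dextran_mw_g_per_mol / glucose_residue_mw_g_per_mol)


def effective_fitc_dose(
    dose_g: float,
    dextran_mw_g_per_mol: float,
    fitc_mw_g_per_mol: float,
    per_glucose: float,
    glucose_residue_mw_g_per_mol: float = GLUCOSE_RESIDUE_MW_G_PER_MOL,
) -> float:
    """Mass of FITC (mg) carried by an oral dose of labelled dextran.

    Glucose moles in the dose are ``dose_g / glucose_residue_mw`` (the
    dextran molecular weight cancels), each carrying ``per_glucose`` mol of
    FITC of mass ``fitc_mw``.
    """
    if dose_g < 0:
        raise ValueError("dose must be non-negative")
    if dextran_mw_g_per_mol <= 0 or fitc_mw_g_per_mol <= 0:
        raise ValueError("molecular weights must be positive")
    if glucose_residue_mw_g_per_mol <= 0:
        raise ValueError("glucose residue mass must be positive")
    if per_glucose < 0:
        raise ValueError("per-glucose ratio must be non-negative")
    glucose_mol = (dose_g / dextran_mw_g_per_mol) * (
        dextran_mw_g_per_mol / glucose_residue_mw_g_per_mol
    )
    return glucose_mol * per_glucose * fitc_mw_g_per_mol * 1000.0


def commercial_ratio_fold_change(
    synth_per_glucose: float, commercial_per_glucose: float
) -> float:
    """Fold change of a synthesised labelling ratio over a commercial one."""
    if synth_per_glucose <= 0 or commercial_per_glucose <= 0:
        raise ValueError("ratios must be positive")
    return synth_per_glucose / commercial_per_glucose
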