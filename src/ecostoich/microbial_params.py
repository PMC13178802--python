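"""Microbial biomass, basal respiration and the derived quotients.

Chloroform fumigation–extraction gives microbial biomass carbon and
nitrogen as the fumigated-minus-unfumigated flush divided by an extraction
efficiency (kEC, kEN).  Basal respiration comes from an alkali CO2 trap
back-titrated with acid (2 mol NaOH consumed per mol CO2).  Two quotients
summarise the physiological state of the community:

* metabolic quotient qCO2 = respiration per unit biomass carbon
  (mg CO2 g MBC-1 h-1) — high values indicate maintenance-dominated,
  stressed communities;
* microbial quotient Cmic/Corg = percentage of total organic carbon held
  in microbial biomass — high values indicate growth-available carbon.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import pandas as pd

from .soil_chemistry import ATOMIC_MASS, mass_to_molar
from .stoichiometry import ValidationError

__all__ = [
    "KEC_DEFAULT",
    "KEN_DEFAULT",
    "BiomassAssayRecord",
    "RespirationRecord",
    "mbc",
    "mbn",
    "basal_respiration",
    "metabolic_quotient",
    "microbial_quotient",
    "params_frame",
]

#: Default fumigation-extraction efficiency for carbon.
KEC_DEFAULT = 0.45
#: Default fumigation-extraction efficiency for nitrogen.
KEN_DEFAULT = 0.54

#: Molar mass of CO2 (g mol-1) used for respiration unit conversion.
CO2_MOLAR_MASS = 44.01


@dataclass(frozen=True)
class BiomassAssayRecord:
    """Fumigation-extraction readings (ug element per g soil)."""

    sample_id: str
    group: str
    C_fumigated: float
    C_unfumigated: float
    N_fumigated: float
    N_unfumigated: float
    kEC: float = KEC_DEFAULT
    kEN: float = KEN_DEFAULT

    def __post_init__(self) -> None:
        if not (0 < self.kEC <= 1 and 0 < self.kEN <= 1):
            raise ValidationError("extraction efficiencies must be in (0, 1]")


@dataclass(frozen=True)
class RespirationRecord:
    """Alkali-trap titration readings for basal respiration."""

    sample_id: str
    group: str
    blank_titre: float  # mL acid
    sample_titre: float  # mL acid
    acid_molarity: float  # mol L-1
    soil_mass: float  # g
    incubation_time: float  # h

    def __post_init__(self) -> None:
        if self.blank_titre < 0 or self.sample_titre < 0:
            raise ValidationError("titres must be >= 0")
        if self.soil_mass <= 0 or self.incubation_time <= 0 or self.acid_molarity <= 0:
            raise ValidationError("soil mass, incubation time and molarity must be positive")


def mbc(record: BiomassAssayRecord) -> tuple[float, bool]:
    """Microbial biomass carbon in umol C g-1: (C_fum - C_unfum)/kEC / 12.011.

    A fumigated reading below the unfumigated one gives a negative value,
    retained and flagged (second return value) rather than clamped.
    """
    flux = (record.C_fumigated - record.C_unfumigated) / record.kEC
    return flux / ATOMIC_MASS["C"], flux < 0


def mbn(record: BiomassAssayRecord) -> tuple[float, bool]:
    """Microbial biomass nitrogen in umol N g-1 (analogous to :func:`mbc`)."""
    flux = (record.N_fumigated - record.N_unfumigated) / record.kEN
    return flux / ATOMIC_MASS["N"], flux < 0


def basal_respiration(record: RespirationRecord) -> tuple[float, bool]:
    """Basal respiration in umol CO2 g soil-1 day-1 from trap titration.

    Trapped CO2 (umol) = (blank - sample) x molarity x 1000 / 2, since two
    NaOH neutralise one CO2; normalised by soil mass and to a 24 h day.
    A sample titre above the blank is physically invalid and flagged.
    """
    diff = record.blank_titre - record.sample_titre
    invalid = diff < 0
    co2_umol = diff * record.acid_molarity * 1000.0 / 2.0
    rate = co2_umol / record.soil_mass * (24.0 / record.incubation_time)
    return rate, invalid


def metabolic_quotient(MR: float, MBC: float) -> float:
    """qCO2 in mg CO2 g MBC-1 h-1 from MR (umol CO2 g-1 day-1) and MBC (umol C g-1)."""
    if MBC <= 0:
        return math.nan
    mr_mg_h = MR * CO2_MOLAR_MASS / 1000.0 / 24.0  # umol day-1 -> mg h-1
    mbc_g = MBC * ATOMIC_MASS["C"] * 1e-6  # umol g-1 -> g C g-1
    return mr_mg_h / mbc_g


def microbial_quotient(MBC: float, TOC: float) -> float:
    """Cmic/Corg in percent from MBC (umol C g-1) and TOC (g kg-1)."""
    if TOC <= 0:
        return math.nan
    return 100.0 * MBC / mass_to_molar(TOC, "C")


def params_frame(
    biomass: pd.DataFrame,
    respiration: pd.DataFrame,
    chemistry_derived: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-sample MBC, MBN, MR and quotients from tidy assay tables.

    ``biomass`` needs the fumigation-extraction columns (kEC/kEN optional),
    ``respiration`` the titration columns; TOC for the microbial quotient is
    merged from ``chemistry_derived`` by group when provided.
    """
    bio = biomass.copy()
    bio["kEC"] = bio.get("kEC", KEC_DEFAULT)
    bio["kEN"] = bio.get("kEN", KEN_DEFAULT)
    bio["MBC"] = (bio["C_fumigated"] - bio["C_unfumigated"]) / bio["kEC"] / ATOMIC_MASS["C"]
    bio["MBN"] = (bio["N_fumigated"] - bio["N_unfumigated"]) / bio["kEN"] / ATOMIC_MASS["N"]
    bio["negative_flux"] = (bio["MBC"] < 0) | (bio["MBN"] < 0)

    resp = respiration.copy()
    diff = resp["blank_titre"] - resp["sample_titre"]
    resp["MR"] = (
        diff * resp["acid_molarity"] * 1000.0 / 2.0
        / resp["soil_mass"] * (24.0 / resp["incubation_time"])
    )
    resp["invalid_titration"] = diff < 0

    out = bio[["sample_id", "group", "MBC", "MBN", "negative_flux"]].merge(
        resp[["sample_id", "MR", "invalid_titration"]], on="sample_id", how="left"
    )
    out["qCO2"] = [
        metabolic_quotient(mr, c) for mr, c in zip(out["MR"], out["MBC"])
    ]
    if chemistry_derived is not None and "TOC" in chemistry_derived.columns:
        toc = chemistry_derived.set_index("group")["TOC"]
        out["Cmic_Corg"] = [
            microbial_quotient(c, toc.get(g, math.nan)) for c, g in zip(out["MBC"], out["group"])
        ]
    return out
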