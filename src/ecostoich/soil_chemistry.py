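"""Soil chemistry derivations: organic carbon, molar ratios, fertility indices.

Measured inputs are the routine soil-fertility panel: pH (water and KCl),
organic matter (OM, g kg-1), total nitrogen (TN, mg kg-1), available
phosphorus (P, mg kg-1) and exchangeable cations plus potential acidity
(mmolc kg-1).  Derived quantities:

* TOC = OM / 1.724 (Van Bemmelen factor)
* molar C, N, P per gram of soil (atomic masses 12.011 / 14.007 / 30.974)
  and the molar ratios CS/NS, CS/PS, NS/PS
* sum of bases SB = Ca+Mg+K+Na, CEC = SB+PA, base saturation
  V% = 100 SB/CEC, aluminium saturation m% = 100 Al/(SB+Al)
* qualitative flags (organic-matter rich, adequate P, high base saturation,
  crop suitability) using strict-inequality thresholds.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, asdict

import numpy as np
import pandas as pd

from .stoichiometry import ValidationError

__all__ = [
    "VAN_BEMMELEN",
    "ATOMIC_MASS",
    "SoilChemistryRecord",
    "om_to_toc",
    "mass_to_molar",
    "elemental_ratios",
    "fertility_indices",
    "classify_soil",
    "derive",
    "derive_frame",
    "read_chemistry_csv",
]

#: Conventional organic-matter to organic-carbon conversion divisor.
VAN_BEMMELEN = 1.724

#: Atomic masses (g mol-1) used for mass-to-molar conversions.
ATOMIC_MASS = {"C": 12.011, "N": 14.007, "P": 30.974}

MEASURED_COLUMNS = (
    "pH_water", "pH_KCl", "OM", "TN", "P", "Ca", "Mg", "K", "Na", "Al", "PA",
)


@dataclass(frozen=True)
class SoilChemistryRecord:
    """Measured chemistry for one (usually pooled) sample.

    Units: OM g kg-1; TN and P mg kg-1; cations and potential acidity (PA)
    mmolc kg-1; pH unitless.
    """

    group: str
    pH_water: float
    pH_KCl: float
    OM: float
    TN: float
    P: float
    Ca: float
    Mg: float
    K: float
    Na: float
    Al: float
    PA: float

    def __post_init__(self) -> None:
        for name in ("OM", "TN", "P", "Ca", "Mg", "K", "Na", "Al", "PA"):
            if getattr(self, name) < 0:
                raise ValidationError(f"negative value for {name}")


def om_to_toc(om: float) -> float:
    """Total organic carbon (g kg-1) from organic matter via OM/1.724."""
    if om < 0:
        raise ValidationError("negative OM")
    return om / VAN_BEMMELEN


def mass_to_molar(concentration: float, element: str) -> float:
    """Convert a soil concentration to umol per g of soil.

    Carbon is given in g kg-1 (equivalently mg g-1), nitrogen and
    phosphorus in mg kg-1 (ug g-1).
    """
    if element not in ATOMIC_MASS:
        raise ValueError(f"unknown element: {element!r}")
    mass = ATOMIC_MASS[element]
    if element == "C":
        return concentration * 1000.0 / mass  # mg g-1 -> ug g-1 -> umol g-1
    return concentration / mass  # ug g-1 / (g mol-1) = umol g-1 ... per kg->g

def elemental_ratios(TOC: float, TN: float, P: float) -> tuple[float, float, float]:
    """Molar ratios (CS/NS, CS/PS, NS/PS) from TOC (g kg-1), TN and P (mg kg-1).

    Zero denominators give NaN rather than raising.
    """
    cs = mass_to_molar(TOC, "C")
    ns = mass_to_molar(TN, "N")
    ps = mass_to_molar(P, "P")
    cs_ns = cs / ns if ns > 0 else math.nan
    cs_ps = cs / ps if ps > 0 else math.nan
    ns_ps = ns / ps if ps > 0 else math.nan
    return cs_ns, cs_ps, ns_ps


def fertility_indices(
    Ca: float, Mg: float, K: float, Na: float, Al: float, PA: float
) -> tuple[float, float, float, float]:
    """Sum of bases, cation exchange capacity, base and aluminium saturation.

    SB = Ca+Mg+K+Na; CEC = SB+PA; V% = 100 SB/CEC; m% = 100 Al/(SB+Al).
    V% is NaN when CEC is zero; m% is 0 when Al is 0.
    """
    sb = Ca + Mg + K + Na
    cec = sb + PA
    v = 100.0 * sb / cec if cec > 0 else math.nan
    m = 100.0 * Al / (sb + Al) if (sb + Al) > 0 else 0.0
    if Al == 0:
        m = 0.0
    return sb, cec, v, m


def classify_soil(derived: dict) -> dict[str, bool]:
    """Qualitative soil flags from measured + derived chemistry.

    Thresholds are strict inequalities: slightly acidic 6.5 < pH <= 7,
    OM-rich > 30 g kg-1, high TOC > 20 g kg-1, adequate P > 10 mg kg-1,
    high base saturation V% > 90; crop suitability requires adequate P and
    high V%.
    """
    flags = {
        "slightly_acidic": 6.5 < derived["pH_water"] <= 7.0,
        "OM_rich": derived["OM"] > 30.0,
        "TOC_high": derived["TOC"] > 20.0,
        "P_adequate": derived["P"] > 10.0,
        "V_high": derived["V_percent"] > 90.0,
    }
    flags["crop_suitable"] = flags["P_adequate"] and flags["V_high"]
    return flags


def derive(record: SoilChemistryRecord) -> dict:
    """All derived chemistry for one record, as a flat dict."""
    out = asdict(record)
    out["TOC"] = om_to_toc(record.OM)
    out["CS_NS"], out["CS_PS"], out["NS_PS"] = elemental_ratios(out["TOC"], record.TN, record.P)
    out["SB"], out["CEC"], out["V_percent"], out["m_percent"] = fertility_indices(
        record.Ca, record.Mg, record.K, record.Na, record.Al, record.PA
    )
    out["flags"] = classify_soil(out)
    return out


def derive_frame(chemistry: pd.DataFrame) -> pd.DataFrame:
    """Vectorised :func:`derive` over a measured-chemistry table.

    Derived columns are always recomputed from the measured ones; any
    derived columns present in the input are ignored.
    """
    missing = [c for c in ("group", *MEASURED_COLUMNS) if c not in chemistry.columns]
    if missing:
        raise ValidationError(f"missing chemistry column(s): {missing}")
    out = chemistry[["group", *MEASURED_COLUMNS]].copy()
    out["TOC"] = out["OM"] / VAN_BEMMELEN
    cs = out["TOC"] * 1000.0 / ATOMIC_MASS["C"]
    ns = out["TN"] / ATOMIC_MASS["N"]
    ps = out["P"] / ATOMIC_MASS["P"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["CS_NS"] = np.where(ns > 0, cs / ns, np.nan)
        out["CS_PS"] = np.where(ps > 0, cs / ps, np.nan)
        out["NS_PS"] = np.where(ns > 0, np.where(ps > 0, ns / ps, np.nan), np.nan)
    out["SB"] = out[["Ca", "Mg", "K", "Na"]].sum(axis=1)
    out["CEC"] = out["SB"] + out["PA"]
    with np.errstate(divide="ignore", invalid="ignore"):
        out["V_percent"] = np.where(out["CEC"] > 0, 100.0 * out["SB"] / out["CEC"], np.nan)
        denom = out["SB"] + out["Al"]
        out["m_percent"] = np.where(out["Al"] > 0, 100.0 * out["Al"] / denom, 0.0)
    return out


def read_chemistry_csv(path) -> pd.DataFrame:
    """Read a measured-chemistry CSV (one row per group or sample)."""
    frame = pd.read_csv(path)
    missing = [c for c in ("group", *MEASURED_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    return frame
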