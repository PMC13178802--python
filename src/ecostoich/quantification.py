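"""Microbial enumeration: four estimators of abundance per gram of sample.

* CFU — plate counts scaled by dilution, plated volume, suspension volume
  and sample mass.
* MPN — most probable number from a serial-dilution tube series, estimated
  by maximum likelihood under independent Poisson inoculation: each tube at
  inoculum v turns positive with probability 1 - exp(-lambda v).  The MLE
  solves the score equation by bracketed root finding; the confidence
  interval uses a log-normal approximation with the Fisher-information
  standard error of log10(MPN).
* TDE — cells inferred from a bulk DNA yield at an assumed per-cell DNA
  mass of 8.14 fg.
* EPI — epifluorescence microscopy counts over a mosaic of fields, scaled
  by filter/field area and the suspension/aliquot volumes, separately for
  viable (SYTO-9) and total (viable + propidium-iodide) cells.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.stats import norm

from .stoichiometry import ValidationError

__all__ = [
    "DNA_PER_CELL_FG",
    "PlateObservation",
    "MPNObservation",
    "DNAYieldObservation",
    "MicroscopyMosaic",
    "AbundanceResult",
    "MPNResult",
    "cfu_per_gram",
    "mpn_estimate",
    "tde_cells_per_gram",
    "epi_cells_per_gram",
    "method_comparison_table",
]

#: Assumed DNA content of a single bacterial cell (femtograms).
DNA_PER_CELL_FG = 8.14

#: Plates with more colonies than this are flagged as uncountable.
MAX_COUNTABLE = 300


@dataclass(frozen=True)
class PlateObservation:
    sample_id: str
    compartment: str  # soil | rhizosphere
    organism: str  # bacteria | fungi
    colony_count: int
    dilution_factor: float
    plated_volume: float  # mL
    suspension_volume: float  # mL
    sample_mass: float  # g

    def __post_init__(self) -> None:
        if self.colony_count < 0:
            raise ValidationError("negative colony count")
        if self.dilution_factor < 1:
            raise ValidationError("dilution_factor must be >= 1")
        if min(self.plated_volume, self.suspension_volume, self.sample_mass) <= 0:
            raise ValidationError("volumes and sample mass must be positive")


@dataclass(frozen=True)
class MPNObservation:
    """Serial-dilution tube outcomes.

    ``dilution_levels`` holds (inoculum amount of original sample per tube
    in g or mL, number of tubes, number of positive tubes), with inoculum
    amounts strictly decreasing.
    """

    sample_id: str
    dilution_levels: tuple[tuple[float, int, int], ...]
    compartment: str = "soil"

    def __post_init__(self) -> None:
        if not self.dilution_levels:
            raise ValidationError("at least one dilution level required")
        amounts = [v for v, _, _ in self.dilution_levels]
        if any(b >= a for a, b in zip(amounts, amounts[1:])):
            raise ValidationError("inoculum amounts must be strictly decreasing")
        for v, n, p in self.dilution_levels:
            if v <= 0 or n <= 0 or not 0 <= p <= n:
                raise ValidationError(f"invalid dilution level ({v}, {n}, {p})")


@dataclass(frozen=True)
class DNAYieldObservation:
    sample_id: str
    dna_mass: float  # ng extracted
    sample_mass: float  # g
    compartment: str = "soil"

    def __post_init__(self) -> None:
        if self.dna_mass < 0 or self.sample_mass <= 0:
            raise ValidationError("dna_mass must be >= 0 and sample_mass > 0")


@dataclass(frozen=True)
class MicroscopyMosaic:
    sample_id: str
    field_counts_live: tuple[int, ...]
    field_counts_dead: tuple[int, ...]
    field_area: float  # um^2
    filter_area: float  # um^2
    suspension_volume: float  # mL
    aliquot_volume: float  # mL
    sample_mass: float  # g
    compartment: str = "soil"
    expected_fields: int = 25

    def __post_init__(self) -> None:
        if not self.field_counts_live:
            raise ValidationError("at least one microscopy field required")
        if len(self.field_counts_live) != len(self.field_counts_dead):
            raise ValidationError("live/dead field lists differ in length")
        if any(c < 0 for c in self.field_counts_live + self.field_counts_dead):
            raise ValidationError("negative field counts")


@dataclass
class AbundanceResult:
    """One abundance estimate per sample x method (x organism)."""

    sample_id: str
    compartment: str
    method: str
    value: float
    organism: str = ""
    censored: bool = False
    flags: tuple[str, ...] = ()


@dataclass
class MPNResult(AbundanceResult):
    ci_lower: float = math.nan
    ci_upper: float = math.nan
    se_log10: float = math.nan


def cfu_per_gram(obs: PlateObservation, max_countable: int = MAX_COUNTABLE) -> AbundanceResult:
    """Colony-forming units per gram from a single plate."""
    value = (
        obs.colony_count * obs.dilution_factor / obs.plated_volume
        * obs.suspension_volume / obs.sample_mass
    )
    flags: list[str] = []
    censored = False
    if obs.colony_count == 0:
        censored = True
        flags.append("below_detection")
    if obs.colony_count > max_countable:
        flags.append("uncountable")
    return AbundanceResult(
        sample_id=obs.sample_id, compartment=obs.compartment, method="CFU",
        organism=obs.organism, value=value, censored=censored, flags=tuple(flags),
    )


def _mpn_score(lam: float, levels: Sequence[tuple[float, int, int]]) -> float:
    # d/dlambda of the log-likelihood sum_i [p_i log(1-e^{-lam v}) - (n_i-p_i) lam v]
    total = 0.0
    for v, n, p in levels:
        em = math.exp(-lam * v)
        if p > 0:
            total += p * v * em / (1.0 - em)
        total -= (n - p) * v
    return total


def _mpn_fisher_info(lam: float, levels: Sequence[tuple[float, int, int]]) -> float:
    total = 0.0
    for v, n, _ in levels:
        em = math.exp(-lam * v)
        if em < 1.0:
            total += n * v * v * em / (1.0 - em)
    return total


def mpn_estimate(obs: MPNObservation, confidence: float = 0.95) -> MPNResult:
    """Maximum-likelihood most probable number per g (or mL) of sample.

    All tubes negative gives a zero estimate with a one-sided upper bound;
    all tubes positive at every level has no finite MLE and raises.
    """
    levels = obs.dilution_levels
    total_pos = sum(p for _, _, p in levels)
    total_tubes = sum(n for _, n, _ in levels)
    if total_pos == 0:
        # one-sided bound: P(all negative | lambda) = exp(-lambda sum(n v))
        nv = sum(n * v for v, n, _ in levels)
        upper = -math.log(1.0 - confidence) / nv
        return MPNResult(
            sample_id=obs.sample_id, compartment=obs.compartment, method="MPN",
            value=0.0, censored=True, flags=("all_negative",),
            ci_lower=0.0, ci_upper=upper,
        )
    if total_pos == total_tubes:
        raise ValidationError("all tubes positive: only a lower bound exists")

    # Bracket the root of the score equation; score is decreasing in lambda.
    lo, hi = 1e-12 / levels[0][0], 1.0 / levels[-1][0]
    while _mpn_score(hi, levels) > 0:
        hi *= 10.0
        if hi > 1e18 / levels[0][0]:  # pragma: no cover - defensive
            raise RuntimeError("MPN root bracketing failed")
    lam = brentq(lambda l: _mpn_score(l, levels), lo, hi, xtol=1e-15, rtol=1e-12)

    info = _mpn_fisher_info(lam, levels)
    se_log10 = 1.0 / (lam * math.log(10.0) * math.sqrt(info)) if info > 0 else math.nan
    z = norm.ppf(0.5 + confidence / 2.0)
    lower = lam * 10 ** (-z * se_log10)
    upper = lam * 10 ** (z * se_log10)
    return MPNResult(
        sample_id=obs.sample_id, compartment=obs.compartment, method="MPN",
        value=lam, ci_lower=lower, ci_upper=upper, se_log10=se_log10,
    )


def tde_cells_per_gram(obs: DNAYieldObservation, fg_per_cell: float = DNA_PER_CELL_FG) -> AbundanceResult:
    """Cells per gram from a bulk DNA yield (ng) at ``fg_per_cell`` DNA each."""
    fg = obs.dna_mass * 1e6  # ng -> fg
    value = fg / fg_per_cell / obs.sample_mass
    return AbundanceResult(
        sample_id=obs.sample_id, compartment=obs.compartment, method="TDE",
        value=value, censored=obs.dna_mass == 0,
        flags=("below_detection",) if obs.dna_mass == 0 else (),
    )


def epi_cells_per_gram(obs: MicroscopyMosaic) -> tuple[AbundanceResult, AbundanceResult, float]:
    """Viable and total cells per gram from an epifluorescence mosaic.

    Returns (viable result, total result, viability fraction); the fraction
    is NaN when no cells were seen at all.
    """
    live = np.asarray(obs.field_counts_live, dtype=float)
    dead = np.asarray(obs.field_counts_dead, dtype=float)
    scale = (
        (obs.filter_area / obs.field_area)
        * (obs.suspension_volume / obs.aliquot_volume)
        / obs.sample_mass
    )
    viable = live.mean() * scale
    total = (live + dead).mean() * scale
    viability = viable / total if total > 0 else math.nan
    flags = ("single_field",) if live.size == 1 else ()
    mk = lambda value, organism: AbundanceResult(
        sample_id=obs.sample_id, compartment=obs.compartment, method="EPI",
        organism=organism, value=value, censored=value == 0,
        flags=flags + (("below_detection",) if value == 0 else ()),
    )
    return mk(viable, "viable"), mk(total, "total"), viability


def method_comparison_table(results: Iterable[AbundanceResult]) -> pd.DataFrame:
    """Long-format abundance table for the correlation stage.

    One row per result with log10-transformed values; censored
    (below-detection) entries keep a NaN log10 and are flagged so the
    correlation stage can exclude them.
    """
    rows = []
    for r in results:
        rows.append({
            "sample_id": r.sample_id,
            "compartment": r.compartment,
            "method": r.method,
            "organism": r.organism,
            "value": r.value,
            "log10_value": math.log10(r.value) if r.value > 0 else math.nan,
            "censored": r.censored,
        })
    return pd.DataFrame(rows, columns=[
        "sample_id", "compartment", "method", "organism", "value", "log10_value", "censored",
    ])
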