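"""Ecoenzymatic stoichiometry and enzyme vector analysis.

Extracellular enzyme activities (EEA) assayed on soil are pooled into the
three nutrient-acquisition classes

    CE = beta-glucosidase + cellulase + xylanase - dehydrogenase   (carbon)
    NE = urease + protease                                         (nitrogen)
    PE = acid phosphatase                                          (phosphorus)

i.e. carbon-supplying hydrolases minus the carbon-consuming dehydrogenase.
The relative carbon investment of the community is summarised as a point

    x = CE / (CE + PE),   y = CE / (CE + NE)

in the unit square; the polar form of that point gives the vector length
(strength of carbon limitation) and vector angle (>45 deg: phosphorus
limitation, <45 deg: nitrogen limitation).

A negative CE (dehydrogenase exceeding the supply enzymes) is retained as a
value but the vector and the ratios built from it are reported as undefined
rather than clamped to zero.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, fields as dc_fields
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd

__all__ = [
    "ENZYME_COLUMNS",
    "EnzymeActivityRecord",
    "EcoenzymeSummary",
    "GroupSummary",
    "ValidationError",
    "aggregate_eea",
    "stoichiometric_ratios",
    "vector_components",
    "vector_length_angle",
    "classify_limitation",
    "alk_acid_phosphatase_index",
    "summarize_record",
    "summaries_frame",
    "summarize_group",
    "read_enzyme_csv",
]

#: The nine assayed ecoenzymes, in canonical column order.
ENZYME_COLUMNS = (
    "beta_glucosidase",
    "cellulase",
    "xylanase",
    "dehydrogenase",
    "urease",
    "protease",
    "acid_phosphatase",
    "alkaline_phosphatase",
    "arylsulphatase",
)

#: Default vector-angle threshold (degrees) separating N from P limitation.
ANGLE_THRESHOLD = 45.0
#: Default vector-length cutoff below which a limitation is called "weak".
LENGTH_LOW_CUTOFF = 0.5
#: Alkaline/acid phosphatase ratio above which no liming is indicated.
ALK_ACD_LIMING_THRESHOLD = 0.5


class ValidationError(ValueError):
    """Raised when an input record violates the schema or an invariant."""


@dataclass(frozen=True)
class EnzymeActivityRecord:
    """Per-sample activities of the nine assayed ecoenzymes.

    Units: beta_glucosidase, acid/alkaline phosphatase and arylsulphatase in
    umol p-nitrophenol g soil-1 h-1; cellulase and xylanase in umol glucose
    g-1 h-1; dehydrogenase in umol TTF g-1 h-1; protease in umol L-tyrosine
    g-1 h-1; urease in umol NH4+ g-1 h-1.
    """

    sample_id: str
    group: str
    beta_glucosidase: float
    cellulase: float
    xylanase: float
    dehydrogenase: float
    urease: float
    protease: float
    acid_phosphatase: float
    alkaline_phosphatase: float
    arylsulphatase: float
    compartment: str = "soil"

    def __post_init__(self) -> None:
        for name in ENZYME_COLUMNS:
            value = getattr(self, name)
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise ValidationError(f"missing activity field: {name}")
            if value < 0:
                raise ValidationError(f"negative activity for {name}: {value}")


@dataclass
class EcoenzymeSummary:
    """Pooled activities, stoichiometric ratios and enzymatic vector.

    Undefined quantities (e.g. the vector when CE <= 0, or a ratio with a
    zero denominator) are NaN, with ``limitation_call`` set accordingly.
    """

    CE: float
    NE: float
    PE: float
    ratio_CE_PE: float = math.nan
    ratio_CE_NE: float = math.nan
    ratio_NE_PE: float = math.nan
    x_component: float = math.nan
    y_component: float = math.nan
    vector_length: float = math.nan
    vector_angle: float = math.nan
    limitation_call: Literal["P_limited", "N_limited", "balanced", "undefined"] = "undefined"
    limitation_strength: Literal["weak", "strong", "undefined"] = "undefined"
    alk_acid_ratio: float = math.nan
    liming_flag: str = ""
    sample_id: str = ""
    group: str = ""


@dataclass
class GroupSummary:
    """Group-level ecoenzyme summary with replicate dispersion.

    ``mode`` records whether the summary was computed from group-mean
    activities (``of_means``) or as the mean of per-replicate summaries
    (``per_replicate``) — the two differ for any nonlinear quantity
    (ratios, vector length/angle) whenever replicates vary.
    """

    group: str
    n: int
    mode: str
    mean: EcoenzymeSummary
    sd: dict[str, float] = field(default_factory=dict)


def aggregate_eea(record: EnzymeActivityRecord) -> EcoenzymeSummary:
    """Build the CE/NE/PE pools from a single activity record.

    CE may be negative when dehydrogenase (carbon consumption) exceeds the
    carbon-supplying activities; it is kept as-is and the downstream vector
    is then undefined.
    """
    ce = record.beta_glucosidase + record.cellulase + record.xylanase - record.dehydrogenase
    ne = record.urease + record.protease
    pe = record.acid_phosphatase
    return EcoenzymeSummary(CE=ce, NE=ne, PE=pe, sample_id=record.sample_id, group=record.group)


def stoichiometric_ratios(CE: float, NE: float, PE: float) -> tuple[float, float, float]:
    """Return (CE/PE, CE/NE, NE/PE); zero denominators yield NaN, not errors."""
    ce_pe = CE / PE if PE > 0 else math.nan
    ce_ne = CE / NE if NE > 0 else math.nan
    ne_pe = NE / PE if PE > 0 else math.nan
    return ce_pe, ce_ne, ne_pe


def vector_components(CE: float, NE: float, PE: float) -> tuple[float, float]:
    """Relative carbon investment: x = CE/(CE+PE), y = CE/(CE+NE).

    Undefined (NaN, NaN) when CE <= 0.
    """
    if CE <= 0:
        return math.nan, math.nan
    return CE / (CE + PE), CE / (CE + NE)


def vector_length_angle(x: float, y: float) -> tuple[float, float]:
    """Polar form of the investment point: length sqrt(x^2+y^2), angle
    degrees(arctan2(y, x)) measured from the x-axis.

    (0, 0) has no direction; both quantities are then NaN.
    """
    if math.isnan(x) or math.isnan(y) or (x == 0 and y == 0):
        return math.nan, math.nan
    return math.hypot(x, y), math.degrees(math.atan2(y, x))


def classify_limitation(
    vector_length: float,
    vector_angle: float,
    angle_threshold: float = ANGLE_THRESHOLD,
    length_low_cutoff: float = LENGTH_LOW_CUTOFF,
) -> tuple[str, str]:
    """Nutrient-limitation call from the enzymatic vector.

    Angle above the threshold indicates phosphorus limitation, below it
    nitrogen limitation, exactly at it balanced 1:1:1 stoichiometry.  The
    strength qualifier compares the vector length against
    ``length_low_cutoff`` (short vectors: weak limitation).
    """
    if math.isnan(vector_angle) or math.isnan(vector_length):
        return "undefined", "undefined"
    if vector_angle > angle_threshold:
        call = "P_limited"
    elif vector_angle < angle_threshold:
        call = "N_limited"
    else:
        call = "balanced"
    strength = "weak" if vector_length < length_low_cutoff else "strong"
    return call, strength


def alk_acid_phosphatase_index(alkaline: float, acid: float) -> tuple[float, str]:
    """Alkaline/acid phosphatase ratio and the liming indication.

    Ratios above 0.5 indicate no need for soil pH correction.
    """
    if acid <= 0:
        return math.nan, "undefined"
    ratio = alkaline / acid
    flag = "no correction needed" if ratio > ALK_ACD_LIMING_THRESHOLD else "liming indicated"
    return ratio, flag


def summarize_record(
    record: EnzymeActivityRecord,
    angle_threshold: float = ANGLE_THRESHOLD,
    length_low_cutoff: float = LENGTH_LOW_CUTOFF,
) -> EcoenzymeSummary:
    """Full ecoenzyme summary for one sample: pools, ratios, vector, calls."""
    s = aggregate_eea(record)
    s.ratio_CE_PE, s.ratio_CE_NE, s.ratio_NE_PE = stoichiometric_ratios(s.CE, s.NE, s.PE)
    s.x_component, s.y_component = vector_components(s.CE, s.NE, s.PE)
    s.vector_length, s.vector_angle = vector_length_angle(s.x_component, s.y_component)
    s.limitation_call, s.limitation_strength = classify_limitation(
        s.vector_length, s.vector_angle, angle_threshold, length_low_cutoff
    )
    s.alk_acid_ratio, s.liming_flag = alk_acid_phosphatase_index(
        record.alkaline_phosphatase, record.acid_phosphatase
    )
    return s


_SUMMARY_COLUMNS = (
    "CE", "NE", "PE", "ratio_CE_PE", "ratio_CE_NE", "ratio_NE_PE",
    "x_component", "y_component", "vector_length", "vector_angle", "alk_acid_ratio",
)


def summaries_frame(activities: pd.DataFrame, **kwargs) -> pd.DataFrame:
    """Vectorised per-sample summaries from a tidy activity table.

    ``activities`` needs ``sample_id``, ``group`` and the nine enzyme
    columns; returns one row per sample with pools, ratios, vector and
    limitation calls.
    """
    missing = [c for c in ("sample_id", "group", *ENZYME_COLUMNS) if c not in activities.columns]
    if missing:
        raise ValidationError(f"missing activity field: {missing[0]}")
    if activities[list(ENZYME_COLUMNS)].isna().any().any():
        raise ValidationError("missing activity values in table")
    if (activities[list(ENZYME_COLUMNS)] < 0).any().any():
        raise ValidationError("negative activity values in table")

    ce = (
        activities["beta_glucosidase"] + activities["cellulase"]
        + activities["xylanase"] - activities["dehydrogenase"]
    )
    ne = activities["urease"] + activities["protease"]
    pe = activities["acid_phosphatase"]
    out = pd.DataFrame({"sample_id": activities["sample_id"], "group": activities["group"]})
    out["CE"], out["NE"], out["PE"] = ce, ne, pe
    with np.errstate(divide="ignore", invalid="ignore"):
        out["ratio_CE_PE"] = np.where(pe > 0, ce / pe, np.nan)
        out["ratio_CE_NE"] = np.where(ne > 0, ce / ne, np.nan)
        out["ratio_NE_PE"] = np.where(pe > 0, ne / pe, np.nan)
        defined = ce > 0
        x = np.where(defined, ce / (ce + pe), np.nan)
        y = np.where(defined, ce / (ce + ne), np.nan)
    out["x_component"], out["y_component"] = x, y
    out["vector_length"] = np.hypot(x, y)
    out["vector_angle"] = np.degrees(np.arctan2(y, x))
    angle_threshold = kwargs.get("angle_threshold", ANGLE_THRESHOLD)
    length_low = kwargs.get("length_low_cutoff", LENGTH_LOW_CUTOFF)
    call = np.select(
        [np.isnan(out["vector_angle"]), out["vector_angle"] > angle_threshold,
         out["vector_angle"] < angle_threshold],
        ["undefined", "P_limited", "N_limited"],
        default="balanced",
    )
    out["limitation_call"] = call
    out["limitation_strength"] = np.select(
        [np.isnan(out["vector_length"]), out["vector_length"] < length_low],
        ["undefined", "weak"], default="strong",
    )
    with np.errstate(divide="ignore", invalid="ignore"):
        out["alk_acid_ratio"] = np.where(
            activities["acid_phosphatase"] > 0,
            activities["alkaline_phosphatase"] / activities["acid_phosphatase"],
            np.nan,
        )
    return out


def summarize_group(
    records: Sequence[EnzymeActivityRecord] | pd.DataFrame,
    mode: Literal["of_means", "per_replicate"] = "per_replicate",
    **kwargs,
) -> list[GroupSummary]:
    """Group-level summaries under either aggregation order.

    ``of_means`` first averages the nine activities within a group and then
    derives pools/ratios/vector from the mean activities; ``per_replicate``
    derives everything per sample and then averages.  The two agree exactly
    when replicates are identical and differ in general (Jensen gap) for
    ratios and the vector.
    """
    if mode not in ("of_means", "per_replicate"):
        raise ValueError(f"unknown aggregation mode: {mode}")
    if isinstance(records, pd.DataFrame):
        frame = records
    else:
        frame = pd.DataFrame([vars(r) for r in records])
    if frame.empty:
        raise ValidationError("empty group")

    results: list[GroupSummary] = []
    for group, sub in frame.groupby("group", sort=False):
        if mode == "of_means":
            means = sub[list(ENZYME_COLUMNS)].mean()
            rec = EnzymeActivityRecord(sample_id=f"{group}::mean", group=str(group), **means)
            summary = summarize_record(rec, **kwargs)
            sds = sub[list(ENZYME_COLUMNS)].std(ddof=1).to_dict()
        else:
            per = summaries_frame(sub, **kwargs)
            summary = EcoenzymeSummary(
                CE=per["CE"].mean(), NE=per["NE"].mean(), PE=per["PE"].mean(),
                sample_id=f"{group}::mean", group=str(group),
            )
            for col in _SUMMARY_COLUMNS[3:]:
                setattr(summary, col, per[col].mean())
            summary.limitation_call, summary.limitation_strength = classify_limitation(
                summary.vector_length, summary.vector_angle,
                kwargs.get("angle_threshold", ANGLE_THRESHOLD),
                kwargs.get("length_low_cutoff", LENGTH_LOW_CUTOFF),
            )
            _, summary.liming_flag = alk_acid_phosphatase_index(summary.alk_acid_ratio, 1.0)
            sds = per[list(_SUMMARY_COLUMNS)].std(ddof=1).to_dict()
        results.append(GroupSummary(group=str(group), n=len(sub), mode=mode, mean=summary, sd=sds))
    return results


def read_enzyme_csv(path) -> pd.DataFrame:
    """Read a per-sample enzyme activity CSV and validate its schema."""
    frame = pd.read_csv(path)
    missing = [c for c in ("sample_id", "group", *ENZYME_COLUMNS) if c not in frame.columns]
    if missing:
        raise ValidationError(f"{path}: missing column(s) {missing}")
    if frame["sample_id"].duplicated().any():
        dup = frame.loc[frame["sample_id"].duplicated(), "sample_id"].iloc[0]
        raise ValidationError(f"{path}: duplicated sample_id {dup!r}")
    return frame
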