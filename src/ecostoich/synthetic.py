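"""Seeded synthetic datasets with the study's 3 species x 5 replicate layout.

The generator emulates a field study of three fibre agave plantings
(*A. sisalana* and the hybrids H11648 and H400f) sampled with five
biological replicates per species in two compartments (bulk soil and
rhizosphere).  Default group means are the published per-species values:
nine enzyme activities, the bulk-soil chemistry panel, microbial biomass
C/N, basal respiration, and enumeration magnitudes of 1e7 cells g-1 for
culturable and 1e9 cells g-1 for total organisms.  Raw assay observations
(plate counts, dilution tubes, DNA yields, microscopy fields, fumigation
and titration readings) are back-calculated from per-replicate target
quantities so that the analysis pipeline run forward recovers them.

Replicate dispersion is not published, so the coefficients of variation are
package assumptions: 0.40 for enzyme activities and 0.25 for basal
respiration (no significant species differences were reported for those),
0.10 for chemistry and biomass (clearly separated between species), and
lognormal noise with CV 0.30 for enumeration targets.  With CV = 0 every
replicate equals its group mean exactly, which makes the deterministic
worked-example checks possible.
"""

from __future__ import annotations

import copy
import math
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .quantification import DNA_PER_CELL_FG
from .stoichiometry import ENZYME_COLUMNS, ValidationError

__all__ = [
    "DesignSpec",
    "DatasetBundle",
    "default_design",
    "generate",
    "null_dataset",
    "toc_effect_scenario",
    "design_from_dict",
]

GROUPS = ("A. sisalana", "H11648", "H400f")

# Published per-species mean enzyme activities; the H11648 dehydrogenase
# entry is 2.44e-3, the value consistent with the published carbon pool
# (CE = 1.334) and the across-species dehydrogenase mean (3.95e-3).
ENZYME_MEANS = {
    "A. sisalana": {
        "beta_glucosidase": 0.358, "cellulase": 0.146, "xylanase": 0.391,
        "dehydrogenase": 2.35e-3, "urease": 10.775, "protease": 0.217,
        "acid_phosphatase": 27.415, "alkaline_phosphatase": 40.645,
        "arylsulphatase": 1.764,
    },
    "H11648": {
        "beta_glucosidase": 0.491, "cellulase": 0.172, "xylanase": 0.673,
        "dehydrogenase": 2.44e-3, "urease": 8.417, "protease": 0.673,
        "acid_phosphatase": 39.865, "alkaline_phosphatase": 41.570,
        "arylsulphatase": 1.936,
    },
    "H400f": {
        "beta_glucosidase": 0.550, "cellulase": 0.086, "xylanase": 0.428,
        "dehydrogenase": 7.06e-3, "urease": 7.191, "protease": 0.237,
        "acid_phosphatase": 29.308, "alkaline_phosphatase": 44.405,
        "arylsulphatase": 2.354,
    },
}

# Published bulk-soil chemistry (single pooled analysis per species).
CHEMISTRY_MEANS = {
    "A. sisalana": {"pH_water": 6.67, "pH_KCl": 5.36, "OM": 37.5, "TN": 2905.0,
                    "P": 12.2, "Ca": 269.5, "Mg": 142.1, "K": 3.4, "Na": 6.3,
                    "Al": 0.0, "PA": 34.8},
    "H11648": {"pH_water": 6.71, "pH_KCl": 5.6, "OM": 56.6, "TN": 3290.0,
               "P": 44.0, "Ca": 292.1, "Mg": 110.3, "K": 3.8, "Na": 4.1,
               "Al": 0.0, "PA": 41.2},
    "H400f": {"pH_water": 6.9, "pH_KCl": 5.84, "OM": 54.4, "TN": 1918.0,
              "P": 32.5, "Ca": 279.1, "Mg": 118.5, "K": 5.2, "Na": 4.3,
              "Al": 0.0, "PA": 12.8},
}

# MBC / MBN in umol g-1 (published); MR in umol CO2 g-1 day-1,
# back-computed from the published per-species metabolic quotients and MBC
# (only the across-species mean respiration, 1.61, is published; the
# back-computed values average 1.63).
MICROBIAL_MEANS = {
    "A. sisalana": {"MBC": 37.31, "MBN": 0.60, "MR": 1.390},
    "H11648": {"MBC": 28.0, "MBN": 0.27, "MR": 1.876},
    "H400f": {"MBC": 8.46, "MBN": 0.25, "MR": 1.620},
}

# Enumeration targets (cells or cfu per g). TDE separates compartments by
# one order of magnitude; the other methods do not, and H400f soil carries
# a lower culturable bacterial count, as reported.
QUANT_MEANS = {
    "cfu_bacteria": {
        "soil": {"A. sisalana": 1e7, "H11648": 1e7, "H400f": 2e6},
        "rhizosphere": {g: 1e7 for g in GROUPS},
    },
    "cfu_fungi": {c: {g: 1e5 for g in GROUPS} for c in ("soil", "rhizosphere")},
    "mpn": {c: {g: 1e7 for g in GROUPS} for c in ("soil", "rhizosphere")},
    "tde_total": {
        "soil": {g: 1e9 for g in GROUPS},
        "rhizosphere": {g: 1e8 for g in GROUPS},
    },
    "epi_viable": {c: {g: 8e8 for g in GROUPS} for c in ("soil", "rhizosphere")},
}

DEFAULT_CV = {
    "enzymes": 0.40,
    "chemistry": 0.10,
    "microbial": 0.10,
    "MR": 0.25,
    "quantification": 0.30,
}

# Fixed assay geometry used when inverting targets to raw readings.
ASSAY = {
    "kEC": 0.45, "kEN": 0.54,
    "C_unfumigated": 150.0, "N_unfumigated": 20.0,  # ug g-1 extract baselines
    "resp_soil_mass": 10.0, "resp_molarity": 0.1,
    "resp_blank": 10.0, "resp_hours": 24.0,
    "plate_mass": 1.0, "plate_suspension": 10.0, "plate_volume": 0.1,
    "plate_dilution_bacteria": 1e3, "plate_dilution_fungi": 10.0,
    "mpn_inocula": (1e-6, 1e-7, 1e-8), "mpn_tubes": 5,
    "tde_mass": 0.25,
    "epi_field_area": 1e4, "epi_filter_area": 1e8,
    "epi_suspension": 10.0, "epi_aliquot": 0.01, "epi_mass": 1.0,
    "epi_fields": 25, "epi_dead_fraction": 0.2,
}


@dataclass
class DesignSpec:
    """Full parameterisation of a synthetic study."""

    groups: tuple[str, ...] = GROUPS
    replicates: int = 5
    enzyme_means: dict = field(default_factory=lambda: copy.deepcopy(ENZYME_MEANS))
    chemistry_means: dict = field(default_factory=lambda: copy.deepcopy(CHEMISTRY_MEANS))
    microbial_means: dict = field(default_factory=lambda: copy.deepcopy(MICROBIAL_MEANS))
    quant_means: dict = field(default_factory=lambda: copy.deepcopy(QUANT_MEANS))
    cv: dict = field(default_factory=lambda: dict(DEFAULT_CV))
    assay: dict = field(default_factory=lambda: dict(ASSAY))
    species_effect: bool = True

    def validate(self) -> None:
        if self.replicates < 2:
            raise ValidationError("replicates must be >= 2")
        if any(v < 0 for v in self.cv.values()):
            raise ValidationError("coefficients of variation must be >= 0")
        for g in self.groups:
            for source in (self.enzyme_means, self.chemistry_means, self.microbial_means):
                if g not in source:
                    raise ValidationError(f"no means configured for group {g!r}")
                if any(v < 0 for v in source[g].values()):
                    raise ValidationError(f"negative mean configured for group {g!r}")

    def with_cv(self, value: float) -> "DesignSpec":
        """Copy of the spec with every coefficient of variation set to ``value``."""
        out = copy.deepcopy(self)
        out.cv = {k: value for k in out.cv}
        return out

    def pooled(self) -> "DesignSpec":
        """Null design: all groups share the across-group mean of every variable."""
        out = copy.deepcopy(self)
        out.species_effect = False
        for source in (out.enzyme_means, out.chemistry_means, out.microbial_means):
            keys = source[self.groups[0]].keys()
            pooled = {k: float(np.mean([source[g][k] for g in self.groups])) for k in keys}
            for g in self.groups:
                source[g] = dict(pooled)
        for metric in out.quant_means:
            for comp in out.quant_means[metric]:
                pooled_v = float(np.mean([out.quant_means[metric][comp][g] for g in self.groups]))
                out.quant_means[metric][comp] = {g: pooled_v for g in self.groups}
        return out


@dataclass
class DatasetBundle:
    """The generated tables, one per assay type."""

    enzymes: pd.DataFrame
    chemistry: pd.DataFrame
    biomass: pd.DataFrame
    respiration: pd.DataFrame
    plates: pd.DataFrame
    mpn_tubes: pd.DataFrame
    dna: pd.DataFrame
    microscopy: pd.DataFrame

    _FILES = ("enzymes", "chemistry", "biomass", "respiration",
              "plates", "mpn_tubes", "dna", "microscopy")

    def to_dir(self, outdir) -> None:
        outdir = Path(outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name in self._FILES:
            getattr(self, name).to_csv(outdir / f"{name}.csv", index=False)

    @classmethod
    def from_dir(cls, indir) -> "DatasetBundle":
        indir = Path(indir)
        return cls(**{name: pd.read_csv(indir / f"{name}.csv") for name in cls._FILES})


def default_design() -> DesignSpec:
    """The packaged study design (published group means, assumed CVs)."""
    spec = DesignSpec()
    spec.validate()
    return spec


def _sample_id(group: str, rep: int) -> str:
    return f"{group.replace(' ', '').replace('.', '')}-r{rep + 1}"


def _truncnorm_draw(rng, mean: float, cv: float, size=None):
    """Normal truncated at zero; degenerate at the mean when cv or mean is 0."""
    if cv == 0 or mean == 0:
        return np.full(size, float(mean)) if size else float(mean)
    sd = cv * mean
    a = (0.0 - mean) / sd
    return truncnorm.rvs(a, np.inf, loc=mean, scale=sd, size=size, random_state=rng)


def _lognormal_draw(rng, mean: float, cv: float, size=None):
    """Lognormal with the requested arithmetic mean and CV."""
    if cv == 0 or mean == 0:
        return np.full(size, float(mean)) if size else float(mean)
    sigma2 = math.log(1.0 + cv * cv)
    mu = math.log(mean) - sigma2 / 2.0
    return rng.lognormal(mu, math.sqrt(sigma2), size=size)


def generate(spec: DesignSpec, seed: int) -> DatasetBundle:
    """Draw one seeded dataset bundle from a design.

    Chemistry is a single pooled analysis per species (one row per group);
    under ``species_effect=False`` a single pooled analysis is shared by
    all groups so that samples remain exchangeable across labels.
    """
    spec.validate()
    rng = np.random.default_rng(seed)
    a = spec.assay
    stochastic = any(v > 0 for v in spec.cv.values())
    n = spec.replicates

    enz_parts, bio_parts, resp_parts = [], [], []
    plate_parts, tube_parts, dna_parts, micro_parts = [], [], [], []
    for group in spec.groups:
        sids = [_sample_id(group, rep) for rep in range(n)]
        enz = {"sample_id": sids, "group": group, "compartment": "soil"}
        for enzyme in ENZYME_COLUMNS:
            enz[enzyme] = _truncnorm_draw(rng, spec.enzyme_means[group][enzyme],
                                          spec.cv["enzymes"], size=n)
        enz_parts.append(pd.DataFrame(enz))

        mbc = _truncnorm_draw(rng, spec.microbial_means[group]["MBC"], spec.cv["microbial"], size=n)
        mbn = _truncnorm_draw(rng, spec.microbial_means[group]["MBN"], spec.cv["microbial"], size=n)
        mr = _truncnorm_draw(rng, spec.microbial_means[group]["MR"], spec.cv["MR"], size=n)
        bio_parts.append(pd.DataFrame({
            "sample_id": sids, "group": group,
            "C_fumigated": a["C_unfumigated"] + mbc * 12.011 * a["kEC"],
            "C_unfumigated": a["C_unfumigated"],
            "N_fumigated": a["N_unfumigated"] + mbn * 14.007 * a["kEN"],
            "N_unfumigated": a["N_unfumigated"],
            "kEC": a["kEC"], "kEN": a["kEN"],
        }))
        # MR umol g-1 day-1 -> titre drop: 2 NaOH per CO2
        trapped = mr * a["resp_soil_mass"] * a["resp_hours"] / 24.0
        titre_drop = trapped * 2.0 / (a["resp_molarity"] * 1000.0)
        resp_parts.append(pd.DataFrame({
            "sample_id": sids, "group": group,
            "blank_titre": a["resp_blank"], "sample_titre": a["resp_blank"] - titre_drop,
            "acid_molarity": a["resp_molarity"], "soil_mass": a["resp_soil_mass"],
            "incubation_time": a["resp_hours"],
        }))

        cvq = spec.cv["quantification"]
        for comp in ("soil", "rhizosphere"):
            for organism, metric, dilution in (
                ("bacteria", "cfu_bacteria", a["plate_dilution_bacteria"]),
                ("fungi", "cfu_fungi", a["plate_dilution_fungi"]),
            ):
                abund = _lognormal_draw(rng, spec.quant_means[metric][comp][group], cvq, size=n)
                count = abund * a["plate_mass"] * a["plate_volume"] / (
                    dilution * a["plate_suspension"])
                plate_parts.append(pd.DataFrame({
                    "sample_id": sids, "group": group, "compartment": comp,
                    "organism": organism, "colony_count": np.rint(count).astype(int),
                    "dilution_factor": dilution, "plated_volume": a["plate_volume"],
                    "suspension_volume": a["plate_suspension"], "sample_mass": a["plate_mass"],
                }))

            lam = _lognormal_draw(rng, spec.quant_means["mpn"][comp][group], cvq, size=n)
            for inoc in a["mpn_inocula"]:
                p_pos = 1.0 - np.exp(-lam * inoc)
                if stochastic:
                    positives = rng.binomial(a["mpn_tubes"], p_pos)
                else:
                    positives = np.rint(a["mpn_tubes"] * p_pos).astype(int)
                tube_parts.append(pd.DataFrame({
                    "sample_id": sids, "group": group, "compartment": comp,
                    "inoculum": inoc, "tubes": a["mpn_tubes"], "positives": positives,
                }))

            total = _lognormal_draw(rng, spec.quant_means["tde_total"][comp][group], cvq, size=n)
            dna_parts.append(pd.DataFrame({
                "sample_id": sids, "group": group, "compartment": comp,
                "dna_mass": total * a["tde_mass"] * DNA_PER_CELL_FG * 1e-6,  # ng
                "sample_mass": a["tde_mass"],
            }))

            viable = _lognormal_draw(rng, spec.quant_means["epi_viable"][comp][group], cvq, size=n)
            scale = (a["epi_filter_area"] / a["epi_field_area"]) * (
                a["epi_suspension"] / a["epi_aliquot"]) / a["epi_mass"]
            live_mean = viable / scale
            dead_mean = live_mean * a["epi_dead_fraction"] / (1.0 - a["epi_dead_fraction"])
            nf = a["epi_fields"]
            if stochastic:
                live = rng.poisson(np.repeat(live_mean, nf))
                dead = rng.poisson(np.repeat(dead_mean, nf))
            else:
                live = np.repeat(np.rint(live_mean).astype(int), nf)
                dead = np.repeat(np.rint(dead_mean).astype(int), nf)
            micro_parts.append(pd.DataFrame({
                "sample_id": np.repeat(sids, nf), "group": group, "compartment": comp,
                "field": np.tile(np.arange(1, nf + 1), n),
                "count_live": live, "count_dead": dead,
                "field_area": a["epi_field_area"], "filter_area": a["epi_filter_area"],
                "suspension_volume": a["epi_suspension"], "aliquot_volume": a["epi_aliquot"],
                "sample_mass": a["epi_mass"],
            }))

    chem_rows = []
    if spec.species_effect:
        for group in spec.groups:
            row = {"group": group}
            for name, mean in spec.chemistry_means[group].items():
                row[name] = _truncnorm_draw(rng, mean, spec.cv["chemistry"])
            chem_rows.append(row)
    else:
        shared = {
            name: _truncnorm_draw(rng, mean, spec.cv["chemistry"])
            for name, mean in spec.chemistry_means[spec.groups[0]].items()
        }
        for group in spec.groups:
            chem_rows.append({"group": group, **shared})

    cat = lambda parts: pd.concat(parts, ignore_index=True)
    return DatasetBundle(
        enzymes=cat(enz_parts),
        chemistry=pd.DataFrame(chem_rows),
        biomass=cat(bio_parts),
        respiration=cat(resp_parts),
        plates=cat(plate_parts),
        mpn_tubes=cat(tube_parts),
        dna=cat(dna_parts),
        microscopy=cat(micro_parts),
    )


def null_dataset(spec: DesignSpec, seed: int) -> DatasetBundle:
    """Dataset with species effects removed (identical group distributions)."""
    return generate(spec.pooled(), seed)


def toc_effect_scenario(
    seed: int,
    n_per_group: int = 5,
    n_responses: int = 10,
    effect_size: float = 1.0,
):
    """Response matrix driven by a TOC gradient, plus a pure-noise predictor.

    Builds ``3 * n_per_group`` samples whose TOC follows the three
    published group values with small noise; each response variable is
    ``effect_size * weight * TOC_z + N(0, 1)`` noise.  The returned env
    table has the structured ``TOC`` column and an independent ``TN``
    column carrying no signal, for use in permutation-inference checks.
    """
    rng = np.random.default_rng(seed)
    toc_means = np.repeat([21.75, 32.83, 31.55], n_per_group)
    toc = toc_means + rng.normal(0.0, 0.5, toc_means.size)
    toc_z = (toc - toc.mean()) / toc.std(ddof=1)
    weights = rng.uniform(0.5, 1.0, n_responses) * rng.choice([-1, 1], n_responses)
    Y = effect_size * np.outer(toc_z, weights) + rng.normal(0.0, 1.0, (toc.size, n_responses))
    env = pd.DataFrame({"TOC": toc, "TN": rng.normal(0.0, 1.0, toc.size)})
    resp = pd.DataFrame(Y, columns=[f"resp{i + 1}" for i in range(n_responses)])
    return resp, env


def design_from_dict(overrides: dict) -> DesignSpec:
    """Default design with (possibly nested) overrides applied.

    Top-level keys mirror :class:`DesignSpec` fields; dict-valued fields
    are deep-merged so a YAML file can override a single mean.
    """
    spec = default_design()
    for key, value in overrides.items():
        if not hasattr(spec, key):
            raise ValidationError(f"unknown design field: {key}")
        current = getattr(spec, key)
        if isinstance(current, dict) and isinstance(value, dict):
            merged = copy.deepcopy(current)
            _deep_update(merged, value)
            setattr(spec, key, merged)
        elif key == "groups":
            setattr(spec, key, tuple(value))
        else:
            setattr(spec, key, value)
    spec.validate()
    return spec


def _deep_update(base: dict, update: dict) -> None:
    for k, v in update.items():
        if isinstance(v, dict) and isinstance(base.get(k), dict):
            _deep_update(base[k], v)
        else:
            base[k] = v
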