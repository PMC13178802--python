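"""End-to-end orchestration: generate/ingest -> derive -> integrate -> report.

The pipeline consumes a dataset bundle (from the synthetic generator or a
directory of CSVs), runs every analysis stage that its inputs allow, and
writes derived CSVs plus a machine-readable JSON report.  Stages whose
inputs are missing are skipped and recorded, not fatal.  All randomness
(permutation tests, k-means restarts) flows from the single config seed
via independent child streams.
"""

from __future__ import annotations

import hashlib
import json
import math
from dataclasses import dataclass, field, asdict
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd
from pydantic import BaseModel

from . import multivariate as mv
from . import quantification as quant
from .microbial_params import params_frame
from .soil_chemistry import classify_soil, derive_frame
from .stoichiometry import ValidationError, ENZYME_COLUMNS, summaries_frame, summarize_group
from .synthetic import DatasetBundle, DesignSpec, default_design, generate

__all__ = ["PipelineConfig", "PipelineReport", "run", "validate_inputs", "quantification_results"]


@dataclass
class PipelineConfig:
    """Knobs of a pipeline run; defaults follow the study's choices."""

    input_dir: str | None = None  # read bundle CSVs from here when set
    design: DesignSpec | None = None  # otherwise generate from this design
    outdir: str | None = None
    seed: int = 0
    mode: str = "per_replicate"  # group aggregation order
    angle_threshold: float = 45.0
    vif_threshold: float = 2.0
    alpha: float = 0.05
    k_clusters: int = 3
    permutations: int = 999
    env_candidates: tuple[str, ...] = ("TOC", "TN")

    def __post_init__(self) -> None:
        if self.permutations < 99:
            raise ValidationError("permutations must be >= 99")
        if self.mode not in ("per_replicate", "of_means"):
            raise ValidationError(f"unknown aggregation mode: {self.mode}")


class PipelineReport(BaseModel):
    """Schema of the JSON report (shipped as docs/report.schema.json)."""

    config: dict
    config_hash: str
    seed: int
    versions: dict
    skipped: dict[str, str]
    stoichiometry: dict | None = None
    chemistry: dict | None = None
    quantification: dict | None = None
    microbial: dict | None = None
    multivariate: dict | None = None


def _jsonable(obj: Any) -> Any:
    if isinstance(obj, dict):
        return {str(k): _jsonable(v) for k, v in obj.items()}
    if isinstance(obj, (list, tuple, set, np.ndarray)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, (np.floating, float)):
        f = float(obj)
        return None if math.isnan(f) else f
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.bool_, bool)):
        return bool(obj)
    if isinstance(obj, pd.DataFrame):
        return _jsonable(obj.to_dict(orient="records"))
    if isinstance(obj, pd.Series):
        return _jsonable(obj.to_dict())
    return obj


def _bundle_from_dir(indir: Path) -> dict[str, pd.DataFrame | None]:
    tables = {}
    for name in DatasetBundle._FILES:
        path = indir / f"{name}.csv"
        tables[name] = pd.read_csv(path) if path.exists() else None
    return tables


def quantification_results(
    plates: pd.DataFrame | None,
    mpn_tubes: pd.DataFrame | None,
    dna: pd.DataFrame | None,
    microscopy: pd.DataFrame | None,
) -> list[quant.AbundanceResult]:
    """Run all four estimators over the raw observation tables."""
    results: list[quant.AbundanceResult] = []
    if plates is not None:
        for _, r in plates.iterrows():
            results.append(quant.cfu_per_gram(quant.PlateObservation(
                sample_id=r["sample_id"], compartment=r["compartment"],
                organism=r["organism"], colony_count=int(r["colony_count"]),
                dilution_factor=r["dilution_factor"], plated_volume=r["plated_volume"],
                suspension_volume=r["suspension_volume"], sample_mass=r["sample_mass"],
            )))
    if mpn_tubes is not None:
        for (sid, comp), sub in mpn_tubes.groupby(["sample_id", "compartment"], sort=False):
            sub = sub.sort_values("inoculum", ascending=False)
            obs = quant.MPNObservation(
                sample_id=sid, compartment=comp,
                dilution_levels=tuple(
                    (float(r["inoculum"]), int(r["tubes"]), int(r["positives"]))
                    for _, r in sub.iterrows()
                ),
            )
            try:
                results.append(quant.mpn_estimate(obs))
            except ValidationError:
                results.append(quant.AbundanceResult(
                    sample_id=sid, compartment=comp, method="MPN",
                    value=math.nan, censored=True, flags=("all_positive",),
                ))
    if dna is not None:
        for _, r in dna.iterrows():
            results.append(quant.tde_cells_per_gram(quant.DNAYieldObservation(
                sample_id=r["sample_id"], compartment=r["compartment"],
                dna_mass=r["dna_mass"], sample_mass=r["sample_mass"],
            )))
    if microscopy is not None:
        for (sid, comp), sub in microscopy.groupby(["sample_id", "compartment"], sort=False):
            first = sub.iloc[0]
            obs = quant.MicroscopyMosaic(
                sample_id=sid, compartment=comp,
                field_counts_live=tuple(int(v) for v in sub["count_live"]),
                field_counts_dead=tuple(int(v) for v in sub["count_dead"]),
                field_area=first["field_area"], filter_area=first["filter_area"],
                suspension_volume=first["suspension_volume"],
                aliquot_volume=first["aliquot_volume"], sample_mass=first["sample_mass"],
            )
            viable, total, viability = quant.epi_cells_per_gram(obs)
            results.extend([viable, total])
    return results


def run(config: PipelineConfig) -> dict:
    """Execute all stages the inputs allow and return the report dict.

    When ``config.outdir`` is set, derived CSVs, ``report.json`` and a run
    log are written there.
    """
    if config.input_dir is not None:
        tables = _bundle_from_dir(Path(config.input_dir))
    else:
        design = config.design or default_design()
        bundle = generate(design, seed=config.seed)
        tables = {name: getattr(bundle, name) for name in DatasetBundle._FILES}

    skipped: dict[str, str] = {}
    report: dict[str, Any] = {}
    outputs: dict[str, pd.DataFrame] = {}

    enzymes = tables.get("enzymes")
    stoich_summaries = None
    if enzymes is not None:
        stoich_summaries = summaries_frame(enzymes, angle_threshold=config.angle_threshold)
        groups_summary = summarize_group(enzymes, mode=config.mode,
                                         angle_threshold=config.angle_threshold)
        report["stoichiometry"] = {
            "mode": config.mode,
            "per_sample": stoich_summaries,
            "per_group": {
                g.group: {"n": g.n, "mean": {k: v for k, v in vars(g.mean).items()
                                             if not isinstance(v, dict)},
                          "sd": g.sd}
                for g in groups_summary
            },
        }
        outputs["stoichiometry"] = stoich_summaries
    else:
        skipped["stoichiometry"] = "enzymes.csv missing"

    chemistry = tables.get("chemistry")
    chem_derived = None
    if chemistry is not None:
        chem_derived = derive_frame(chemistry)
        flags = {
            str(r["group"]): classify_soil(r)
            for r in chem_derived.to_dict(orient="records")
        }
        report["chemistry"] = {"derived": chem_derived, "flags": flags}
        outputs["chemistry"] = chem_derived
    else:
        skipped["chemistry"] = "chemistry.csv missing"

    qtables = [tables.get(k) for k in ("plates", "mpn_tubes", "dna", "microscopy")]
    if any(t is not None for t in qtables):
        results = quantification_results(*qtables)
        qtable = quant.method_comparison_table(results)
        report["quantification"] = {"table": qtable}
        outputs["quantification"] = qtable
    else:
        qtable = None
        skipped["quantification"] = "no raw quantification tables"

    biomass, respiration = tables.get("biomass"), tables.get("respiration")
    micro = None
    if biomass is not None and respiration is not None:
        micro = params_frame(biomass, respiration, chem_derived)
        per_group = micro.groupby("group", sort=False).agg(
            {c: "mean" for c in micro.columns if micro[c].dtype.kind == "f"})
        report["microbial"] = {"per_sample": micro, "per_group": per_group.reset_index()}
        outputs["microbial"] = micro
    else:
        skipped["microbial"] = "biomass.csv or respiration.csv missing"

    if enzymes is not None and chem_derived is not None and micro is not None:
        fm = mv.assemble_features(enzymes, chem_derived, micro)
        ord_res = mv.pca(fm)
        tests = mv.component_tests(ord_res.scores.iloc[:, :2], fm.groups)
        labels, purity = mv.kmeans_clusters(
            ord_res.scores.iloc[:, :2], fm.groups, k=config.k_clusters, seed=config.seed)
        perm = mv.permanova(fm.data, fm.groups, n_perm=config.permutations, seed=config.seed)

        env_all = fm.raw.loc[:, [c for c in config.env_candidates if c in fm.raw.columns]]
        rda_block: dict[str, Any] | None = None
        if env_all.shape[1] >= 1:
            selected, vifs, dropped_env = mv.vif_screen(env_all, threshold=config.vif_threshold)
            response = fm.data[[c for c in fm.data.columns
                                if fm.roles.get(c) == "biological"]]
            rda_res = mv.rda(response, env_all[selected],
                             n_perm=config.permutations, seed=config.seed)
            rda_block = {
                "selected_env": selected, "dropped_env": dropped_env, "vifs": vifs,
                "constrained_fraction": rda_res.constrained_fraction,
                "r2": rda_res.r2, "adj_r2": rda_res.adj_r2,
                "p_global": rda_res.p_global, "p_axes": rda_res.p_axes,
                "p_terms": rda_res.p_terms,
                "eigenvalues": rda_res.eigenvalues,
                "permutations": rda_res.permutations,
            }

        spearman_block = None
        if qtable is not None:
            ok = qtable[~qtable["censored"] & (qtable["organism"] != "total")]
            wide = ok.assign(key=lambda d: (
                d["method"] + "." + d["compartment"].str[0].str.upper()
                + np.where(d["organism"].isin(["bacteria", "fungi"]),
                           "." + d["organism"].str[0].str.upper(), "")
            )).pivot_table(index="sample_id", columns="key", values="log10_value")
            joined = wide.join(fm.raw, how="inner")
            rho, pval, sig = mv.spearman_matrix(
                wide.loc[joined.index], fm.raw.loc[joined.index], alpha=config.alpha)
            spearman_block = {"rho": rho, "p": pval,
                             "significant_pairs": [
                                 {"quantification": str(i), "parameter": str(c),
                                  "rho": float(rho.loc[i, c]), "p": float(pval.loc[i, c])}
                                 for i in sig.index for c in sig.columns if bool(sig.loc[i, c])
                             ]}

        report["multivariate"] = {
            "n_samples": int(fm.data.shape[0]),
            "n_variables": int(fm.raw.shape[1]),
            "dropped_zero_variance": list(fm.dropped),
            "pca": {
                "explained": ord_res.explained,
                "eigenvalues": ord_res.eigenvalues,
                "scores": ord_res.scores.reset_index(),
                "loadings": ord_res.loadings.reset_index(names="variable"),
            },
            "component_tests": tests,
            "kmeans": {"k": config.k_clusters, "labels": labels, "purity": purity},
            "permanova": vars(perm),
            "rda": rda_block,
            "spearman": spearman_block,
        }
        outputs["pca_scores"] = ord_res.scores.reset_index()
        outputs["pca_loadings"] = ord_res.loadings.reset_index(names="variable")
    else:
        skipped["multivariate"] = "needs enzymes, chemistry and microbial stages"

    cfg_dict = {k: v for k, v in asdict(config).items() if k != "design"}
    cfg_json = json.dumps(_jsonable(cfg_dict), sort_keys=True)
    full_report = {
        "config": cfg_dict,
        "config_hash": hashlib.sha256(cfg_json.encode()).hexdigest(),
        "seed": config.seed,
        "versions": _versions(),
        "skipped": skipped,
        **{k: report.get(k) for k in
           ("stoichiometry", "chemistry", "quantification", "microbial", "multivariate")},
    }
    full_report = _jsonable(full_report)
    PipelineReport.model_validate(full_report)

    if config.outdir is not None:
        outdir = Path(config.outdir)
        outdir.mkdir(parents=True, exist_ok=True)
        for name, frame in outputs.items():
            frame.to_csv(outdir / f"{name}.csv", index=False)
        (outdir / "report.json").write_text(
            json.dumps(full_report, indent=1, sort_keys=True) + "\n")
        (outdir / "run.log").write_text(
            f"seed={config.seed} config_hash={full_report['config_hash']}\n"
            f"versions={full_report['versions']}\nskipped={skipped}\n")
    return full_report


def _versions() -> dict[str, str]:
    import scipy, sklearn, statsmodels
    from importlib.metadata import version
    return {
        "ecostoich": version("ecostoich"),
        "numpy": np.__version__, "pandas": pd.__version__,
        "scipy": scipy.__version__, "scikit-learn": sklearn.__version__,
        "statsmodels": statsmodels.__version__,
    }


def validate_inputs(indir) -> dict:
    """Schema and invariant checks on an input directory; report-only.

    Returns ``{"files": {...}, "findings": [...]}`` where each finding
    names the file, the row (where applicable) and the problem.
    """
    indir = Path(indir)
    findings: list[dict] = []
    files: dict[str, str] = {}

    def note(fname: str, message: str, row=None) -> None:
        findings.append({"file": fname, "row": row, "message": message})

    tables = _bundle_from_dir(indir)
    for name in DatasetBundle._FILES:
        files[name] = "present" if tables[name] is not None else "missing"

    enzymes = tables["enzymes"]
    if enzymes is not None:
        for col in ("sample_id", "group", *ENZYME_COLUMNS):
            if col not in enzymes.columns:
                note("enzymes.csv", f"missing column {col}")
        if "sample_id" in enzymes.columns:
            for idx in enzymes.index[enzymes["sample_id"].duplicated()]:
                note("enzymes.csv", f"duplicated sample_id {enzymes.loc[idx, 'sample_id']!r}", int(idx))
        for col in ENZYME_COLUMNS:
            if col in enzymes.columns:
                for idx in enzymes.index[enzymes[col] < 0]:
                    note("enzymes.csv", f"negative activity in {col}", int(idx))
                for idx in enzymes.index[enzymes[col].isna()]:
                    note("enzymes.csv", f"missing activity in {col}", int(idx))

    chemistry = tables["chemistry"]
    if chemistry is not None:
        for col in ("OM", "TN", "P", "Ca", "Mg", "K", "Na", "Al", "PA"):
            if col in chemistry.columns:
                for idx in chemistry.index[chemistry[col] < 0]:
                    note("chemistry.csv", f"negative value in {col}", int(idx))

    plates = tables["plates"]
    if plates is not None and "colony_count" in plates.columns:
        for idx in plates.index[plates["colony_count"] < 0]:
            note("plates.csv", "negative colony count", int(idx))
        if "dilution_factor" in plates.columns:
            for idx in plates.index[plates["dilution_factor"] < 1]:
                note("plates.csv", "dilution_factor below 1", int(idx))

    tubes = tables["mpn_tubes"]
    if tubes is not None and {"tubes", "positives"} <= set(tubes.columns):
        bad = (tubes["positives"] < 0) | (tubes["positives"] > tubes["tubes"])
        for idx in tubes.index[bad]:
            note("mpn_tubes.csv", "positives outside [0, tubes]", int(idx))

    resp = tables["respiration"]
    if resp is not None and {"blank_titre", "sample_titre"} <= set(resp.columns):
        for idx in resp.index[resp["sample_titre"] > resp["blank_titre"]]:
            note("respiration.csv", "sample titre exceeds blank", int(idx))

    return {"files": files, "findings": findings, "n_findings": len(findings)}
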