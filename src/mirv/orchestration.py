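"""End-to-end pipeline: ingest/simulate → validate → reduce → score →
response → associate → survival, with a run manifest for reproducibility.

Every configurable analysis decision (thresholds, direction convention,
standardization flag, FDR method, tie handling, dichotomization rule,
reference categories, seed) is recorded in the manifest so a run can be
audited and reproduced bit-identically.
"""

from __future__ import annotations

import hashlib
import json
import logging
from dataclasses import asdict
from pathlib import Path

import pandas as pd

from . import __version__
from .association_stats import (
    assemble_liquid_biopsy_variables,
    assemble_volumetric_variables,
    association_matrix,
)
from .cohort_io import (
    HISTOLOGY_COL,
    PATIENT_COL,
    ClinicalTable,
    LesionTable,
    filter_multimetastatic,
    read_clinical_table,
    read_lesion_table,
    validate_cohort,
    write_clinical_table,
    write_lesion_table,
)
from .feature_reduction import feature_matrix, reduce_features
from .mirv_metrics import cohort_mirv
from .response_metrics import cohort_response
from .survival_stats import (
    build_design_matrix,
    fit_cox,
    subgroup_analysis,
)
from .synthetic_cohort import SyntheticConfig, generate_cohort

logger = logging.getLogger(__name__)

DEFAULT_PARAMS = {
    "min_lesions": 2,
    "volume_tau": 0.1,
    "correlation_tau": 0.7,
    "standardize": True,
    "tsrc_threshold": 33.0,
    "tsrc_convention": "reduction",
    "fdr_method": "benjamini-hochberg",
    "cox_ties": "efron",
    "mirv_variant": "mirv_max_distance",
    "km_split": "median",
    "interaction": True,
    "subgroup_min": 20,
    "histology_reference": "Other",
    "recist_reference": "SD",
}


class PipelineError(RuntimeError):
    def __init__(self, stage: str, cause: Exception):
        super().__init__(f"pipeline aborted at stage '{stage}': {cause}")
        self.stage = stage
        self.cause = cause


def _sha256(path: Path) -> str:
    return hashlib.sha256(path.read_bytes()).hexdigest()


def run_pipeline(config: dict, out_dir, seed: int | None = None) -> dict:
    """Run every stage and write the output bundle under ``out_dir``.

    ``config`` has either a ``simulate`` block (SyntheticConfig fields) or
    an ``inputs`` block (``lesions``/``clinical`` CSV paths), plus an
    optional ``params`` block overriding :data:`DEFAULT_PARAMS`. Returns
    the run manifest (also written as ``manifest.json``).
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    params = {**DEFAULT_PARAMS, **config.get("params", {})}
    manifest: dict = {
        "tool": "mirv",
        "version": __version__,
        "seed": seed,
        "params": params,
        "inputs": {},
        "stages": {},
    }

    # --- ingest or simulate -------------------------------------------------
    try:
        if "simulate" in config:
            sim_cfg = SyntheticConfig(**config["simulate"])
            lesions, clinical, truth = generate_cohort(sim_cfg, seed=seed or 0)
            write_lesion_table(lesions, out / "lesions.csv")
            write_clinical_table(clinical, out / "clinical.csv")
            truth.patients.to_csv(out / "truth_patients.csv", index=False)
            manifest["inputs"]["simulate"] = asdict(sim_cfg)
        else:
            paths = config["inputs"]
            lesions = read_lesion_table(paths["lesions"])
            clinical = read_clinical_table(paths["clinical"])
            manifest["inputs"] = {
                "lesions": {"path": str(paths["lesions"]), "sha256": _sha256(Path(paths["lesions"]))},
                "clinical": {"path": str(paths["clinical"]), "sha256": _sha256(Path(paths["clinical"]))},
            }
    except Exception as exc:
        raise PipelineError("ingest", exc) from exc

    # --- validate -----------------------------------------------------------
    report = validate_cohort(lesions, clinical)
    manifest["stages"]["validate"] = {
        "n_patients": report.n_patients,
        "n_lesions": report.n_lesions,
        "errors": [list(e) for e in report.errors],
        "warnings": report.warnings,
    }
    if not report.ok:
        raise PipelineError("validate", ValueError(f"{len(report.errors)} validation error(s)"))

    # --- filter + reduce ----------------------------------------------------
    try:
        lesions = filter_multimetastatic(lesions, min_lesions=params["min_lesions"])
        M, volumes = feature_matrix(lesions)
        reduced, red_report = reduce_features(
            M, volumes,
            volume_tau=params["volume_tau"],
            correlation_tau=params["correlation_tau"],
        )
        reduced.reset_index().to_csv(out / "reduced.csv", index=False)
        (out / "reduction_report.json").write_text(
            json.dumps(red_report.to_dict(), indent=2, sort_keys=True)
        )
        manifest["stages"]["reduce"] = {
            "n_features_in": M.shape[1],
            "n_features_out": reduced.shape[1],
            "removed": red_report.to_dict(),
        }
    except Exception as exc:
        raise PipelineError("reduce", exc) from exc

    # --- MIRV scoring -------------------------------------------------------
    try:
        mirv_table = cohort_mirv(reduced, apply_standardize=params["standardize"])
        mirv_table.to_csv(out / "mirv.csv", index=False)
        manifest["stages"]["mirv"] = {"n_patients": len(mirv_table)}
    except Exception as exc:
        raise PipelineError("mirv", exc) from exc

    # --- volumetric response ------------------------------------------------
    response_table = None
    if "followup_volume_mm3" in lesions.df.columns and lesions.df[
        "followup_volume_mm3"
    ].notna().any():
        try:
            response_table = cohort_response(
                lesions,
                threshold=params["tsrc_threshold"],
                convention=params["tsrc_convention"],
            )
            response_table.to_csv(out / "response.csv", index=False)
            manifest["stages"]["response"] = {
                "n_patients": len(response_table),
                "complete_response_rate": float(response_table["tsrc"].mean()),
            }
        except Exception as exc:
            raise PipelineError("response", exc) from exc

    # --- associations -------------------------------------------------------
    clinical_patients = set(clinical.df[PATIENT_COL])
    if response_table is not None:
        try:
            vol_vars = assemble_volumetric_variables(mirv_table, response_table)
            assoc_vol = association_matrix(vol_vars)
            assoc_vol.to_csv(out / "associations_volumetric.csv", index=False)
            manifest["stages"]["associate_volumetric"] = {"n_pairs": len(assoc_vol)}
        except Exception as exc:
            raise PipelineError("associate_volumetric", exc) from exc
        if clinical.has_ctdna:
            try:
                lb_vars = assemble_liquid_biopsy_variables(
                    mirv_table, response_table, clinical.df
                )
                assoc_lb = association_matrix(lb_vars)
                assoc_lb.to_csv(out / "associations_liquid_biopsy.csv", index=False)
                manifest["stages"]["associate_liquid_biopsy"] = {"n_pairs": len(assoc_lb)}
            except Exception as exc:
                raise PipelineError("associate_liquid_biopsy", exc) from exc

    # --- survival -----------------------------------------------------------
    try:
        surv = mirv_table.merge(clinical.df, on=PATIENT_COL, how="inner")
        if response_table is not None:
            surv = surv.merge(
                response_table[[PATIENT_COL, "baseline_total"]], on=PATIENT_COL, how="left"
            )
        else:
            from .response_metrics import baseline_volume_metrics

            totals = lesions.df.groupby(PATIENT_COL)["baseline_volume_mm3"].sum()
            surv["baseline_total"] = surv[PATIENT_COL].map(totals)
        skipped = len(mirv_table) - len(surv)
        if skipped:
            logger.warning("%d scored patient(s) lack clinical data; excluded "
                           "from survival analysis", skipped)
        design = build_design_matrix(
            surv,
            mirv_col=params["mirv_variant"],
            histology_reference=params["histology_reference"],
            recist_reference=params["recist_reference"],
            interaction=params["interaction"],
        )
        cox = fit_cox(design)
        cox.summary.to_csv(out / "cox.csv", index=False)
        subgroups = subgroup_analysis(
            surv, mirv_col=params["mirv_variant"], min_size=params["subgroup_min"]
        )
        sub_rows = [
            {
                "stratum": level,
                "statistic": r.statistic,
                "p": r.p,
                "n_low": r.group_sizes.get("low", 0),
                "n_high": r.group_sizes.get("high", 0),
            }
            for level, r in subgroups.items()
        ]
        pd.DataFrame(sub_rows).to_csv(out / "km_subgroups.csv", index=False)
        km_rows = []
        for level, r in subgroups.items():
            for g, curve in r.curves.items():
                c = curve.copy()
                c.insert(0, "group", g)
                c.insert(0, "stratum", level)
                km_rows.append(c)
        if km_rows:
            pd.concat(km_rows, ignore_index=True).to_csv(out / "km_curves.csv", index=False)
        manifest["stages"]["survival"] = {
            "n": cox.n,
            "n_events": cox.n_events,
            "n_subgroups_tested": len(subgroups),
            "note": "per-stratum log-rank p-values are exploratory (no multiplicity adjustment)",
        }
    except Exception as exc:
        raise PipelineError("survival", exc) from exc

    (out / "manifest.json").write_text(json.dumps(manifest, indent=2, sort_keys=True))
    return manifest
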