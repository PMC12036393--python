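"""Reading, validation and filtering of lesion-level and patient-level tables.

The lesion table is the tabular output of a radiomic feature extractor:
one row per contoured lesion, keyed by ``patient_id`` and ``lesion_id``,
with the lesion's baseline volume (and optionally its first-follow-up
volume) in mm³ and an arbitrary number of named numeric feature columns.
The clinical table carries one row per patient: right-censored overall
survival, histological subtype, age, performance status, the RECIST 1.1
category, and optional binary pre/post-treatment ctDNA status.

Everything downstream (feature reduction, heterogeneity scoring, response
and survival analysis) consumes the two containers defined here.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

logger = logging.getLogger(__name__)

# Mandatory / recognised column names for the lesion table. Any other
# numeric column is registered as a radiomic feature.
PATIENT_COL = "patient_id"
LESION_COL = "lesion_id"
BASELINE_VOL_COL = "baseline_volume_mm3"
FOLLOWUP_VOL_COL = "followup_volume_mm3"

# Clinical table columns.
OS_TIME_COL = "os_time_years"
OS_EVENT_COL = "os_event"
HISTOLOGY_COL = "histology"
AGE_COL = "age"
PERFORMANCE_COL = "performance_status"
RECIST_COL = "recist"
CTDNA_PRE_COL = "ctdna_pre"
CTDNA_POST_COL = "ctdna_post"

HISTOLOGY_LEVELS = ("Leiomyosarcoma", "Liposarcoma", "UPS", "Other")
RECIST_LEVELS = ("PR", "SD", "PD", "NE")

_CLINICAL_MANDATORY = (
    PATIENT_COL,
    OS_TIME_COL,
    OS_EVENT_COL,
    HISTOLOGY_COL,
    AGE_COL,
    PERFORMANCE_COL,
    RECIST_COL,
)


class CohortFormatError(ValueError):
    """A table file does not conform to the expected layout."""


class CohortParseError(ValueError):
    """A cell could not be parsed as the required type."""


class ParameterError(ValueError):
    """An operation was called with an out-of-range parameter."""


@dataclass
class LesionTable:
    """Per-lesion radiomic feature vectors plus volumes.

    ``df`` holds one row per lesion with string keys, float volume columns
    and float feature columns; ``feature_names`` fixes the feature order.
    """

    df: pd.DataFrame
    feature_names: list[str]

    @property
    def n_lesions(self) -> int:
        return len(self.df)

    @property
    def patient_ids(self) -> list[str]:
        return list(dict.fromkeys(self.df[PATIENT_COL]))

    def lesions_of(self, patient_id: str) -> pd.DataFrame:
        return self.df[self.df[PATIENT_COL] == patient_id]


@dataclass
class ClinicalTable:
    """Per-patient clinical covariates and survival endpoint."""

    df: pd.DataFrame
    has_ctdna: bool

    @property
    def n_patients(self) -> int:
        return len(self.df)


@dataclass
class ValidationReport:
    """Outcome of cohort validation: errors block the pipeline, warnings do not."""

    errors: list[tuple[str, str]] = field(default_factory=list)
    warnings: list[str] = field(default_factory=list)
    n_patients: int = 0
    n_lesions: int = 0

    @property
    def ok(self) -> bool:
        return not self.errors


def _parse_numeric(df: pd.DataFrame, columns: list[str], path: str) -> pd.DataFrame:
    """Convert ``columns`` to float, raising a located error on bad cells."""
    out = df.copy()
    for col in columns:
        converted = pd.to_numeric(out[col], errors="coerce")
        bad = converted.isna() & out[col].notna()
        if out[col].isna().any():
            row = int(out.index[out[col].isna()][0])
            raise CohortParseError(
                f"{path}: missing value in column '{col}' at data row {row}"
            )
        if bad.any():
            row = int(out.index[bad][0])
            raise CohortParseError(
                f"{path}: non-numeric value {out[col][bad].iloc[0]!r} in column "
                f"'{col}' at data row {row}"
            )
        out[col] = converted.astype(float)
    return out


def read_lesion_table(path) -> LesionTable:
    """Read a lesion-level CSV.

    Mandatory columns: ``patient_id``, ``lesion_id``, ``baseline_volume_mm3``;
    ``followup_volume_mm3`` is optional (empty cells allowed). Every other
    column is parsed as a numeric radiomic feature; a non-numeric or missing
    feature cell is a hard error. Row order is preserved.
    """
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    for col in (PATIENT_COL, LESION_COL, BASELINE_VOL_COL):
        if col not in raw.columns:
            raise CohortFormatError(f"{path}: missing mandatory column '{col}'")
    feature_names = [
        c
        for c in raw.columns
        if c not in (PATIENT_COL, LESION_COL, BASELINE_VOL_COL, FOLLOWUP_VOL_COL)
    ]
    df = _parse_numeric(raw, [BASELINE_VOL_COL] + feature_names, str(path))
    if FOLLOWUP_VOL_COL in df.columns:
        # optional column: blanks stay NaN, non-blank cells must parse
        converted = pd.to_numeric(df[FOLLOWUP_VOL_COL], errors="coerce")
        bad = converted.isna() & df[FOLLOWUP_VOL_COL].notna()
        if bad.any():
            row = int(df.index[bad][0])
            raise CohortParseError(
                f"{path}: non-numeric value in column '{FOLLOWUP_VOL_COL}' "
                f"at data row {row}"
            )
        df[FOLLOWUP_VOL_COL] = converted.astype(float)
    df[PATIENT_COL] = df[PATIENT_COL].astype(str)
    df[LESION_COL] = df[LESION_COL].astype(str)
    logger.info(
        "read %d lesions, %d features from %s", len(df), len(feature_names), path
    )
    return LesionTable(df=df.reset_index(drop=True), feature_names=feature_names)


def write_lesion_table(table: LesionTable, path) -> None:
    table.df.to_csv(path, index=False)


def read_clinical_table(path) -> ClinicalTable:
    """Read a patient-level clinical CSV; ctDNA columns may be absent."""
    raw = pd.read_csv(path, dtype=str, keep_default_na=False)
    raw = raw.replace({"": None})
    for col in _CLINICAL_MANDATORY:
        if col not in raw.columns:
            raise CohortFormatError(f"{path}: missing mandatory column '{col}'")
    df = _parse_numeric(
        raw, [OS_TIME_COL, OS_EVENT_COL, AGE_COL, PERFORMANCE_COL], str(path)
    )
    df[PATIENT_COL] = df[PATIENT_COL].astype(str)

    bad_hist = ~df[HISTOLOGY_COL].isin(HISTOLOGY_LEVELS)
    if bad_hist.any():
        raise CohortParseError(
            f"{path}: histology value {df[HISTOLOGY_COL][bad_hist].iloc[0]!r} "
            f"not in {HISTOLOGY_LEVELS}"
        )
    bad_recist = ~df[RECIST_COL].isin(RECIST_LEVELS)
    if bad_recist.any():
        raise CohortParseError(
            f"{path}: recist value {df[RECIST_COL][bad_recist].iloc[0]!r} "
            f"not in {RECIST_LEVELS}"
        )
    if (df[OS_TIME_COL] <= 0).any():
        raise CohortParseError(f"{path}: os_time_years must be > 0")
    if not df[OS_EVENT_COL].isin([0.0, 1.0]).all():
        raise CohortParseError(f"{path}: os_event must be 0 or 1")

    has_ctdna = CTDNA_PRE_COL in df.columns or CTDNA_POST_COL in df.columns
    for col in (CTDNA_PRE_COL, CTDNA_POST_COL):
        if col in df.columns:
            converted = pd.to_numeric(df[col], errors="coerce")
            present = df[col].notna()
            if (converted[present].isna()).any() or not converted[present].isin(
                [0.0, 1.0]
            ).all():
                raise CohortParseError(f"{path}: column '{col}' must be binary 0/1")
            df[col] = converted
    logger.info("read %d patients from %s", len(df), path)
    return ClinicalTable(df=df.reset_index(drop=True), has_ctdna=has_ctdna)


def write_clinical_table(table: ClinicalTable, path) -> None:
    table.df.to_csv(path, index=False)


def validate_cohort(lesions: LesionTable, clinical: ClinicalTable) -> ValidationReport:
    """Check cross-table invariants; every violation goes into the report.

    Lesion-table patients absent from the clinical table are warnings only:
    they can still be scored for heterogeneity and volumetric response but
    are excluded from association/survival stages.
    """
    report = ValidationReport()
    ldf, cdf = lesions.df, clinical.df

    dup = ldf.duplicated(subset=[PATIENT_COL, LESION_COL])
    for _, row in ldf[dup].iterrows():
        report.errors.append(
            (f"{row[PATIENT_COL]}/{row[LESION_COL]}", "duplicate (patient, lesion) key")
        )
    bad_v0 = ldf[BASELINE_VOL_COL] <= 0
    for _, row in ldf[bad_v0].iterrows():
        report.errors.append(
            (f"{row[PATIENT_COL]}/{row[LESION_COL]}", "baseline_volume_mm3 must be > 0")
        )
    if FOLLOWUP_VOL_COL in ldf.columns:
        bad_v1 = ldf[FOLLOWUP_VOL_COL].notna() & (ldf[FOLLOWUP_VOL_COL] <= 0)
        for _, row in ldf[bad_v1].iterrows():
            report.errors.append(
                (
                    f"{row[PATIENT_COL]}/{row[LESION_COL]}",
                    "followup_volume_mm3 must be > 0 when present",
                )
            )
    for feat in lesions.feature_names:
        if ldf[feat].isna().any():
            report.errors.append((feat, "missing feature values"))

    dup_p = cdf.duplicated(subset=[PATIENT_COL])
    for _, row in cdf[dup_p].iterrows():
        report.errors.append((row[PATIENT_COL], "duplicate patient_id"))

    lesion_patients = set(ldf[PATIENT_COL])
    clinical_patients = set(cdf[PATIENT_COL])
    orphans = sorted(lesion_patients - clinical_patients)
    if orphans:
        report.warnings.append(
            f"{len(orphans)} lesion-table patient(s) absent from clinical table "
            f"(excluded from survival/association stages): {orphans[:5]}"
        )
    report.n_patients = len(lesion_patients)
    report.n_lesions = len(ldf)
    return report


def filter_multimetastatic(lesions: LesionTable, min_lesions: int = 2) -> LesionTable:
    """Keep only patients with at least ``min_lesions`` contoured lesions.

    Intertumor heterogeneity is undefined for single-lesion patients, so the
    default keeps the multi-metastatic subset. Row order is preserved and the
    operation is idempotent.
    """
    if min_lesions < 1:
        raise ParameterError(f"min_lesions must be >= 1, got {min_lesions}")
    if lesions.df.empty:
        return LesionTable(df=lesions.df.copy(), feature_names=list(lesions.feature_names))
    counts = lesions.df[PATIENT_COL].value_counts()
    keep = counts.index[counts >= min_lesions]
    out = lesions.df[lesions.df[PATIENT_COL].isin(keep)].reset_index(drop=True)
    if out.empty and not lesions.df.empty:
        logger.warning("filter_multimetastatic removed every patient")
    return LesionTable(df=out, feature_names=list(lesions.feature_names))
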