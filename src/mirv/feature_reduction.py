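"""Stepwise radiomic feature reduction.

Radiomic panels are massively redundant: many texture features are noisy
re-parameterisations of each other or thin surrogates of lesion volume.
Before heterogeneity can be scored, the panel is reduced in three ordered
stages on the pooled lesion matrix (all lesions of all patients):

1. variance filter  — drop features whose sample variance is strictly
   below the median variance across all features;
2. volume filter    — drop features whose absolute Spearman correlation
   with baseline lesion volume exceeds 0.1 (volume surrogates);
3. redundancy filter — greedy scan in column order, dropping any feature
   whose absolute Spearman correlation with an already-retained feature
   exceeds 0.7.

The surviving feature set is what the heterogeneity metrics operate on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .cohort_io import (
    BASELINE_VOL_COL,
    LESION_COL,
    PATIENT_COL,
    LesionTable,
    ParameterError,
)

logger = logging.getLogger(__name__)

DEFAULT_VOLUME_TAU = 0.1
DEFAULT_CORRELATION_TAU = 0.7


class EmptyFeatureSetError(ValueError):
    """Every feature was removed; nothing remains to score."""


@dataclass
class ReductionReport:
    """Audit trail: per stage, the removed features and their triggering statistic."""

    variance: list[tuple[str, float]] = field(default_factory=list)
    volume: list[tuple[str, float]] = field(default_factory=list)
    correlation: list[tuple[str, float]] = field(default_factory=list)

    def removed(self) -> list[str]:
        return [n for stage in (self.variance, self.volume, self.correlation) for n, _ in stage]

    def to_dict(self) -> dict:
        return {
            "variance": [[n, s] for n, s in self.variance],
            "volume": [[n, s] for n, s in self.volume],
            "correlation": [[n, s] for n, s in self.correlation],
        }


def feature_matrix(lesions: LesionTable) -> tuple[pd.DataFrame, pd.Series]:
    """Extract the lesions × features matrix and the aligned baseline volumes.

    Rows are indexed by (patient_id, lesion_id).
    """
    idx = pd.MultiIndex.from_frame(lesions.df[[PATIENT_COL, LESION_COL]])
    M = lesions.df[lesions.feature_names].copy()
    M.index = idx
    volumes = lesions.df[BASELINE_VOL_COL].copy()
    volumes.index = idx
    return M, volumes


def _check_matrix(M: pd.DataFrame, min_rows: int) -> None:
    if len(M) < min_rows:
        raise ValueError(f"feature matrix needs >= {min_rows} rows, got {len(M)}")
    if M.isna().any().any():
        raise ValueError("feature matrix contains missing values")


def variance_filter(M: pd.DataFrame) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Drop features with sample variance strictly below the median variance.

    Features exactly at the median are retained (strict inequality), so a
    matrix of equal-variance features passes through unchanged.
    """
    _check_matrix(M, 2)
    variances = M.var(ddof=1)
    median = float(variances.median())
    removed = [(c, float(variances[c])) for c in M.columns if variances[c] < median]
    kept = [c for c in M.columns if variances[c] >= median]
    return M[kept], removed


def volume_filter(
    M: pd.DataFrame, volumes: pd.Series, tau: float = DEFAULT_VOLUME_TAU
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Drop features with |Spearman rho| vs baseline volume strictly above ``tau``.

    Correlation is computed on all lesions pooled across patients — the
    reduction produces one cohort-level feature set.
    """
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"tau must be in [0, 1], got {tau}")
    _check_matrix(M, 3)
    if len(volumes) != len(M):
        raise ValueError("volumes must align with matrix rows")
    vol = np.asarray(volumes, dtype=float)
    removed, kept = [], []
    for c in M.columns:
        rho = stats.spearmanr(M[c].to_numpy(), vol).statistic
        if np.isnan(rho):  # constant feature: no volume association measurable
            kept.append(c)
        elif abs(rho) > tau:
            removed.append((c, float(rho)))
        else:
            kept.append(c)
    return M[kept], removed


def correlation_filter(
    M: pd.DataFrame, tau: float = DEFAULT_CORRELATION_TAU
) -> tuple[pd.DataFrame, list[tuple[str, float]]]:
    """Greedy redundancy filter: scan columns left to right, drop a feature iff
    its |Spearman rho| with an already-retained feature exceeds ``tau``.

    Keep-first tie-breaking makes the result deterministic and order-stable;
    reordering columns changes which member of a correlated clique survives.
    The output has all pairwise |rho| <= tau and the filter is idempotent.
    """
    if not 0.0 <= tau <= 1.0:
        raise ParameterError(f"tau must be in [0, 1], got {tau}")
    _check_matrix(M, 3)
    corr = M.corr(method="spearman").abs()
    retained: list[str] = []
    removed: list[tuple[str, float]] = []
    for c in M.columns:
        over = [k for k in retained if corr.loc[c, k] > tau]
        if over:
            removed.append((c, float(corr.loc[c, over[0]])))
        else:
            retained.append(c)
    return M[retained], removed


def reduce_features(
    M: pd.DataFrame,
    volumes: pd.Series,
    volume_tau: float = DEFAULT_VOLUME_TAU,
    correlation_tau: float = DEFAULT_CORRELATION_TAU,
) -> tuple[pd.DataFrame, ReductionReport]:
    """Run the three filters in order: variance → volume → redundancy."""
    report = ReductionReport()
    M1, report.variance = variance_filter(M)
    if M1.shape[1] == 0:
        raise EmptyFeatureSetError("variance filter removed every feature")
    M2, report.volume = volume_filter(M1, volumes, tau=volume_tau)
    if M2.shape[1] == 0:
        raise EmptyFeatureSetError("volume filter removed every feature")
    M3, report.correlation = correlation_filter(M2, tau=correlation_tau)
    if M3.shape[1] == 0:
        raise EmptyFeatureSetError("correlation filter removed every feature")
    logger.info(
        "feature reduction: %d -> %d features (variance -%d, volume -%d, redundancy -%d)",
        M.shape[1],
        M3.shape[1],
        len(report.variance),
        len(report.volume),
        len(report.correlation),
    )
    return M3, report
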