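"""Survival analysis: multivariable Cox model and Kaplan–Meier subgroups.

The heterogeneity score enters a Cox proportional-hazards model as a
continuous covariate alongside the clinical covariates (histology,
baseline tumor burden, performance status, age, RECIST category), with an
optional score × histology interaction. A significant interaction
motivates subgroup analysis: within each histology level the score is
median-dichotomized into low/high groups, Kaplan–Meier curves estimated,
and the two-group log-rank test applied.

Fitting uses the lifelines toolkit; tied event times are handled with
Efron's approximation. Reference categories: histology = "Other",
RECIST = "SD" (configurable).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from lifelines import CoxPHFitter, KaplanMeierFitter
from lifelines.exceptions import ConvergenceError
from lifelines.statistics import logrank_test

from .cohort_io import (
    AGE_COL,
    HISTOLOGY_COL,
    HISTOLOGY_LEVELS,
    OS_EVENT_COL,
    OS_TIME_COL,
    PERFORMANCE_COL,
    RECIST_COL,
    RECIST_LEVELS,
)

logger = logging.getLogger(__name__)

DEFAULT_HISTOLOGY_REFERENCE = "Other"
DEFAULT_RECIST_REFERENCE = "SD"
DEFAULT_SUBGROUP_MIN = 20


class CoxFitError(RuntimeError):
    """The partial-likelihood fit failed (non-convergence, separation, no events)."""


@dataclass
class CoxResult:
    """Fitted Cox model: one row per covariate in ``summary``.

    Columns: coef (log hazard ratio), hr, ci_lower, ci_upper (95%, on the
    HR scale), p.
    """

    summary: pd.DataFrame
    log_likelihood: float
    n: int
    n_events: int


@dataclass
class LogRankResult:
    statistic: float
    p: float
    group_sizes: dict[str, int]
    curves: dict[str, pd.DataFrame] = field(default_factory=dict)


def _dummy_code(
    series: pd.Series, levels: tuple[str, ...], reference: str, prefix: str
) -> pd.DataFrame:
    cols = {}
    for level in levels:
        if level == reference:
            continue
        cols[f"{prefix}_{level}"] = (series == level).astype(float)
    return pd.DataFrame(cols, index=series.index)


def build_design_matrix(
    df: pd.DataFrame,
    mirv_col: str,
    continuous_covariates: tuple[str, ...] = (AGE_COL, PERFORMANCE_COL, "baseline_total"),
    histology_reference: str = DEFAULT_HISTOLOGY_REFERENCE,
    recist_reference: str = DEFAULT_RECIST_REFERENCE,
    interaction: bool = False,
) -> pd.DataFrame:
    """Reference-coded design matrix for the multivariable Cox model.

    With ``interaction=True``, score × histology product terms are added
    (one per non-reference level), so the main-effect coefficient of the
    score is its effect in the reference histology.
    """
    parts = [df[[OS_TIME_COL, OS_EVENT_COL, mirv_col]].copy()]
    parts.append(df[[c for c in continuous_covariates if c in df.columns]].astype(float))
    hist = _dummy_code(df[HISTOLOGY_COL], HISTOLOGY_LEVELS, histology_reference, "hist")
    parts.append(hist)
    parts.append(_dummy_code(df[RECIST_COL], RECIST_LEVELS, recist_reference, "recist"))
    if interaction:
        inter = hist.mul(df[mirv_col].to_numpy(), axis=0)
        inter.columns = [f"{mirv_col}_x_{c}" for c in hist.columns]
        parts.append(inter)
    X = pd.concat(parts, axis=1)
    # drop all-zero dummy columns (level absent from this cohort)
    keep = [c for c in X.columns if X[c].nunique() > 1 or c in (OS_TIME_COL, OS_EVENT_COL, mirv_col)]
    dropped = sorted(set(X.columns) - set(keep))
    if dropped:
        logger.warning("dropping constant design columns: %s", dropped)
    return X[keep]


def fit_cox(design: pd.DataFrame) -> CoxResult:
    """Maximize the Cox partial likelihood (Efron ties) on a design matrix.

    ``design`` must contain the duration and event columns plus numeric
    covariates only. Zero observed events or a failed / separated fit
    raise :class:`CoxFitError` rather than returning silent output.
    """
    n_events = int(design[OS_EVENT_COL].sum())
    if n_events == 0:
        raise CoxFitError("no observed events; Cox model cannot be fit")
    covars = [c for c in design.columns if c not in (OS_TIME_COL, OS_EVENT_COL)]
    for c in covars:
        if design[c].nunique() <= 1:
            raise CoxFitError(f"covariate {c!r} is constant")
    fitter = CoxPHFitter()
    try:
        fitter.fit(
            design,
            duration_col=OS_TIME_COL,
            event_col=OS_EVENT_COL,
            fit_options={"precision": 1e-9},
        )
    except (ConvergenceError, np.linalg.LinAlgError) as exc:
        raise CoxFitError(f"Cox fit failed: {exc}") from exc
    s = fitter.summary
    summary = pd.DataFrame(
        {
            "covariate": s.index,
            "coef": s["coef"].to_numpy(),
            "hr": np.exp(s["coef"].to_numpy()),
            "ci_lower": np.exp(s["coef lower 95%"].to_numpy()),
            "ci_upper": np.exp(s["coef upper 95%"].to_numpy()),
            "p": s["p"].to_numpy(),
        }
    ).reset_index(drop=True)
    return CoxResult(
        summary=summary,
        log_likelihood=float(fitter.log_likelihood_),
        n=len(design),
        n_events=n_events,
    )


def dichotomize(values: pd.Series, method: str = "median") -> pd.Series:
    """Split a continuous score into 'low' (<= median) and 'high' (> median)."""
    if method != "median":
        raise ValueError(f"unknown dichotomization method {method!r}")
    v = pd.Series(values).astype(float)
    if v.nunique() < 2:
        raise ValueError("cannot dichotomize a constant score")
    cut = float(v.median())
    groups = pd.Series(np.where(v > cut, "high", "low"), index=v.index)
    logger.info("median dichotomization at %.6g: %d low / %d high",
                cut, (groups == "low").sum(), (groups == "high").sum())
    return groups


def km_logrank(times, events, groups) -> LogRankResult:
    """Two-group Kaplan–Meier estimates plus the log-rank test.

    The statistic is the usual observed-minus-expected score over the
    hypergeometric variance accumulated at each distinct event time.
    """
    df = pd.DataFrame(
        {"time": np.asarray(times, float), "event": np.asarray(events, int),
         "group": np.asarray(groups)}
    )
    labels = sorted(df["group"].unique())
    if len(labels) != 2:
        raise ValueError(f"expected exactly 2 groups, got {labels}")
    sizes = {g: int((df["group"] == g).sum()) for g in labels}
    if min(sizes.values()) == 0:
        raise ValueError("both groups must be non-empty")
    a = df[df["group"] == labels[0]]
    b = df[df["group"] == labels[1]]
    res = logrank_test(a["time"], b["time"], event_observed_A=a["event"],
                       event_observed_B=b["event"])
    curves = {}
    for g, sub in ((labels[0], a), (labels[1], b)):
        km = KaplanMeierFitter()
        km.fit(sub["time"], event_observed=sub["event"], label=str(g))
        ev = km.event_table
        curves[g] = pd.DataFrame(
            {
                "time": km.survival_function_.index.to_numpy(),
                "survival": km.survival_function_.iloc[:, 0].to_numpy(),
                "at_risk": ev["at_risk"].reindex(km.survival_function_.index).to_numpy(),
            }
        )
    return LogRankResult(
        statistic=float(res.test_statistic),
        p=float(res.p_value),
        group_sizes=sizes,
        curves=curves,
    )


def subgroup_analysis(
    df: pd.DataFrame,
    mirv_col: str,
    stratify_by: str = HISTOLOGY_COL,
    min_size: int = DEFAULT_SUBGROUP_MIN,
) -> dict[str, LogRankResult]:
    """Median-dichotomized log-rank test within each stratum.

    Strata smaller than ``min_size`` are skipped with a warning. The
    per-stratum p-values are exploratory (no multiplicity adjustment);
    downstream reporting should carry that caveat.
    """
    results: dict[str, LogRankResult] = {}
    for level, sub in df.groupby(stratify_by, sort=True):
        if len(sub) < min_size:
            logger.warning(
                "stratum %r has %d patients (< %d); skipped", level, len(sub), min_size
            )
            continue
        try:
            groups = dichotomize(sub[mirv_col])
        except ValueError as exc:
            logger.warning("stratum %r skipped: %s", level, exc)
            continue
        results[str(level)] = km_logrank(sub[OS_TIME_COL], sub[OS_EVENT_COL], groups)
    return results
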