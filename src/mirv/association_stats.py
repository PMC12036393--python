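"""Correlation analysis between heterogeneity scores and response variables.

All pairwise associations among the MIRV metrics, the response variables
(Complete Tumor Response label, response range), the baseline-volume
controls and — in the liquid-biopsy subset — the binary ctDNA labels are
measured with Spearman's rank correlation and adjusted per matrix with
the Benjamini–Hochberg false-discovery-rate procedure. Binary variables
enter as their 0/1 coding (rank-based, equivalent to a rank-biserial
association up to sign), so one uniform machinery covers every cell.
"""

from __future__ import annotations

import itertools
import logging

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats.multitest import multipletests

logger = logging.getLogger(__name__)

FDR_ALPHA = 0.05

# Default variable sets for the two association matrices.
VOLUMETRIC_VARIABLES = (
    "mirv_max_distance",
    "mirv_max_dissimilarity",
    "tsrc",
    "response_range",
    "baseline_range",
    "baseline_sd",
    "baseline_total",
)
LIQUID_BIOPSY_VARIABLES = (
    "mirv_max_distance",
    "mirv_max_dissimilarity",
    "ctdna_pre",
    "ctdna_post",
    "baseline_range",
    "baseline_sd",
    "baseline_total",
)


def spearman(x, y) -> tuple[float, float]:
    """Spearman rho (average ranks for ties) and its two-sided p-value.

    A constant input has no rank ordering: returns (nan, nan) so callers
    can exclude the pair from an FDR family.
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.shape != y.shape:
        raise ValueError("inputs must have equal length")
    if len(x) < 3:
        raise ValueError("spearman needs >= 3 observations")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return float("nan"), float("nan")
    res = stats.spearmanr(x, y)
    return float(res.statistic), float(res.pvalue)


def fdr_adjust(pvals) -> np.ndarray:
    """Benjamini–Hochberg step-up q-values, in input order."""
    p = np.asarray(list(pvals), dtype=float)
    if len(p) == 0:
        return p
    if np.any((p < 0) | (p > 1)) or np.any(np.isnan(p)):
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def association_matrix(
    variables: pd.DataFrame, alpha: float = FDR_ALPHA
) -> pd.DataFrame:
    """Test every unordered pair of columns; one FDR family per call.

    Pairwise-complete observations are used per cell; pairs with fewer
    than 3 complete observations or an undefined (constant-input) rho are
    reported with NaN statistics and excluded from the FDR family. The
    ``significant`` flag mirrors the display rule: a cell is shown only
    when its q-value is <= ``alpha``.
    """
    cols = list(variables.columns)
    if len(cols) < 2:
        raise ValueError("need >= 2 variables")
    rows = []
    for a, b in itertools.combinations(cols, 2):
        sub = variables[[a, b]].dropna()
        if len(sub) < 3:
            rho, p = float("nan"), float("nan")
        else:
            rho, p = spearman(sub[a], sub[b])
        rows.append({"var_a": a, "var_b": b, "rho": rho, "p": p, "n": len(sub)})
    out = pd.DataFrame(rows)
    testable = out["p"].notna()
    if not testable.any():
        raise ValueError("no testable variable pair (all constant or too few rows)")
    q = np.full(len(out), np.nan)
    q[testable.to_numpy()] = fdr_adjust(out.loc[testable, "p"])
    out["q"] = q
    out["significant"] = (out["q"] <= alpha).fillna(False)
    return out


def assemble_volumetric_variables(
    mirv_table: pd.DataFrame, response_table: pd.DataFrame
) -> pd.DataFrame:
    """Join heterogeneity scores with the volumetric-response subset."""
    merged = mirv_table.merge(response_table, on="patient_id", how="inner")
    if merged.empty:
        raise ValueError("volumetric subset is empty")
    return merged[[c for c in VOLUMETRIC_VARIABLES if c in merged.columns]]


def assemble_liquid_biopsy_variables(
    mirv_table: pd.DataFrame,
    response_table: pd.DataFrame,
    clinical_df: pd.DataFrame,
) -> pd.DataFrame:
    """Join heterogeneity scores, baseline-volume controls and ctDNA labels."""
    if not {"ctdna_pre", "ctdna_post"} & set(clinical_df.columns):
        raise ValueError("clinical table has no ctDNA columns")
    merged = mirv_table.merge(response_table, on="patient_id", how="inner").merge(
        clinical_df, on="patient_id", how="inner"
    )
    merged = merged[merged[["ctdna_pre", "ctdna_post"]].notna().any(axis=1)]
    if merged.empty:
        raise ValueError("liquid-biopsy subset is empty")
    return merged[[c for c in LIQUID_BIOPSY_VARIABLES if c in merged.columns]]
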