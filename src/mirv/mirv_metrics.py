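"""Per-patient intertumor heterogeneity scores (MIRV).

MIRV (Measured Intrapatient Radiomic Variability) summarises how different
a patient's metastatic lesions look in reduced radiomic feature space. For
each patient all C(n, 2) unordered lesion pairs are compared and the most
divergent pair reported under two complementary metrics:

    max Distance       = max over pairs of the Euclidean distance
    max Dissimilarity  = max over pairs of 1 − cosine similarity

Euclidean distance responds to both magnitude and direction of feature
differences; cosine dissimilarity only to direction (feature *pattern*),
making it insensitive to overall feature magnitude. Features are z-scored
cohort-wide by default so no single raw-scale feature dominates the
Euclidean metric; this can be disabled.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.spatial.distance import pdist, squareform

logger = logging.getLogger(__name__)


class ZeroVarianceError(ValueError):
    """A feature column is constant and cannot be standardized."""


class ZeroNormError(ValueError):
    """A lesion vector has zero norm; cosine direction is undefined."""


@dataclass
class MIRVResult:
    patient_id: str
    mirv_max_distance: float
    mirv_max_dissimilarity: float
    n_lesions: int
    argmax_pair_distance: tuple[str, str]
    argmax_pair_dissimilarity: tuple[str, str]


def standardize(M: pd.DataFrame) -> pd.DataFrame:
    """Z-score every feature column over all lesions (mean 0, sample sd 1)."""
    if len(M) < 2:
        raise ValueError("standardize needs >= 2 rows")
    sd = M.std(ddof=1)
    zero = sd[sd == 0]
    if len(zero):
        raise ZeroVarianceError(f"zero-variance column(s): {list(zero.index)}")
    return (M - M.mean()) / sd


def euclidean_distance(u, v) -> float:
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    return float(np.sqrt(np.sum((u - v) ** 2)))


def cosine_dissimilarity(u, v) -> float:
    """1 − cosine similarity, in [0, 2]; invariant to positive rescaling."""
    u = np.asarray(u, dtype=float)
    v = np.asarray(v, dtype=float)
    if u.shape != v.shape:
        raise ValueError(f"length mismatch: {u.shape} vs {v.shape}")
    nu, nv = np.linalg.norm(u), np.linalg.norm(v)
    if nu == 0 or nv == 0:
        raise ZeroNormError("cosine dissimilarity undefined for zero-norm vector")
    return float(1.0 - np.dot(u, v) / (nu * nv))


def _argmax_pair(
    D: np.ndarray, lesion_ids: list[str]
) -> tuple[float, tuple[str, str]]:
    """Max off-diagonal entry with ties broken by lexicographically smallest
    (sorted) lesion-id pair."""
    best_val = -np.inf
    best_pair = None
    order = sorted(range(len(lesion_ids)), key=lambda i: lesion_ids[i])
    for a in range(len(order)):
        for b in range(a + 1, len(order)):
            i, j = order[a], order[b]
            if D[i, j] > best_val:
                best_val = D[i, j]
                best_pair = (lesion_ids[i], lesion_ids[j])
    return float(best_val), best_pair


def patient_mirv(M_patient: pd.DataFrame, patient_id: str | None = None) -> MIRVResult:
    """Score one patient from their lesions × features sub-matrix.

    Rows must be indexed by (patient_id, lesion_id) or by lesion_id alone.
    Requires >= 2 lesions; evaluates both metrics over every unordered pair.
    """
    if len(M_patient) < 2:
        raise ValueError("MIRV undefined for fewer than 2 lesions")
    if isinstance(M_patient.index, pd.MultiIndex):
        if patient_id is None:
            patient_id = str(M_patient.index[0][0])
        lesion_ids = [str(i[1]) for i in M_patient.index]
    else:
        if patient_id is None:
            patient_id = ""
        lesion_ids = [str(i) for i in M_patient.index]

    X = M_patient.to_numpy(dtype=float)
    norms = np.linalg.norm(X, axis=1)
    if (norms == 0).any():
        bad = lesion_ids[int(np.argmin(norms))]
        raise ZeroNormError(f"lesion {bad!r} has zero-norm feature vector")

    D_euc = squareform(pdist(X, metric="euclidean"))
    D_cos = squareform(pdist(X, metric="cosine"))
    max_d, pair_d = _argmax_pair(D_euc, lesion_ids)
    max_c, pair_c = _argmax_pair(D_cos, lesion_ids)
    # floating-point guard: cosine dissimilarity lives in [0, 2]
    max_c = float(np.clip(max_c, 0.0, 2.0))
    return MIRVResult(
        patient_id=patient_id,
        mirv_max_distance=max_d,
        mirv_max_dissimilarity=max_c,
        n_lesions=len(M_patient),
        argmax_pair_distance=pair_d,
        argmax_pair_dissimilarity=pair_c,
    )


def cohort_mirv(
    M: pd.DataFrame, apply_standardize: bool = True, strict: bool = False
) -> pd.DataFrame:
    """Score every patient with >= 2 lesions.

    ``M`` is the reduced feature matrix indexed by (patient_id, lesion_id).
    Single-lesion patients are skipped with a warning (or rejected when
    ``strict``). Returns one row per qualifying patient.
    """
    if not isinstance(M.index, pd.MultiIndex):
        raise ValueError("matrix must be indexed by (patient_id, lesion_id)")
    Z = standardize(M) if apply_standardize else M
    rows = []
    for pid in dict.fromkeys(Z.index.get_level_values(0)):
        sub = Z.loc[[pid]]
        if len(sub) < 2:
            if strict:
                raise ValueError(f"patient {pid!r} has < 2 lesions")
            logger.warning("patient %r has < 2 lesions; skipped", pid)
            continue
        r = patient_mirv(sub, patient_id=str(pid))
        rows.append(
            {
                "patient_id": r.patient_id,
                "n_lesions": r.n_lesions,
                "mirv_max_distance": r.mirv_max_distance,
                "mirv_max_dissimilarity": r.mirv_max_dissimilarity,
                "argmax_pair_distance": "|".join(r.argmax_pair_distance),
                "argmax_pair_dissimilarity": "|".join(r.argmax_pair_dissimilarity),
            }
        )
    if not rows:
        raise ValueError("no patient has >= 2 lesions; MIRV undefined for cohort")
    return pd.DataFrame(rows)
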