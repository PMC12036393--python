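import numpy as np
import pandas as pd
import pytest

from mirv import SyntheticConfig, generate_cohort


@pytest.fixture(scope="session")
def default_cohort():
    """One mid-size synthetic cohort shared by read-only tests."""
    return generate_cohort(SyntheticConfig(n_patients=80), seed=42)


@pytest.fixture
def toy_lesion_csv(tmp_path):
    """2 patients x 2 lesions x 3 features, exact decimal values."""
    path = tmp_path / "lesions.csv"
    path.write_text(
        "patient_id,lesion_id,baseline_volume_mm3,followup_volume_mm3,f1,f2,f3\n"
        "A,L1,100.0,50.0,1.5,2.25,3.125\n"
        "A,L2,200.0,210.0,0.5,1.75,2.5\n"
        "B,L1,300.0,100.0,2.5,0.25,1.125\n"
        "B,L2,400.0,500.0,3.5,1.25,0.5\n"
    )
    return path


@pytest.fixture
def toy_clinical_csv(tmp_path):
    path = tmp_path / "clinical.csv"
    path.write_text(
        "patient_id,os_time_years,os_event,histology,age,performance_status,recist\n"
        "A,1.5,1,Leiomyosarcoma,60.0,1,SD\n"
        "B,2.25,0,Other,55.0,0,PR\n"
    )
    return path


def brute_force_mirv(X: np.ndarray):
    """Independent exhaustive pair scan: plain double loop, textbook formulas."""
    n = X.shape[0]
    best_d, best_c = -np.inf, -np.inf
    for i in range(n):
        for j in range(i + 1, n):
            u, v = X[i], X[j]
            d = 0.0
            for k in range(len(u)):
                d += (u[k] - v[k]) ** 2
            d = d**0.5
            dot = sum(u[k] * v[k] for k in range(len(u)))
            nu = sum(x * x for x in u) ** 0.5
            nv = sum(x * x for x in v) ** 0.5
            c = 1.0 - dot / (nu * nv)
            best_d = max(best_d, d)
            best_c = max(best_c, c)
    return best_d, best_c


def stepup_bh(p: np.ndarray) -> np.ndarray:
    """Direct Benjamini-Hochberg step-up: q_(i) = min_{j>=i} m p_(j) / j."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    q_sorted = np.empty(m)
    running = np.inf
    for rank in range(m, 0, -1):
        running = min(running, m * p[order[rank - 1]] / rank)
        q_sorted[rank - 1] = min(running, 1.0)
    q = np.empty(m)
    q[order] = q_sorted
    return q


def cox_partial_loglik(beta: float, times, events, x) -> float:
    """Plain-numpy log partial likelihood for a single covariate, no ties."""
    times = np.asarray(times, float)
    events = np.asarray(events, int)
    x = np.asarray(x, float)
    ll = 0.0
    for i in np.where(events == 1)[0]:
        risk = times >= times[i]
        ll += beta * x[i] - np.log(np.sum(np.exp(beta * x[risk])))
    return ll
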