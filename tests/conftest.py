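import numpy as np
import pandas as pd
import pytest
from hypothesis import settings, HealthCheck

from gestval import CohortConfig, generate_cohort

settings.register_profile(
    "ci",
    derandomize=True,
    max_examples=60,
    deadline=None,
    suppress_health_check=[HealthCheck.too_slow],
)
settings.load_profile("ci")


def auroc_brute(scores, labels):
    """All-pairs AUROC oracle: ties between a case and a control credit 1/2."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = (pos[:, None] > neg[None, :]).sum() + 0.5 * (pos[:, None] == neg[None, :]).sum()
    return wins / (len(pos) * len(neg))


def km_brute(times, events, t):
    """Risk-set recomputation oracle for the product-limit estimator.

    At each death time t_i <= t: n_i = #{follow-up >= t_i} (deaths
    processed before censorings at ties), d_i = deaths at t_i.
    """
    times = np.asarray(times, dtype=float)
    events = np.asarray(events, dtype=int)
    s = 1.0
    for ti in sorted(set(times[events == 1])):
        if ti > t:
            break
        n_i = np.sum(times >= ti)
        d_i = np.sum((times == ti) & (events == 1))
        s *= 1.0 - d_i / n_i
    return s


@pytest.fixture(scope="session")
def small_cohort():
    """~550 encounters; enough for structural checks, fast to build."""
    return generate_cohort(CohortConfig(n_patients=300, seed=11))


@pytest.fixture(scope="session")
def single_visit_cohort():
    """One visit per patient: encounter covariates equal patient anchors."""
    return generate_cohort(
        CohortConfig(n_patients=6000, seed=5, visits_per_patient_mean=1.0,
                     missingness_rates={})
    )
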