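import numpy as np
import pytest

from dshrisk.ehr_data import (
    ClinicalEvent,
    Demographics,
    Followup,
    PatientTimeline,
    load_conditions,
)
from dshrisk.synth import SimulationConfig, simulate_cohort


@pytest.fixture(scope="session")
def config():
    return load_conditions()


def ev(age, kind, code, value=None, unit=None, dose=None, pid="p1"):
    return ClinicalEvent(pid, age, kind, code, value, unit, dose)


def make_timeline(
    events=(),
    pid="p1",
    age_at_index=50.0,
    entry=56.0,
    exit_age=60.0,
    acm=0,
    mce=0,
    sex="F",
    race="white",
):
    return PatientTimeline(
        demographics=Demographics(pid, sex, race, age_at_index),
        events=list(events),
        followup=Followup(entry, exit_age, acm, mce),
    )


@pytest.fixture(scope="session")
def small_cohort():
    """Shared 300-patient synthetic cohort with ground truth."""
    return simulate_cohort(SimulationConfig(n_patients=300, seed=5))


def brute_force_partial_loglik(eta, entry, exit_, event):
    """Enumerated Breslow partial log-likelihood with delayed entry."""
    ll = 0.0
    n = len(eta)
    for i in range(n):
        if event[i]:
            t = exit_[i]
            denom = sum(np.exp(eta[j]) for j in range(n) if entry[j] < t <= exit_[j])
            ll += eta[i] - np.log(denom)
    return ll


def brute_force_auc(risks, pos, neg, w):
    """Pairwise comparable-pair AUC with weights; ties count one half."""
    num = den = 0.0
    for i in np.flatnonzero(pos):
        for j in np.flatnonzero(neg):
            wij = w[i] * w[j]
            den += wij
            if risks[i] > risks[j]:
                num += wij
            elif risks[i] == risks[j]:
                num += 0.5 * wij
    return num / den
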