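"""Shared fixtures: generated datasets, validated panels, and one MLE fit.

Session-scoped so the expensive pieces (generation at n=2000, one full
maximum-likelihood fit) run once for the whole suite.
"""

import datetime

import numpy as np
import pytest

from healthspan import (GeneratorConfig, Gender, HealthState, SubjectPanel,
                        Vital, WaveObservation, build_panels, fit_mle, generate)

#: Frozen seed for every fixture that needs one.
SEED = 1234


@pytest.fixture(scope="session")
def default_dataset():
    return generate(GeneratorConfig(n_subjects=2000, seed=SEED))


@pytest.fixture(scope="session")
def default_panels(default_dataset):
    return build_panels(default_dataset.frame)


@pytest.fixture(scope="session")
def default_fit(default_panels):
    fit = fit_mle(default_panels)
    assert fit.converged
    return fit


@pytest.fixture(scope="session")
def gender_Q(default_dataset):
    """True intensity matrices of the generator, one per gender."""
    from healthspan.msm import build_Q
    model = default_dataset.config.intensity_model()
    return {g: build_Q(model, (float(g),)) for g in Gender}


def make_panel(subject_id, gender, waypoints, entry_age=60.0):
    """Build a SubjectPanel from (date, state) waypoints.

    A DEAD waypoint's date is used as both ascertainment and death date.
    """
    obs = []
    t0 = waypoints[0][0]
    for date, state in waypoints:
        state = HealthState(state)
        years = (date - t0).days / 365.25
        if state is HealthState.DEAD:
            obs.append(WaveObservation(
                subject_id=subject_id, gender=gender, interview_date=date,
                age_years=entry_age + years, vital=Vital.DEAD,
                death_date=date, state=state))
        else:
            badl = 1 if state is HealthState.BADL else 0
            iadl = 1 if state is HealthState.IADL else 0
            obs.append(WaveObservation(
                subject_id=subject_id, gender=gender, interview_date=date,
                age_years=entry_age + years, vital=Vital.ALIVE,
                badl_limited=badl, iadl_limited=iadl, state=state))
    panel = SubjectPanel(subject_id=subject_id, gender=gender,
                         observations=obs, entry_age=entry_age)
    panel.validate()
    return panel


def expm_series(M, terms=60):
    """Independent truncated-Taylor-series matrix exponential oracle.

    Large-norm arguments are halved (scaling and squaring) until the series
    is well conditioned; the alternating terms of a raw series at norm ~20
    would otherwise lose ~1e-9 to rounding.
    """
    M = np.asarray(M, dtype=float)
    n_half = 0
    while np.linalg.norm(M, 1) > 0.5:
        M = M / 2.0
        n_half += 1
    out = np.eye(M.shape[0])
    term = np.eye(M.shape[0])
    for k in range(1, terms + 1):
        term = term @ M / k
        out = out + term
    for _ in range(n_half):
        out = out @ out
    return out


#: Independent transcription of the allowed-transition order (origin-major).
ORACLE_TRANSITIONS = ((1, 2), (1, 3), (1, 4), (2, 1), (2, 3), (2, 4),
                      (3, 1), (3, 2), (3, 4))


def per_pair_loglik_oracle(panels, log_q0, gender_beta):
    """Panel log-likelihood recomputed pair by pair with the series expm.

    Entirely independent of the package's likelihood path: intensity
    matrices are assembled here from the parameter vectors, interval lengths
    recomputed from dates, and the matrix exponential comes from
    :func:`expm_series`.
    """
    total = 0.0
    for p in panels:
        origin = p.observations[0].interview_date
        rates = np.exp(np.asarray(log_q0)
                       + np.asarray(gender_beta) * float(p.gender))
        Q = np.zeros((4, 4))
        for (a, b), q in zip(ORACLE_TRANSITIONS, rates):
            Q[a - 1, b - 1] = q
        Q[np.arange(4), np.arange(4)] = -Q.sum(axis=1)
        times = [((o.death_date if o.state is HealthState.DEAD
                   else o.interview_date) - origin).days / 365.25
                 for o in p.observations]
        for i in range(len(times) - 1):
            dt = max(times[i + 1] - times[i], 0.5 / 365.25)
            P = expm_series(Q * dt)
            a = int(p.observations[i].state) - 1
            b = int(p.observations[i + 1].state) - 1
            if p.observations[i + 1].state is HealthState.DEAD:
                total += np.log(P[a, :3] @ Q[:3, 3])
            else:
                total += np.log(P[a, b])
    return total


@pytest.fixture
def rng():
    return np.random.default_rng(SEED)
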