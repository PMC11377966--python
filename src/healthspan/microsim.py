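"""Stochastic microsimulation of health-state trajectories and life tables.

The workflow mirrors stochastic population analysis of complex events: a
per-origin-state multinomial next-state model (destination probabilities in
age and gender over one cycle, default two years) is estimated from observed
consecutive interview pairs, a cohort of individuals (default 100 000) is
simulated from age 50 to 90 in cycles, and average person-years in each live
state give total and state-specific temporary life expectancy on
[start_age, max_age].

Two model inputs are accepted by :func:`simulate_cohort`:

* a :class:`DiscreteTransitionModel` — simulated in discrete cycles, with the
  standard half-cycle credit in the origin state for the cycle of death;
* a 4x4 intensity matrix Q — simulated as an exact event-driven
  continuous-time chain with exact person-years, so that results converge to
  the analytic temporary expectancies ``int_0^T expm(Qu)[s, live] du`` with
  no discretisation bias.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
import statsmodels.api as sm

from .states import Gender, HealthState, LIVE_STATES, SubjectPanel, ValidationError

logger = logging.getLogger(__name__)

__all__ = [
    "DiscreteTransitionModel",
    "SimConfig",
    "Occupancy",
    "fit_discrete_model",
    "simulate_cohort",
    "life_expectancy",
    "conditional_le_by_age",
    "gender_gap",
    "baseline_state_mix",
]

_STATE_NAMES = {1: "ROBUST", 2: "IADL", 3: "BADL", 4: "DEAD"}


def _design_row(age: float, gender: float, quadratic: bool) -> np.ndarray:
    x = (age - 70.0) / 10.0
    cols = [1.0, x] + ([x * x] if quadratic else []) + [gender]
    return np.asarray(cols)


@dataclass
class DiscreteTransitionModel:
    """Per-origin multinomial next-state model over one simulation cycle.

    For each live origin state the destination (stay, or move to any other
    state including death) follows a multinomial logit with linear predictor
    ``intercept + b_age * (age-70)/10 + b_age2 * ((age-70)/10)^2 +
    b_gender * gender``; staying in the origin state is the reference
    destination.  Destinations never observed from an origin carry
    probability zero.
    """

    cycle_years: float = 2.0
    quadratic_age: bool = True
    #: origin state -> (destination codes incl. origin first, coef matrix
    #: of shape (n_dest - 1, n_features) for the non-reference destinations)
    blocks: dict = field(default_factory=dict)
    #: origin state -> standard errors, same shape as coefs (diagnostics)
    se_blocks: dict = field(default_factory=dict)

    def destination_probs(self, origin: HealthState, age: float,
                          gender: float) -> np.ndarray:
        """Probability vector over the four destination states."""
        origin = HealthState(origin)
        dests, coefs = self.blocks[origin]
        x = _design_row(age, gender, self.quadratic_age)
        logits = np.concatenate([[0.0], coefs @ x])
        logits -= logits.max()
        w = np.exp(logits)
        w /= w.sum()
        out = np.zeros(4)
        for d, p in zip(dests, w):
            out[int(d) - 1] = p
        return out


def fit_discrete_model(panels: list[SubjectPanel], cycle_years: float = 2.0,
                       quadratic_age: bool = True,
                       min_pairs: int = 30) -> DiscreteTransitionModel:
    """Fit the per-origin multinomial next-state models from panel pairs.

    Consecutive observation pairs are kept when their length is within 25%
    of one cycle (pairs spanning a different number of cycles are excluded
    and counted); covariates are age at the interval start (centred at 70,
    per decade, optional quadratic) and gender.  Death is a destination like
    any other.  An origin state with fewer than ``min_pairs`` usable pairs
    raises, naming the state.
    """
    records = {s: [] for s in LIVE_STATES}
    n_excluded = 0
    for p in panels:
        obs = p.observations
        origin_date = obs[0].interview_date
        for a, b in zip(obs, obs[1:]):
            t_a = (a.interview_date - origin_date).days / 365.25
            dt = (b.interview_date - a.interview_date).days / 365.25
            if not (0.75 * cycle_years <= dt <= 1.25 * cycle_years):
                n_excluded += 1
                continue
            age_start = p.entry_age + t_a
            records[a.state].append(
                (age_start, float(p.gender), int(b.state)))
    if n_excluded:
        logger.info("fit_discrete_model: %d pairs excluded (span != 1 cycle)",
                    n_excluded)

    for origin in LIVE_STATES:
        if len(records[origin]) < min_pairs:
            raise ValidationError(
                f"origin state {origin.name} has only {len(records[origin])} "
                f"usable pairs (<{min_pairs}); enlarge the input data")

    model = DiscreteTransitionModel(cycle_years=cycle_years,
                                    quadratic_age=quadratic_age)
    for origin in LIVE_STATES:
        rows = records[origin]
        ages = np.array([r[0] for r in rows])
        genders = np.array([r[1] for r in rows])
        dests = np.array([r[2] for r in rows])
        observed = [int(origin)] + sorted(set(int(d) for d in dests)
                                          - {int(origin)})
        code = {d: k for k, d in enumerate(observed)}
        y = np.array([code[int(d)] for d in dests])
        X = np.stack([_design_row(a, g, quadratic_age)
                      for a, g in zip(ages, genders)])
        if len(observed) == 1:          # no movement ever observed
            model.blocks[origin] = (observed, np.zeros((0, X.shape[1])))
            model.se_blocks[origin] = np.zeros((0, X.shape[1]))
            continue
        fit = sm.MNLogit(y, X).fit(method="bfgs", maxiter=500, disp=0)
        coefs = fit.params.T            # (n_dest - 1, n_features)
        model.blocks[origin] = (observed, np.asarray(coefs))
        model.se_blocks[origin] = np.asarray(fit.bse).T
    return model


@dataclass
class SimConfig:
    """Microsimulation settings (defaults: 100 000 lives, ages 50 to 90,
    two-year cycles)."""

    n_individuals: int = 100_000
    start_age: float = 50.0
    max_age: float = 90.0
    cycle_years: float = 2.0
    #: probability vector over (ROBUST, IADL, BADL), or a mapping
    #: Gender -> vector for gender-specific baseline mixes.
    start_state_distribution: object = (1.0, 0.0, 0.0)
    gender: object = "both"          # Gender, or "both"
    seed: int = 0

    def __post_init__(self):
        if self.start_age >= self.max_age:
            raise ValidationError("start_age must be below max_age")
        n_cycles = (self.max_age - self.start_age) / self.cycle_years
        if abs(n_cycles - round(n_cycles)) > 1e-9:
            raise ValidationError(
                "(max_age - start_age) must be a whole number of cycles")

    @property
    def n_cycles(self) -> int:
        return int(round((self.max_age - self.start_age) / self.cycle_years))

    def state_probs(self, gender: Gender) -> np.ndarray:
        dist = self.start_state_distribution
        if isinstance(dist, dict):
            dist = dist[gender]
        v = np.asarray(dist, dtype=float)
        if v.shape != (3,) or abs(v.sum() - 1) > 1e-9 or v.min() < 0:
            raise ValidationError(
                "start_state_distribution must be a probability 3-vector")
        return v


@dataclass
class Occupancy:
    """Simulated cohort occupancy.

    ``states`` holds the state code at each cycle boundary (DEAD persists
    after death); ``person_years`` is present for exact continuous-time
    simulations and holds exact years per live state per individual.
    """

    states: np.ndarray               # (n, n_cycles + 1) int8
    genders: np.ndarray              # (n,) int8
    config: SimConfig
    person_years: np.ndarray | None = None   # (n, 3) exact years, optional


def _draw_categorical(rng, probs: np.ndarray, n: int) -> np.ndarray:
    """Vectorised draw of n indices from one probability vector."""
    return np.searchsorted(np.cumsum(probs), rng.random(n), side="right")


def simulate_cohort(model, config: SimConfig) -> Occupancy:
    """Simulate the cohort; dispatches on the model type.

    A :class:`DiscreteTransitionModel` advances in cycles, drawing each
    individual's destination from the multinomial at the current (age,
    gender).  A 4x4 intensity matrix is simulated exactly (event-driven),
    recording exact person-years; its cycle-boundary states are still
    reported for compatibility.
    """
    rng = np.random.default_rng(config.seed)
    n = config.n_individuals
    if config.gender == "both":
        genders = (rng.random(n) < 0.5).astype(np.int8)
    else:
        genders = np.full(n, int(Gender(config.gender)), dtype=np.int8)

    states0 = np.empty(n, dtype=np.int8)
    for g in (0, 1):
        mask = genders == g
        if mask.any():
            probs = config.state_probs(Gender(g))
            states0[mask] = _draw_categorical(rng, probs, int(mask.sum())) + 1

    if isinstance(model, DiscreteTransitionModel):
        return _simulate_discrete(model, config, rng, genders, states0)
    Q = np.asarray(model, dtype=float)
    if Q.shape != (4, 4):
        raise ValidationError("model must be a DiscreteTransitionModel or a "
                              "4x4 intensity matrix")
    return _simulate_ctmc(Q, config, rng, genders, states0)


def _simulate_discrete(model, config, rng, genders, states0) -> Occupancy:
    n, K = config.n_individuals, config.n_cycles
    grid = np.full((n, K + 1), int(HealthState.DEAD), dtype=np.int8)
    grid[:, 0] = states0
    for k in range(K):
        age = config.start_age + k * config.cycle_years
        cur = grid[:, k]
        nxt = cur.copy()
        for g in (0, 1):
            for origin in LIVE_STATES:
                mask = (cur == int(origin)) & (genders == g)
                m = int(mask.sum())
                if m == 0:
                    continue
                probs = model.destination_probs(origin, age, float(g))
                nxt[mask] = _draw_categorical(rng, probs, m) + 1
        grid[:, k + 1] = nxt
    return Occupancy(states=grid, genders=genders, config=config)


def _simulate_ctmc(Q, config, rng, genders, states0) -> Occupancy:
    """Exact event-driven CTMC simulation, vectorised over individuals."""
    n, K = config.n_individuals, config.n_cycles
    horizon = config.max_age - config.start_age
    grid = np.full((n, K + 1), int(HealthState.DEAD), dtype=np.int8)
    person_years = np.zeros((n, 3))
    boundaries = np.arange(K + 1) * config.cycle_years

    state = states0.astype(np.int64) - 1        # 0..2 live, 3 dead
    t_now = np.zeros(n)
    active = state < 3
    rates = -np.diag(Q)
    jump_probs = {s: None for s in range(3)}
    for s in range(3):
        row = np.maximum(Q[s].copy(), 0.0)
        row[s] = 0.0
        tot = row.sum()
        jump_probs[s] = row / tot if tot > 0 else None

    def _credit(idx, s_codes, t0, t1):
        np.add.at(person_years, (idx, s_codes), t1 - t0)
        # fill cycle-boundary grid for boundaries in [t0, t1)
        k0 = np.ceil((t0 - 1e-12) / config.cycle_years).astype(int)
        k1 = np.ceil((t1 - 1e-12) / config.cycle_years).astype(int)
        for k in range(K + 1):
            m = (k >= k0) & (k < k1)
            if m.any():
                grid[idx[m], k] = s_codes[m] + 1

    while active.any():
        idx = np.flatnonzero(active)
        s = state[idx]
        rate = rates[s]
        hold = np.where(rate > 0,
                        rng.exponential(1.0, size=len(idx)) / np.maximum(rate, 1e-300),
                        np.inf)
        t_next = t_now[idx] + hold
        reached_end = t_next >= horizon
        # censored at the horizon: credit to horizon, deactivate
        ce = idx[reached_end]
        if len(ce):
            _credit(ce, s[reached_end], t_now[ce],
                    np.full(len(ce), horizon))
            grid[ce, K] = s[reached_end] + 1
            active[ce] = False
        # jumps inside the horizon
        mv = idx[~reached_end]
        if len(mv):
            s_mv = s[~reached_end]
            t1 = t_next[~reached_end]
            _credit(mv, s_mv, t_now[mv], t1)
            u = rng.random(len(mv))
            new_state = np.empty(len(mv), dtype=np.int64)
            for sc in range(3):
                m = s_mv == sc
                if m.any():
                    cum = np.cumsum(jump_probs[sc])
                    new_state[m] = np.searchsorted(cum, u[m], side="right")
            state[mv] = new_state
            t_now[mv] = t1
            died = mv[new_state == 3]
            if len(died):
                # grid already DEAD-filled by default beyond last credit
                active[died] = False
    return Occupancy(states=grid, genders=genders, config=config,
                     person_years=person_years)


def _le_from_occupancy(occ: Occupancy, mask: np.ndarray) -> dict:
    cfg = occ.config
    n = int(mask.sum())
    if occ.person_years is not None:
        py = occ.person_years[mask].sum(axis=0)
    else:
        py = np.zeros(3)
        grid = occ.states[mask]
        for k in range(cfg.n_cycles):
            origin = grid[:, k]
            dest = grid[:, k + 1]
            for s in range(3):
                in_s = origin == s + 1
                full = in_s & (dest != int(HealthState.DEAD))
                half = in_s & (dest == int(HealthState.DEAD))
                py[s] += cfg.cycle_years * (full.sum() + 0.5 * half.sum())
    le = py / max(n, 1)
    return {
        "le_total": float(le.sum()),
        "le_robust": float(le[0]),
        "le_iadl": float(le[1]),
        "le_badl": float(le[2]),
        "n_effective": n,
    }


def life_expectancy(occ: Occupancy, config: SimConfig | None = None,
                    start_state: str = "mixture") -> pd.DataFrame:
    """Life-expectancy table from simulated occupancy.

    Person-years per state are cycles occupied times the cycle length, with
    a half-cycle credit in the origin state for the cycle of death (exact
    person-years are used when the simulation recorded them).  Rows are per
    gender present plus a pooled row when both genders were simulated.
    """
    cfg = config or occ.config
    rows = []
    present = sorted(set(occ.genders.tolist()))
    for g in present:
        rec = _le_from_occupancy(occ, occ.genders == g)
        rows.append({"gender": Gender(g).name.lower(),
                     "start_age": cfg.start_age, "start_state": start_state,
                     **rec})
    if len(present) > 1:
        rec = _le_from_occupancy(occ, np.ones(len(occ.genders), dtype=bool))
        rows.append({"gender": "both", "start_age": cfg.start_age,
                     "start_state": start_state, **rec})
    return pd.DataFrame(rows)


def conditional_le_by_age(model, config: SimConfig,
                          ages=(50.0, 60.0, 70.0, 80.0),
                          states=LIVE_STATES) -> pd.DataFrame:
    """LE conditional on being alive in a given state at a given age.

    Each (age, state) cell is a fresh simulation started there with a
    degenerate initial distribution; seeds are spawned deterministically
    from ``config.seed``.
    """
    frames = []
    ss = np.random.SeedSequence(config.seed)
    children = ss.spawn(len(ages) * len(states))
    k = 0
    for age in ages:
        if age >= config.max_age:
            raise ValidationError(f"start age {age} must be below max_age")
        for state in states:
            state = HealthState(state)
            if state is HealthState.DEAD:
                raise ValidationError("cannot condition on starting DEAD")
            dist = np.zeros(3)
            dist[int(state) - 1] = 1.0
            sub = replace(config, start_age=float(age),
                          start_state_distribution=tuple(dist),
                          seed=int(children[k].generate_state(1)[0] % (2**31)))
            k += 1
            occ = simulate_cohort(model, sub)
            frames.append(life_expectancy(occ, sub, start_state=state.name))
    return pd.concat(frames, ignore_index=True)


def gender_gap(le_women: pd.DataFrame, le_men: pd.DataFrame) -> pd.DataFrame:
    """Women-minus-men LE gaps (men as reference), per (age, state) cell.

    ``delta_disabled`` pools IADL and BADL years; by construction
    ``delta_total = delta_robust + delta_disabled``.
    """
    w = le_women[le_women["gender"] != "both"] if "gender" in le_women else le_women
    m = le_men[le_men["gender"] != "both"] if "gender" in le_men else le_men
    w = w[w["gender"] == "woman"] if (w["gender"] == "woman").any() else w
    m = m[m["gender"] == "man"] if (m["gender"] == "man").any() else m
    keys = ["start_age", "start_state"]
    wk = w.set_index(keys).sort_index()
    mk = m.set_index(keys).sort_index()
    if not wk.index.equals(mk.index):
        raise ValidationError("LE tables are on different (age, state) grids")
    rows = []
    for key in wk.index:
        rw, rm = wk.loc[key], mk.loc[key]
        d_total = rw["le_total"] - rm["le_total"]
        d_rob = rw["le_robust"] - rm["le_robust"]
        d_dis = ((rw["le_iadl"] + rw["le_badl"])
                 - (rm["le_iadl"] + rm["le_badl"]))
        rows.append({"start_age": key[0], "start_state": key[1],
                     "delta_total": float(d_total),
                     "delta_robust": float(d_rob),
                     "delta_disabled": float(d_dis)})
    return pd.DataFrame(rows)


def baseline_state_mix(panels: list[SubjectPanel]) -> dict:
    """Gender-specific baseline live-state distribution of a panel set."""
    out = {}
    for g in Gender:
        counts = np.zeros(3)
        for p in panels:
            if p.gender is g:
                s = int(p.observations[0].state)
                if s <= 3:
                    counts[s - 1] += 1
        total = counts.sum()
        out[g] = tuple(counts / total) if total else (1.0, 0.0, 0.0)
    return out
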