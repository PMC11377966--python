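"""Continuous-time multi-state Markov model for interval-censored panel data.

The model: four states (robust, IADL-disabled, BADL-disabled, dead) with a
time-homogeneous intensity matrix Q whose allowed off-diagonal entries follow
a proportional-hazards form in subject covariates z,

    q_rs(z) = exp(log_q0_rs + beta_rs . z),

dead being absorbing.  Live states are observed only at interview times
(panel observation), so the likelihood of moving from state r at one
interview to state s at the next, dt years later, is the (r, s) entry of the
matrix exponential P(dt) = expm(Q dt).  Death times are treated as known to
the day (recorded or midpoint-imputed), contributing the exact-death density

    sum_{r in live} P(dt)[from, r] * q_{r, dead},

the penultimate living state being unobserved.  Maximisation is by BFGS on
the unconstrained log-intensity scale with complex-step (machine-precision)
gradients; the covariance of the estimates is the inverse observed
information from a central finite difference of that gradient.  Wald
intervals for hazard ratios assume normality of the log effect.
"""

from __future__ import annotations

import json
import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import scipy.linalg
import scipy.optimize
import scipy.stats

from .states import (Gender, HealthState, LIVE_STATES, SubjectPanel,
                     ValidationError)

logger = logging.getLogger(__name__)

__all__ = [
    "DEFAULT_TRANSITIONS",
    "TransitionStructure",
    "IntensityModel",
    "FitResult",
    "build_Q",
    "transition_probability",
    "interval_loglik",
    "exact_death_loglik",
    "panel_loglik",
    "fit_mle",
    "wald_hr",
    "horizon_probability_table",
]

_R, _I, _B, _D = (HealthState.ROBUST, HealthState.IADL,
                  HealthState.BADL, HealthState.DEAD)

#: Canonical transition order: by origin, then destination.
DEFAULT_TRANSITIONS: tuple[tuple[HealthState, HealthState], ...] = (
    (_R, _I), (_R, _B), (_R, _D),
    (_I, _R), (_I, _B), (_I, _D),
    (_B, _R), (_B, _I), (_B, _D),
)

#: Floor rate (per year) for crude initialisation and dropped transitions.
RATE_FLOOR = 1e-4

_MIN_DT_YEARS = 0.5 / 365.25  # tie-break for same-day interview and death


@dataclass(frozen=True)
class TransitionStructure:
    """Set of allowed instantaneous transitions among the four states."""

    transitions: tuple[tuple[HealthState, HealthState], ...] = DEFAULT_TRANSITIONS

    def __post_init__(self):
        outgoing = {s: 0 for s in LIVE_STATES}
        for frm, to in self.transitions:
            if frm is _D or frm == _D:
                raise ValidationError("DEAD cannot be a transition source")
            if frm == to:
                raise ValidationError("self-transitions are not intensities")
            outgoing[HealthState(frm)] += 1
        lacking = [s.name for s, k in outgoing.items() if k == 0]
        if lacking:
            raise ValidationError(
                f"live states without outgoing transitions: {lacking}")

    @property
    def n_transitions(self) -> int:
        return len(self.transitions)

    def labels(self) -> list[str]:
        return [f"{HealthState(a).name}->{HealthState(b).name}"
                for a, b in self.transitions]


@dataclass
class IntensityModel:
    """Proportional-hazards intensity model q_rs(z) = exp(log_q0 + beta.z)."""

    structure: TransitionStructure = field(default_factory=TransitionStructure)
    log_q0: np.ndarray = None
    beta: np.ndarray = None
    covariate_names: tuple[str, ...] = ("gender",)

    def __post_init__(self):
        nt = self.structure.n_transitions
        nc = len(self.covariate_names)
        if self.log_q0 is None:
            self.log_q0 = np.full(nt, np.log(0.05))
        self.log_q0 = np.asarray(self.log_q0, dtype=float)
        if self.beta is None:
            self.beta = np.zeros((nt, nc))
        self.beta = np.asarray(self.beta, dtype=float).reshape(nt, nc)
        if self.log_q0.shape != (nt,):
            raise ValidationError(f"log_q0 must have length {nt}")
        if not np.all(np.isfinite(self.log_q0)):
            raise ValidationError("log_q0 must be finite")


def build_Q(model: IntensityModel, covariates) -> np.ndarray:
    """Intensity matrix at a covariate vector (rows R, I, B, D; 1/year)."""
    z = np.atleast_1d(np.asarray(covariates, dtype=float))
    if z.shape != (len(model.covariate_names),):
        raise ValidationError(
            f"covariate vector length {z.shape} does not match "
            f"{model.covariate_names}")
    return _build_Q_raw(model.structure, model.log_q0 + model.beta @ z)


def _build_Q_raw(structure: TransitionStructure, log_rates: np.ndarray) -> np.ndarray:
    Q = np.zeros((4, 4), dtype=log_rates.dtype)
    rates = np.exp(log_rates)
    for (frm, to), q in zip(structure.transitions, rates):
        Q[int(frm) - 1, int(to) - 1] = q
    idx = np.arange(4)
    Q[idx, idx] -= Q.sum(axis=1)
    return Q


def transition_probability(Q: np.ndarray, t: float) -> np.ndarray:
    """Transition-probability matrix P(t) = expm(Q t)."""
    if t < 0:
        raise ValidationError(f"horizon t must be >= 0, got {t}")
    Q = np.asarray(Q, dtype=float)
    P = scipy.linalg.expm(Q * t)
    # expm of a proper intensity matrix is stochastic; clean rounding dust
    np.clip(P, 0.0, 1.0, out=P)
    P /= P.sum(axis=1, keepdims=True)
    return P


def _propagators(Q: np.ndarray, dts: np.ndarray) -> np.ndarray:
    """expm(Q * dt) for a batch of interval lengths, via eigendecomposition.

    Q is 4x4 and generically diagonalisable; P(dt) = V diag(exp(w dt)) V^-1
    is evaluated for the whole dt batch with two matmuls.  Falls back to
    stacked scipy expm if the eigenbasis is ill-conditioned.
    """
    w, V = np.linalg.eig(Q)
    if np.linalg.cond(V) < 1e10:
        E = np.exp(np.multiply.outer(dts, w))           # (m, 4)
        P = np.einsum("ij,mj,jk->mik", V, E, np.linalg.inv(V))
        if not np.iscomplexobj(Q):
            P = P.real
        return P
    return scipy.linalg.expm(Q[None, :, :] * dts[:, None, None])


def interval_loglik(from_state: HealthState, to_state: HealthState,
                    dt: float, Q: np.ndarray) -> float:
    """log P(dt)[from, to] for a live-to-live panel observation pair."""
    if dt <= 0:
        raise ValidationError(f"interval length must be > 0, got {dt}")
    P = transition_probability(Q, dt)
    p = P[int(from_state) - 1, int(to_state) - 1]
    if p <= 0:
        logger.warning("zero transition probability for observed %s -> %s",
                       HealthState(from_state).name, HealthState(to_state).name)
        return -np.inf
    return float(np.log(p))


def exact_death_loglik(from_state: HealthState, dt: float, Q: np.ndarray) -> float:
    """Log-density of dying exactly dt years after being observed in a state.

    The penultimate live state is unobserved, so the density sums, over live
    states r, the probability of occupying r just before death times the
    death intensity from r.
    """
    if dt <= 0:
        raise ValidationError(f"interval length must be > 0, got {dt}")
    Q = np.asarray(Q, dtype=float)
    qd = Q[:3, 3]
    if np.all(qd == 0):
        logger.warning("all death intensities are zero; observed death impossible")
        return -np.inf
    P = transition_probability(Q, dt)
    dens = float(P[int(from_state) - 1, :3] @ qd)
    return float(np.log(dens)) if dens > 0 else -np.inf


# ---------------------------------------------------------------------------
# Likelihood over panels


def _covariate_vector(panel: SubjectPanel, t_start: float,
                      covariate_names: tuple[str, ...]) -> tuple[float, ...]:
    vals = []
    for name in covariate_names:
        if name == "gender":
            vals.append(float(panel.gender))
        elif name == "age":
            # age at interval start, centred at 70, scaled by decade
            vals.append((panel.entry_age + t_start - 70.0) / 10.0)
        else:
            raise ValidationError(f"unknown covariate {name!r}")
    return tuple(vals)


class _IntervalData:
    """Consecutive observation pairs flattened for vectorised likelihood."""

    def __init__(self, panels: list[SubjectPanel],
                 covariate_names: tuple[str, ...]):
        frm, to, dt, death, zkey, sids = [], [], [], [], [], []
        for p in panels:
            if len(p.observations) < 2:
                raise ValidationError(
                    f"subject {p.subject_id}: need >=2 observations")
            origin = p.observations[0].interview_date
            times = []
            for o in p.observations:
                if o.state is HealthState.DEAD:
                    if o.death_date is None:
                        raise ValidationError(
                            f"subject {p.subject_id}: DEAD without a death date")
                    times.append((o.death_date - origin).days / 365.25)
                else:
                    times.append((o.interview_date - origin).days / 365.25)
            for i in range(len(times) - 1):
                a, b = p.observations[i], p.observations[i + 1]
                d = max(times[i + 1] - times[i], _MIN_DT_YEARS)
                frm.append(int(a.state) - 1)
                to.append(int(b.state) - 1)
                dt.append(d)
                death.append(b.state is HealthState.DEAD)
                zkey.append(_covariate_vector(p, times[i], covariate_names))
                sids.append(p.subject_id)
        self.frm = np.asarray(frm)
        self.to = np.asarray(to)
        self.dt = np.asarray(dt, dtype=float)
        self.death = np.asarray(death, dtype=bool)
        self.subject_ids = np.asarray(sids)
        self.n_subjects = len(panels)
        self.groups: list[tuple[np.ndarray, np.ndarray]] = []
        uniq = sorted(set(zkey))
        zarr = np.asarray(zkey, dtype=float)
        for z in uniq:
            mask = np.all(zarr == np.asarray(z), axis=1)
            self.groups.append((np.asarray(z, dtype=float), np.flatnonzero(mask)))

    def __len__(self):
        return len(self.dt)


def _loglik_terms(data: _IntervalData, structure: TransitionStructure,
                  log_q0, beta) -> np.ndarray:
    """Per-interval log-likelihood contributions (complex-safe)."""
    terms = np.zeros(len(data), dtype=log_q0.dtype)
    for z, idx in data.groups:
        Q = _build_Q_raw(structure, log_q0 + beta @ z)
        P = _propagators(Q, data.dt[idx])
        f, t = data.frm[idx], data.to[idx]
        is_death = data.death[idx]
        vals = np.empty(len(idx), dtype=log_q0.dtype)
        live = ~is_death
        p_live = P[live, f[live], t[live]]
        if not np.iscomplexobj(p_live):
            p_live = np.maximum(p_live, 1e-300)
        vals[live] = np.log(p_live)
        if np.any(is_death):
            dens = P[is_death, f[is_death], :3] @ Q[:3, 3]
            if not np.iscomplexobj(dens):
                dens = np.maximum(dens, 1e-300)
            vals[is_death] = np.log(dens)
        terms[idx] = vals
    return terms


def panel_loglik(panels: list[SubjectPanel], model: IntensityModel) -> float:
    """Total log-likelihood of the panels under an intensity model.

    Conditions on each subject's first observed state; each consecutive pair
    contributes a panel term (live target) or an exact-death term (DEAD
    target at its recorded or imputed date).  A non-finite total is reported
    with the offending subjects.
    """
    data = _IntervalData(panels, model.covariate_names)
    terms = _loglik_terms(data, model.structure, model.log_q0, model.beta)
    total = float(np.sum(terms))
    if not np.isfinite(total):
        bad = sorted(set(data.subject_ids[~np.isfinite(terms)]))
        logger.warning("non-finite log-likelihood from subjects %s", bad[:10])
    return total


# ---------------------------------------------------------------------------
# Maximum likelihood


@dataclass
class FitResult:
    """MLE output: estimates in canonical order (log_q0 block, then one beta
    block per covariate), covariance from inverse observed information."""

    structure: TransitionStructure
    covariate_names: tuple[str, ...]
    estimates: np.ndarray
    covariance: np.ndarray
    loglik: float
    converged: bool
    n_subjects: int
    n_transitions: int
    param_names: list[str]
    dropped: list[str] = field(default_factory=list)
    n_iter: int = 0
    grad_norm: float = float("nan")

    def to_intensity_model(self) -> IntensityModel:
        nt = self.structure.n_transitions
        nc = len(self.covariate_names)
        return IntensityModel(
            structure=self.structure,
            log_q0=self.estimates[:nt],
            beta=self.estimates[nt:nt + nt * nc].reshape(nc, nt).T,
            covariate_names=self.covariate_names,
        )

    def to_json(self, path=None) -> str:
        payload = {
            "transitions": self.structure.labels(),
            "covariate_names": list(self.covariate_names),
            "param_names": self.param_names,
            "estimates": self.estimates.tolist(),
            "covariance": self.covariance.tolist(),
            "loglik": self.loglik,
            "converged": self.converged,
            "n_subjects": self.n_subjects,
            "n_transitions": self.n_transitions,
            "dropped": self.dropped,
            "n_iter": self.n_iter,
            "grad_norm": self.grad_norm,
        }
        text = json.dumps(payload, indent=2)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "FitResult":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        name_to_state = {s.name: s for s in HealthState}
        transitions = tuple(
            (name_to_state[a], name_to_state[b])
            for a, b in (lbl.split("->") for lbl in payload["transitions"]))
        return cls(
            structure=TransitionStructure(transitions),
            covariate_names=tuple(payload["covariate_names"]),
            estimates=np.asarray(payload["estimates"], dtype=float),
            covariance=np.asarray(payload["covariance"], dtype=float),
            loglik=payload["loglik"],
            converged=payload["converged"],
            n_subjects=payload["n_subjects"],
            n_transitions=payload["n_transitions"],
            param_names=payload["param_names"],
            dropped=payload.get("dropped", []),
            n_iter=payload.get("n_iter", 0),
            grad_norm=payload.get("grad_norm", float("nan")),
        )


def _param_names(structure: TransitionStructure,
                 covariate_names: tuple[str, ...]) -> list[str]:
    labels = structure.labels()
    names = [f"log_q0[{lbl}]" for lbl in labels]
    for cov in covariate_names:
        names += [f"beta[{cov}][{lbl}]" for lbl in labels]
    return names


def _crude_rates(data: _IntervalData, structure: TransitionStructure) -> np.ndarray:
    """Observed r->s pair counts / person-years observed in r, floored."""
    counts = np.zeros((3, 4))
    exposure = np.zeros(3)
    for f, t, d in zip(data.frm, data.to, data.dt):
        exposure[f] += d
        if t != f:
            counts[f, t] += 1
    rates = np.full(structure.n_transitions, RATE_FLOOR)
    for k, (frm, to) in enumerate(structure.transitions):
        exp_f = exposure[int(frm) - 1]
        if exp_f > 0:
            rates[k] = max(counts[int(frm) - 1, int(to) - 1] / exp_f, RATE_FLOOR)
    return rates


def fit_mle(panels: list[SubjectPanel],
            structure: TransitionStructure | None = None,
            covariate_names: tuple[str, ...] = ("gender",),
            init="crude",
            tol: float = 1e-6,
            max_iter: int = 500) -> FitResult:
    """Maximum-likelihood fit of the proportional-intensity model.

    ``init="crude"`` starts each baseline intensity at the observed
    transition count divided by person-years at risk in the origin state
    (floored at 1e-4/yr) with all covariate effects at zero; an explicit
    parameter vector may be given instead.  Transitions never directly
    observed as a consecutive pair are unidentified: their parameters are
    fixed (rate at the floor, effects at zero), excluded from optimisation
    and listed in ``FitResult.dropped``.
    """
    structure = structure or TransitionStructure()
    covariate_names = tuple(covariate_names)
    nt = structure.n_transitions
    nc = len(covariate_names)
    npar = nt * (1 + nc)
    names = _param_names(structure, covariate_names)
    data = _IntervalData(panels, covariate_names)

    # identifiability: direct consecutive-pair count per allowed transition
    pair_counts = np.zeros(nt)
    for k, (frm, to) in enumerate(structure.transitions):
        pair_counts[k] = np.sum((data.frm == int(frm) - 1)
                                & (data.to == int(to) - 1))
    fixed_mask = np.zeros(npar, dtype=bool)
    dropped = []
    for k in np.flatnonzero(pair_counts == 0):
        dropped.append(structure.labels()[k])
        fixed_mask[k] = True
        for c in range(nc):
            fixed_mask[nt * (1 + c) + k] = True
    if dropped:
        logger.warning("unidentified transitions dropped from fit: %s", dropped)

    full0 = np.zeros(npar)
    if isinstance(init, str) and init == "crude":
        full0[:nt] = np.log(_crude_rates(data, structure))
    else:
        full0 = np.asarray(init, dtype=float).copy()
        if full0.shape != (npar,):
            raise ValidationError(f"init must have length {npar}")
    full0[:nt][pair_counts == 0] = np.log(RATE_FLOOR)

    free = ~fixed_mask
    fixed_values = full0.copy()

    def unpack(theta):
        full = fixed_values.astype(theta.dtype).copy() \
            if np.iscomplexobj(theta) else fixed_values.copy()
        full[free] = theta
        log_q0 = full[:nt]
        beta = full[nt:].reshape(nc, nt).T if nc else np.zeros((nt, 0))
        return log_q0, beta

    # Penalty wall keeping line searches out of the overflow region:
    # rates above e^8 ~ 3000 events/yr are far beyond plausibility.
    LOGRATE_CAP = 8.0

    def _wall(log_q0, beta):
        excess = 0.0
        for z, _ in data.groups:
            log_rates = log_q0 + (beta @ z if nc else 0.0)
            excess += float(np.sum(np.maximum(log_rates.real - LOGRATE_CAP, 0.0)))
        return excess

    def negloglik(theta):
        log_q0, beta = unpack(theta)
        excess = _wall(log_q0, beta)
        if excess > 0:
            return 1e6 * (1.0 + excess)
        return -np.sum(_loglik_terms(data, structure, log_q0, beta))

    # Complex-step size: not the usual 1e-20, because the eigensolver's
    # real-arithmetic rounding (~1e-15) leaks into the imaginary channel
    # near eigenvalue degeneracies; 1e-8 keeps the signal far above that
    # leakage while the O(h^2) truncation error stays at 1e-16.
    h_cs = 1e-8
    src = np.array([int(a) - 1 for a, _ in structure.transitions])
    dst = np.array([int(b) - 1 for _, b in structure.transitions])

    def _grad_slow(theta):
        g = np.empty(len(theta))
        base = theta.astype(complex)
        for j in range(len(theta)):
            pert = base.copy()
            pert[j] += 1j * h_cs
            g[j] = negloglik(pert).imag / h_cs
        return g

    def grad(theta):
        """Complex-step gradient of the negative log-likelihood.

        All free parameters are perturbed at once: the corresponding batch
        of perturbed intensity matrices is eigendecomposed together and the
        per-interval terms are contracted per parameter.  Machine-precision
        derivatives at roughly the cost of a few function evaluations.
        """
        log_q0, beta = unpack(theta)
        g = np.zeros(len(theta))
        in_wall = _wall(log_q0, beta) > 0
        for z, idx in data.groups:
            log_rates = log_q0 + (beta @ z if nc else 0.0)
            W_full = np.zeros((npar, nt))
            W_full[:nt] = np.eye(nt)
            for c in range(nc):
                W_full[nt * (1 + c):nt * (2 + c)] = z[c] * np.eye(nt)
            W = W_full[free]
            if in_wall:
                g += 1e6 * (W * (log_rates > LOGRATE_CAP)).sum(axis=1)
                continue
            L = log_rates[None, :] + 1j * h_cs * W          # (J, nt)
            Qb = np.zeros((len(W), 4, 4), dtype=complex)
            Qb[:, src, dst] = np.exp(L)
            diag = np.arange(4)
            Qb[:, diag, diag] -= Qb.sum(axis=2)
            weig, V = np.linalg.eig(Qb)
            if np.max(np.linalg.cond(V)) > 1e10:
                return _grad_slow(theta)
            Vinv = np.linalg.inv(V)
            dts, f, t = data.dt[idx], data.frm[idx], data.to[idx]
            death = data.death[idx]
            E = np.exp(weig[:, None, :] * dts[None, :, None])   # (J, m, 4)
            live = ~death
            totals = np.zeros(len(W), dtype=complex)
            if live.any():
                coeff = (V[:, f[live], :]
                         * np.transpose(Vinv, (0, 2, 1))[:, t[live], :])
                p = np.einsum("jmk,jmk->jm", coeff, E[:, live, :])
                totals += np.log(p).sum(axis=1)
            if death.any():
                qD = Qb[:, :3, 3]
                wk = np.einsum("jkr,jr->jk", Vinv[:, :, :3], qD)
                coeffD = V[:, f[death], :] * wk[:, None, :]
                dens = np.einsum("jmk,jmk->jm", coeffD, E[:, death, :])
                totals += np.log(dens).sum(axis=1)
            g -= totals.imag / h_cs
        return g

    theta0 = full0[free]
    res = scipy.optimize.minimize(
        negloglik, theta0, jac=grad, method="BFGS",
        options={"gtol": tol, "maxiter": max_iter})
    n_iter = int(res.nit)
    # a stalled line search leaves a stale curvature model; one fresh
    # restart from the best point usually finishes the job
    for _ in range(2):
        if res.success or np.max(np.abs(res.jac)) <= 10 * tol:
            break
        res = scipy.optimize.minimize(
            negloglik, res.x, jac=grad, method="BFGS",
            options={"gtol": tol, "maxiter": max_iter})
        n_iter += int(res.nit)
    theta_hat = res.x
    grad_norm = float(np.max(np.abs(res.jac)))
    # absolute gtol, or small relative to the objective's scale: the
    # attainable gradient floor after a line-search stall grows with the
    # likelihood magnitude, while a residual gradient g moves the optimum
    # by only ~H^-1 g, negligible against the standard errors here
    converged = bool(res.success) or grad_norm <= 10 * tol \
        or grad_norm <= tol * abs(float(res.fun))

    # observed information: central finite difference of the exact gradient
    nfree = len(theta_hat)
    H = np.zeros((nfree, nfree))
    for j in range(nfree):
        h = 1e-5 * max(1.0, abs(theta_hat[j]))
        up, dn = theta_hat.copy(), theta_hat.copy()
        up[j] += h
        dn[j] -= h
        H[:, j] = (grad(up) - grad(dn)) / (2 * h)
    H = 0.5 * (H + H.T)
    try:
        cov_free = np.linalg.inv(H)
    except np.linalg.LinAlgError:
        cov_free = np.linalg.pinv(H)
        converged = False
    if converged and np.any(np.linalg.eigvalsh(H) <= 0):
        logger.warning("observed information not positive definite")
        converged = False

    estimates = fixed_values.copy()
    estimates[free] = theta_hat
    covariance = np.full((npar, npar), np.nan)
    covariance[np.ix_(free, free)] = cov_free

    return FitResult(
        structure=structure, covariate_names=covariate_names,
        estimates=estimates, covariance=covariance,
        loglik=-float(res.fun), converged=converged,
        n_subjects=data.n_subjects, n_transitions=len(data),
        param_names=names, dropped=dropped,
        n_iter=n_iter, grad_norm=grad_norm)


def wald_hr(fit: FitResult, level: float = 0.95) -> pd.DataFrame:
    """Hazard-ratio table with Wald intervals on the log scale.

    One row per (transition, covariate): hr = exp(beta), CI =
    exp(beta -/+ z * SE) with SE from the covariance diagonal.
    """
    if not fit.converged:
        raise ValidationError("fit did not converge; refit before reporting HRs")
    nt = fit.structure.n_transitions
    var = np.diag(fit.covariance)
    free_var = var[~np.isnan(var)]
    if np.any(free_var < 0):
        raise ValidationError(
            "covariance is not positive semi-definite; refit the model")
    z = scipy.stats.norm.ppf(0.5 * (1 + level))
    rows = []
    labels = fit.structure.labels()
    for c, cov in enumerate(fit.covariate_names):
        for k, lbl in enumerate(labels):
            if lbl in fit.dropped:
                continue
            j = nt * (1 + c) + k
            b = fit.estimates[j]
            se = float(np.sqrt(var[j]))
            rows.append({
                "transition": lbl, "covariate": cov,
                "hr": float(np.exp(b)),
                "ci_low": float(np.exp(b - z * se)),
                "ci_high": float(np.exp(b + z * se)),
                "se_log": se,
            })
    return pd.DataFrame(rows)


def horizon_probability_table(fit: FitResult, covariates,
                              horizons=(10.0, 20.0, 30.0),
                              start_states=LIVE_STATES) -> pd.DataFrame:
    """Long-format multi-year transition probabilities at a covariate value.

    For each horizon t and live start state, the row of P(t) = expm(Q t)
    over the four end states — the layout of a per-horizon heat map.
    """
    if not fit.converged:
        raise ValidationError("fit did not converge; refit before tabulating")
    Q = build_Q(fit.to_intensity_model(), covariates)
    rows = []
    for t in horizons:
        P = transition_probability(Q, float(t))
        for s in start_states:
            s = HealthState(s)
            for e in HealthState:
                rows.append({
                    "start_state": s.name, "horizon": float(t),
                    "end_state": e.name,
                    "probability": float(P[int(s) - 1, int(e) - 1]),
                })
    return pd.DataFrame(rows)
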