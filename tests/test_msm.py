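"""Intensity matrices, matrix-exponential likelihood, MLE and HR reporting."""

import datetime

import numpy as np
import pytest

from healthspan import (Gender, HealthState, IntensityModel,
                        TransitionStructure, ValidationError, build_Q,
                        exact_death_loglik, fit_mle, horizon_probability_table,
                        interval_loglik, panel_loglik, transition_probability,
                        wald_hr)
from healthspan.msm import (DEFAULT_TRANSITIONS, FitResult, _IntervalData,
                            _crude_rates)

from conftest import expm_series, make_panel

D = datetime.date


def _random_Q(rng):
    """Valid random intensity matrix over the default 9-transition set."""
    model = IntensityModel(log_q0=rng.uniform(-4.0, -0.5, size=9),
                           beta=np.zeros((9, 1)))
    return build_Q(model, (0.0,))


class TestBuildQ:

    def test_zero_beta_reproduces_baseline(self, rng):
        log_q0 = rng.uniform(-4, -1, size=9)
        model = IntensityModel(log_q0=log_q0, beta=np.zeros((9, 1)))
        Q = build_Q(model, (1.0,))
        for k, (frm, to) in enumerate(DEFAULT_TRANSITIONS):
            assert Q[int(frm) - 1, int(to) - 1] == pytest.approx(np.exp(log_q0[k]))

    def test_gender_hazard_ratio_scales_intensity(self):
        hr = 1.392
        beta = np.zeros((9, 1))
        beta[0, 0] = np.log(hr)          # robust -> IADL effect
        model = IntensityModel(log_q0=np.full(9, np.log(0.05)), beta=beta)
        Q_men = build_Q(model, (0.0,))
        Q_women = build_Q(model, (1.0,))
        assert Q_women[0, 1] == pytest.approx(hr * Q_men[0, 1], rel=1e-12)

    def test_rows_sum_to_zero_and_dead_row_zero(self, rng):
        for _ in range(10):
            Q = _random_Q(rng)
            assert np.allclose(Q.sum(axis=1), 0.0, atol=1e-12)
            assert np.all(Q[3] == 0.0)
            off = Q[~np.eye(4, dtype=bool)]
            assert np.all(off >= 0)

    def test_covariate_length_mismatch_rejected(self):
        model = IntensityModel()
        with pytest.raises(ValidationError):
            build_Q(model, (0.0, 1.0))


class TestTransitionProbability:

    def test_zero_horizon_is_identity(self, rng):
        Q = _random_Q(rng)
        assert np.allclose(transition_probability(Q, 0.0), np.eye(4), atol=1e-14)

    def test_two_state_closed_form(self):
        lam = 0.1
        Q = np.zeros((4, 4))
        Q[0, 0], Q[0, 3] = -lam, lam
        P = transition_probability(Q, 10.0)
        assert P[0, 0] == pytest.approx(np.exp(-1.0), abs=1e-12)
        assert P[0, 3] == pytest.approx(1 - np.exp(-1.0), abs=1e-12)

    def test_matches_series_oracle(self, rng):
        Q = _random_Q(rng)
        P = transition_probability(Q, 2.0)
        assert np.max(np.abs(P - expm_series(Q * 2.0))) < 1e-9

    def test_negative_horizon_rejected(self, rng):
        with pytest.raises(ValidationError):
            transition_probability(_random_Q(rng), -1.0)

    def test_chapman_kolmogorov(self, rng):
        for _ in range(25):
            Q = _random_Q(rng)
            s, t = rng.uniform(0.1, 15.0, size=2)
            lhs = transition_probability(Q, s + t)
            rhs = transition_probability(Q, s) @ transition_probability(Q, t)
            assert np.max(np.abs(lhs - rhs)) < 1e-8


class TestIntervalLoglik:

    def test_same_state_contribution_vanishes_as_dt_to_zero(self, rng):
        Q = _random_Q(rng)
        val = interval_loglik(HealthState.ROBUST, HealthState.ROBUST, 1e-9, Q)
        assert abs(val) < 1e-7

    def test_equals_expm_oracle_entry(self, rng):
        Q = _random_Q(rng)
        expected = np.log(expm_series(Q * 2.0)[0, 1])
        assert interval_loglik(HealthState.ROBUST, HealthState.IADL, 2.0, Q) \
            == pytest.approx(expected, abs=1e-10)


class TestExactDeathLoglik:

    def test_two_state_exponential_density(self):
        lam, dt = 0.2, 3.0
        Q = np.zeros((4, 4))
        Q[0, 0], Q[0, 3] = -lam, lam
        expected = np.log(lam) - lam * dt
        assert exact_death_loglik(HealthState.ROBUST, dt, Q) == \
            pytest.approx(expected, abs=1e-12)

    def test_matches_series_oracle_sum(self, rng):
        Q = _random_Q(rng)
        dt = 1.5
        P = expm_series(Q * dt)
        expected = np.log(P[0, :3] @ Q[:3, 3])
        assert exact_death_loglik(HealthState.ROBUST, dt, Q) == \
            pytest.approx(expected, abs=1e-9)

    def test_scaling_death_rates_raises_density_at_small_dt(self, rng):
        Q = _random_Q(rng)
        Q2 = Q.copy()
        Q2[:3, 3] *= 1.5
        idx = np.arange(4)
        Q2[idx, idx] = 0.0
        Q2[idx, idx] = -Q2.sum(axis=1)
        dt = 0.05
        assert exact_death_loglik(HealthState.IADL, dt, Q2) > \
            exact_death_loglik(HealthState.IADL, dt, Q)

    def test_no_death_intensity_gives_minus_infinity(self):
        Q = np.zeros((4, 4))
        Q[0, 0], Q[0, 1], Q[1, 1], Q[1, 0] = -0.1, 0.1, -0.2, 0.2
        assert exact_death_loglik(HealthState.ROBUST, 1.0, Q) == -np.inf


class TestPanelLoglik:

    def test_single_live_pair_reduction(self, gender_Q):
        panel = make_panel("x", Gender.MAN,
                           [(D(2010, 1, 1), HealthState.ROBUST),
                            (D(2012, 1, 1), HealthState.IADL)])
        model = IntensityModel(log_q0=np.full(9, np.log(0.1)))
        Q = build_Q(model, (0.0,))
        dt = (D(2012, 1, 1) - D(2010, 1, 1)).days / 365.25
        expected = interval_loglik(HealthState.ROBUST, HealthState.IADL, dt, Q)
        assert panel_loglik([panel], model) == pytest.approx(expected, abs=1e-10)

    def test_single_death_pair_reduction(self):
        panel = make_panel("x", Gender.MAN,
                           [(D(2010, 1, 1), HealthState.ROBUST),
                            (D(2011, 4, 20), HealthState.DEAD)])
        model = IntensityModel(log_q0=np.full(9, np.log(0.1)))
        Q = build_Q(model, (0.0,))
        dt = (D(2011, 4, 20) - D(2010, 1, 1)).days / 365.25
        expected = exact_death_loglik(HealthState.ROBUST, dt, Q)
        assert panel_loglik([panel], model) == pytest.approx(expected, abs=1e-10)

    def test_matches_per_pair_oracle_on_simulated_subjects(self):
        """Independent per-pair recomputation with the series-expansion expm."""
        from healthspan import build_panels
        from healthspan.synthetic import (DEFAULT_TRUE_BETA,
                                          DEFAULT_TRUE_LOG_Q0, GeneratorConfig,
                                          generate)
        from conftest import per_pair_loglik_oracle
        ds = generate(GeneratorConfig(n_subjects=50, n_waves=3, seed=99))
        panels = build_panels(ds.frame)
        model = ds.config.intensity_model()
        total = per_pair_loglik_oracle(panels, DEFAULT_TRUE_LOG_Q0,
                                       DEFAULT_TRUE_BETA)
        assert panel_loglik(panels, model) == pytest.approx(total, abs=1e-8)


class TestFit:

    def test_loglik_at_optimum_beats_crude_init(self, default_panels, default_fit):
        data = _IntervalData(default_panels, ("gender",))
        crude = IntensityModel(
            log_q0=np.log(_crude_rates(data, TransitionStructure())),
            beta=np.zeros((9, 1)))
        assert default_fit.loglik >= panel_loglik(default_panels, crude)

    def test_covariance_symmetric_psd(self, default_fit):
        cov = default_fit.covariance
        assert np.allclose(cov, cov.T, atol=1e-10)
        assert np.min(np.linalg.eigvalsh(cov)) > -1e-10

    def test_earlier_death_placement_lowers_intensity_based_le(self, default_dataset):
        """Sliding unrecorded death dates toward the interval start shortens
        the observed survival exposure, so the intensity-fitted model must
        imply a lower temporary life expectancy than with late placement.
        (The shift also re-attributes immediate deaths to the origin state,
        so individual death intensities can move either way; the implied LE
        is the stable direction.)"""
        from scipy.integrate import simpson
        from healthspan import build_panels
        le = {}
        for mode in ("early", "late"):
            fit = fit_mle(build_panels(default_dataset.frame,
                                       death_date_mode=mode))
            assert fit.converged
            us = np.linspace(0.0, 40.0, 801)
            totals = []
            for g in (0.0, 1.0):
                Q = build_Q(fit.to_intensity_model(), (g,))
                alive = [transition_probability(Q, u)[:3, :3].sum(axis=1)
                         for u in us]
                start = np.array([0.75, 0.10, 0.15])
                totals.append(simpson(start @ np.array(alive).T, x=us))
            le[mode] = totals
        assert le["early"][0] < le["late"][0]     # men
        assert le["early"][1] < le["late"][1]     # women

    def test_fit_roundtrips_through_json(self, default_fit, tmp_path):
        path = tmp_path / "fit.json"
        default_fit.to_json(path)
        back = FitResult.from_json(path)
        assert np.allclose(back.estimates, default_fit.estimates)
        assert np.allclose(back.covariance, default_fit.covariance)
        assert back.structure == default_fit.structure


class TestWaldHR:

    def _fit_with(self, beta_idx=0, beta=0.0, se=0.1):
        nt = 9
        est = np.full(nt, np.log(0.1)).tolist() + [0.0] * nt
        est[nt + beta_idx] = beta
        cov = np.eye(2 * nt) * 1e-4
        cov[nt + beta_idx, nt + beta_idx] = se ** 2
        return FitResult(
            structure=TransitionStructure(), covariate_names=("gender",),
            estimates=np.array(est), covariance=cov, loglik=-1.0,
            converged=True, n_subjects=10, n_transitions=20,
            param_names=["p"] * (2 * nt))

    def test_null_effect_interval(self):
        hr = wald_hr(self._fit_with(beta=0.0, se=0.1))
        row = hr.iloc[0]
        assert row.hr == pytest.approx(1.0)
        assert row.ci_low == pytest.approx(0.822, abs=5e-4)
        assert row.ci_high == pytest.approx(1.217, abs=5e-4)

    def test_interval_backsolves_published_style_ci(self):
        # exp(b -/+ 1.96 se) = (1.321, 1.467) around hr = 1.392 => se ~ 0.0267
        se = np.log(1.467 / 1.321) / (2 * 1.959964)
        hr = wald_hr(self._fit_with(beta=np.log(1.392), se=se))
        row = hr.iloc[0]
        assert row.hr == pytest.approx(1.392, abs=1e-3)
        assert row.ci_low == pytest.approx(1.321, abs=2e-3)
        assert row.ci_high == pytest.approx(1.467, abs=2e-3)
        assert row.se_log == pytest.approx(0.0267, abs=1e-3)

    def test_zero_se_degenerates_to_point(self):
        hr = wald_hr(self._fit_with(beta=0.3, se=0.0))
        row = hr.iloc[0]
        assert row.ci_low == row.hr == row.ci_high

    def test_unconverged_fit_rejected(self):
        fit = self._fit_with()
        fit.converged = False
        with pytest.raises(ValidationError):
            wald_hr(fit)


class TestHorizonTable:

    def _known_fit(self):
        from healthspan.synthetic import DEFAULT_TRUE_BETA, DEFAULT_TRUE_LOG_Q0
        est = np.concatenate([DEFAULT_TRUE_LOG_Q0, DEFAULT_TRUE_BETA])
        return FitResult(
            structure=TransitionStructure(), covariate_names=("gender",),
            estimates=est, covariance=np.eye(18), loglik=0.0, converged=True,
            n_subjects=1, n_transitions=1, param_names=["p"] * 18)

    def test_rows_sum_to_one(self):
        tab = horizon_probability_table(self._known_fit(), (1.0,))
        sums = tab.groupby(["start_state", "horizon"])["probability"].sum()
        assert np.allclose(sums.values, 1.0, atol=1e-10)

    def test_death_probability_nondecreasing_in_horizon(self):
        tab = horizon_probability_table(self._known_fit(), (0.0,))
        dead = tab[tab.end_state == "DEAD"].pivot(
            index="start_state", columns="horizon", values="probability")
        assert (dead[20.0] >= dead[10.0] - 1e-12).all()
        assert (dead[30.0] >= dead[20.0] - 1e-12).all()

    def test_matches_expm_oracle(self):
        fit = self._known_fit()
        tab = horizon_probability_table(fit, (1.0,))
        Q = build_Q(fit.to_intensity_model(), (1.0,))
        for t in (10.0, 20.0, 30.0):
            P = expm_series(Q * t)
            sub = tab[tab.horizon == t]
            for _, row in sub.iterrows():
                i = HealthState[row.start_state]
                j = HealthState[row.end_state]
                assert row.probability == pytest.approx(
                    P[int(i) - 1, int(j) - 1], abs=1e-9)
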