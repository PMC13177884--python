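"""Generator: population sampling, trajectories, hazards, event inversion."""

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st
from scipy import stats

from jmsim.synthetic_data import (
    BEYOND_HORIZON,
    CensoringSpec,
    ConfigurationError,
    RandomEffectsSpec,
    ScenarioConfig,
    SubjectTruth,
    SurvivalSpec,
    TrajectorySpec,
    apply_censoring,
    build_scenarios,
    cumulative_hazard,
    generate_dataset,
    invert_event_time,
    sample_population,
    true_trajectory,
    _vectorized_event_times,
)


def subject(age=80.0, sex=0, b0=0.0, b1=0.0, sid=0):
    return SubjectTruth(id=sid, age=age, sex=sex, b0=b0, b1=b1)


# ---------------------------------------------------------------------------
# population sampling


class TestSamplePopulation:
    def test_empty_population(self):
        cfg = ScenarioConfig(n_subjects=0)
        assert sample_population(cfg, 0) == []

    def test_determinism(self):
        cfg = ScenarioConfig(n_subjects=50, seed=7)
        a = sample_population(cfg, 7)
        b = sample_population(cfg, 7)
        assert all(
            s.age == t.age and s.sex == t.sex and s.b0 == t.b0 and s.b1 == t.b1
            for s, t in zip(a, b)
        )

    def test_covariate_moments(self):
        cfg = ScenarioConfig(n_subjects=100_000, seed=1)
        pop = sample_population(cfg, 1)
        ages = np.array([s.age for s in pop])
        sexes = np.array([s.sex for s in pop])
        b = np.array([[s.b0, s.b1] for s in pop])
        se_age = 6.7 / np.sqrt(len(pop))
        assert abs(ages.mean() - 80.0) < 3 * se_age
        assert abs(ages.std() - 6.7) < 0.1
        assert abs(sexes.mean() - 0.52) < 3 * np.sqrt(0.52 * 0.48 / len(pop))
        D = cfg.ranef.matrix
        assert np.allclose(np.cov(b.T), D, atol=3e-3)

    def test_non_psd_D_rejected(self):
        with pytest.raises(ConfigurationError):
            RandomEffectsSpec(D=((1.0, 2.0), (2.0, 1.0)))


# ---------------------------------------------------------------------------
# trajectories


class TestTrajectory:
    def test_linear_value_at_baseline(self):
        # beta0 + beta_age * age = 5.85 - 0.023 * 80 = 4.010
        spec = TrajectorySpec(beta0=5.85, beta_time=-0.0007, beta_age=-0.023)
        assert true_trajectory(subject(age=80.0), spec, 0.0) == pytest.approx(
            4.010, abs=1e-12
        )

    def test_slope_free_case_constant(self):
        spec = TrajectorySpec(beta_time=0.0)
        s = subject(b1=0.0, b0=0.3)
        vals = true_trajectory(s, spec, np.array([0.0, 123.0, 400.0]))
        assert np.ptp(vals) == 0.0

    def test_bspline_zero_coefficients(self):
        lin0 = TrajectorySpec(kind="linear", beta_time=0.0)
        spl = TrajectorySpec(kind="bspline", beta_spline=(0.0, 0.0, 0.0))
        s = subject(b0=0.1, b1=0.002)
        t = np.linspace(0, 400, 9)
        assert np.allclose(
            true_trajectory(s, spl, t), true_trajectory(s, lin0, t), atol=1e-12
        )

    def test_spline_partition_property(self):
        spec = TrajectorySpec(kind="bspline")
        t = np.linspace(0, 400, 201)
        B = spec.spline_basis(t)
        assert B.shape == (201, 3)
        assert np.all(B >= -1e-12)
        assert np.all(B.sum(axis=1) <= 1 + 1e-12)

    def test_spline_outside_boundary_raises(self):
        spec = TrajectorySpec(kind="bspline")
        with pytest.raises(ValueError):
            true_trajectory(subject(), spec, 401.0)

    def test_negative_time_rejected(self):
        with pytest.raises(ValueError):
            true_trajectory(subject(), TrajectorySpec(), -1.0)


# ---------------------------------------------------------------------------
# cumulative hazard


class TestCumulativeHazard:
    def test_closed_form_weibull(self, null_survival):
        surv = SurvivalSpec(phi=2.0, gamma_age=0.0, gamma_sex=0.0, alpha=0.0,
                            gamma0=0.0)
        traj = TrajectorySpec()
        assert cumulative_hazard(subject(), traj, surv, 3.0) == pytest.approx(
            9.0, rel=1e-10
        )
        assert cumulative_hazard(subject(), traj, surv, 0.0) == 0.0

    def test_time_constant_multiplier(self):
        surv = SurvivalSpec(phi=1.5, gamma_age=0.02, gamma_sex=-0.4, alpha=0.0,
                            gamma0=0.1)
        s = subject(age=75.0, sex=1)
        expected = 5.0**1.5 * np.exp(0.1 + 0.02 * 75.0 - 0.4)
        # fixed-order quadrature of s^(phi-1) with non-integer phi is not
        # exact; 31 nodes give ~1e-5 relative accuracy
        assert cumulative_hazard(s, TrajectorySpec(), surv, 5.0) == pytest.approx(
            expected, rel=2e-5
        )

    def test_against_dense_trapezoid_oracle(self):
        surv = SurvivalSpec()  # base parameters incl. calibrated gamma0
        traj = TrajectorySpec()
        s = subject(age=83.0, sex=1, b0=0.21, b1=-4e-4)
        t = 350.0
        grid = np.linspace(1e-12, t, 100_001)
        integ = (
            surv.phi
            * grid ** (surv.phi - 1)
            * np.exp(
                surv.gamma0
                + surv.gamma_age * s.age
                + surv.gamma_sex * s.sex
                + surv.alpha * true_trajectory(s, traj, grid)
            )
        )
        oracle = np.trapezoid(integ, grid)
        val = cumulative_hazard(s, traj, surv, t)
        assert val == pytest.approx(oracle, rel=1e-6)

    def test_nondecreasing(self):
        surv = SurvivalSpec()
        s = subject(age=85.0, b0=-0.3)
        vals = [cumulative_hazard(s, TrajectorySpec(), surv, t)
                for t in (0, 50, 150, 300, 400)]
        assert np.all(np.diff(vals) >= 0)


# ---------------------------------------------------------------------------
# event-time inversion


class TestInvertEventTime:
    def test_closed_form_unit_exponential_draw(self):
        surv = SurvivalSpec(phi=1.97, gamma_age=0.0, gamma_sex=0.0,
                            alpha=0.0, gamma0=0.0)
        t = invert_event_time(subject(), TrajectorySpec(), surv, np.exp(-1.0))
        assert t == pytest.approx(1.0, abs=1e-8)

    def test_monotone_in_u(self):
        surv = SurvivalSpec()
        s = subject(age=82.0, b0=0.1, b1=-3e-4)
        us = [0.05, 0.2, 0.5, 0.9]
        ts = [invert_event_time(s, TrajectorySpec(), surv, u) for u in us]
        assert np.all(np.diff(ts) <= 0)

    def test_residual_of_returned_root(self):
        surv = SurvivalSpec()
        traj = TrajectorySpec()
        s = subject(age=84.0, sex=1, b0=-0.15, b1=2e-4)
        u = 0.37
        tstar = invert_event_time(s, traj, surv, u)
        assert np.isfinite(tstar)
        assert abs(cumulative_hazard(s, traj, surv, tstar) + np.log(u)) <= 1e-8

    def test_beyond_horizon(self):
        # hazard scaled down so the draw is unreachable within the horizon
        surv = SurvivalSpec(gamma0=-40.0)
        t = invert_event_time(subject(), TrajectorySpec(), surv, 0.5)
        assert t == BEYOND_HORIZON

    def test_invalid_u(self):
        with pytest.raises(ValueError):
            invert_event_time(subject(), TrajectorySpec(), SurvivalSpec(), 0.0)

    def test_vectorized_path_matches_scalar(self):
        """Bisection (dataset path) agrees with Brent (scalar op)."""
        cfg = ScenarioConfig(n_subjects=12, seed=5)
        pop = sample_population(cfg, 5)
        E = np.random.default_rng(3).exponential(1.0, len(pop))
        vec = _vectorized_event_times(pop, cfg.trajectory, cfg.survival, E)
        for s, e, tv in zip(pop, E, vec):
            ts = invert_event_time(s, cfg.trajectory, cfg.survival, np.exp(-e))
            if np.isfinite(ts):
                assert tv == pytest.approx(ts, abs=1e-6)
            else:
                assert not np.isfinite(tv)


# ---------------------------------------------------------------------------
# censoring


class TestApplyCensoring:
    def _censor_draw(self, seed, cens):
        r = np.random.default_rng(seed)
        return min(r.uniform(0, cens.uniform_upper), cens.admin_cap)

    def test_event_before_censoring(self):
        cens = CensoringSpec()
        c = self._censor_draw(0, cens)
        assert c > 100.0  # draw known under this seed
        t, d = apply_censoring(100.0, cens, np.random.default_rng(0))
        assert (t, d) == (100.0, 1)

    def test_administrative_censoring(self):
        # pick a seed whose uniform draw exceeds the cap: C = min(draw, 400)
        cens = CensoringSpec()
        seed = next(
            s for s in range(50)
            if np.random.default_rng(s).uniform(0, 800) > 400
        )
        t, d = apply_censoring(500.0, cens, np.random.default_rng(seed))
        assert (t, d) == (400.0, 0)

    def test_tie_is_censored(self):
        cens = CensoringSpec()
        c = self._censor_draw(4, cens)
        t, d = apply_censoring(c, cens, np.random.default_rng(4))
        assert d == 0 and t == c

    def test_beyond_horizon_always_censored(self):
        cens = CensoringSpec()
        c = self._censor_draw(9, cens)
        t, d = apply_censoring(BEYOND_HORIZON, cens, np.random.default_rng(9))
        assert d == 0 and t == c

    @settings(deadline=None, max_examples=25)
    @given(tstar=st.floats(0.1, 1000.0), seed=st.integers(0, 10_000))
    def test_invariants(self, tstar, seed):
        cens = CensoringSpec()
        t, d = apply_censoring(tstar, cens, np.random.default_rng(seed))
        assert 0 <= t <= cens.admin_cap
        assert d in (0, 1)
        if d == 1:
            assert t == tstar


# ---------------------------------------------------------------------------
# datasets


class TestGenerateDataset:
    def test_invariants(self, base_cfg, base_dataset):
        ds = base_dataset
        assert len(ds.survival) == base_cfg.n_subjects
        merged = ds.longitudinal.merge(
            ds.survival[["id", "time_weeks"]], on="id", suffixes=("", "_surv")
        )
        assert (merged["time_weeks"] <= merged["time_weeks_surv"]).all()
        assert set(ds.longitudinal["time_weeks"]).issubset(set(base_cfg.schedule))
        assert ds.longitudinal.groupby("id").size().min() >= 1
        assert set(ds.longitudinal["id"]) == set(ds.survival["id"])

    def test_determinism_bit_identical(self, base_cfg):
        a = generate_dataset(base_cfg, 3)
        b = generate_dataset(base_cfg, 3)
        pd.testing.assert_frame_equal(a.longitudinal, b.longitudinal)
        pd.testing.assert_frame_equal(a.survival, b.survival)
        pd.testing.assert_frame_equal(a.truth, b.truth)

    def test_reps_differ(self, base_cfg):
        a = generate_dataset(base_cfg, 0)
        b = generate_dataset(base_cfg, 1)
        assert not a.survival["time_weeks"].equals(b.survival["time_weeks"])

    def test_noise_recoverable_from_truth(self, base_cfg, base_dataset):
        ds = base_dataset
        truth = ds.truth.set_index("id")
        for sid, g in list(ds.longitudinal.groupby("id"))[:10]:
            row = truth.loc[sid]
            s = SubjectTruth(id=sid, age=row["age"], sex=int(row["sex"]),
                             b0=row["b0"], b1=row["b1"])
            m = true_trajectory(s, base_cfg.trajectory,
                                g["time_weeks"].to_numpy())
            eps = g["y"].to_numpy() - m
            assert np.all(np.abs(eps) < 6 * base_cfg.sigma_eps)

    def test_complete_longitudinal(self, base_cfg):
        ds = generate_dataset(base_cfg, 0, complete_longitudinal=True)
        assert len(ds.longitudinal) == base_cfg.n_subjects * len(base_cfg.schedule)

    def test_empty_schedule_rejected(self):
        with pytest.raises(ConfigurationError):
            ScenarioConfig(schedule=())


# ---------------------------------------------------------------------------
# distributional validation of the simulator


class TestSimulatorDistribution:
    def test_cox_snell_unit_exponential(self):
        """Lambda(T*) at true parameters is Exp(1) for uncensored events.

        Event times come from the vectorized bisection path; the cumulative
        hazard is recomputed with the independent scalar quadrature/Brent
        machinery, so this also cross-checks the two code paths.
        """
        cfg = ScenarioConfig(n_subjects=10_000, seed=42)
        pop = sample_population(cfg, 42)
        rng = np.random.default_rng(99)
        E = rng.exponential(1.0, len(pop))
        tstar = _vectorized_event_times(pop, cfg.trajectory, cfg.survival, E,
                                        horizon=20_000.0)
        finite = np.isfinite(tstar)
        assert finite.mean() > 0.99
        lam = np.array(
            [
                cumulative_hazard(s, cfg.trajectory, cfg.survival, t)
                for s, t in zip(
                    [p for p, f in zip(pop, finite) if f], tstar[finite]
                )
            ][:2000]
        )
        stat, pval = stats.kstest(lam, "expon")
        assert pval > 0.01

    def test_weibull_closed_form_limit(self):
        """With alpha = gamma = 0 event times are Weibull(phi, scale 1)."""
        surv = SurvivalSpec(phi=1.97, gamma_age=0.0, gamma_sex=0.0,
                            alpha=0.0, gamma0=0.0)
        traj = TrajectorySpec(beta_time=0.0)
        cfg = ScenarioConfig(n_subjects=5000, seed=8)
        pop = sample_population(cfg, 8)
        E = np.random.default_rng(13).exponential(1.0, len(pop))
        tstar = _vectorized_event_times(pop, traj, surv, E, horizon=50.0)
        assert np.all(np.isfinite(tstar))
        for t0 in (0.5, 1.0, 1.5):
            emp = (tstar > t0).mean()
            expected = np.exp(-(t0**1.97))
            se = np.sqrt(expected * (1 - expected) / len(tstar))
            assert abs(emp - expected) < 4 * max(se, 1e-3)

    def test_trajectory_conservation(self):
        """Mean observed y at fixed t matches the fixed-effect trajectory."""
        cfg = ScenarioConfig(n_subjects=4000, seed=21)
        ds = generate_dataset(cfg, 0, complete_longitudinal=True)
        pop_age = ds.survival["age"].mean()
        for t in (0.0, 200.0, 400.0):
            ybar = ds.longitudinal.loc[
                ds.longitudinal["time_weeks"] == t, "y"
            ].mean()
            m = (
                cfg.trajectory.beta0
                + cfg.trajectory.beta_time * t
                + cfg.trajectory.beta_age * pop_age
            )
            tol = 4 * np.sqrt(0.08) / np.sqrt(cfg.n_subjects)
            assert abs(ybar - m) < tol


# ---------------------------------------------------------------------------
# scenario grids


class TestBuildScenarios:
    def test_base_schedule(self):
        cfgs = build_scenarios("2a")
        assert cfgs[0].schedule == (0.0, 100.0, 200.0, 300.0, 400.0)

    def test_setting2_endpoints(self):
        alphas = {c.survival.alpha for c in build_scenarios("2a")}
        assert {0.0, -1.5} <= alphas

    def test_setting5_endpoints(self):
        sigmas = {c.sigma_eps for c in build_scenarios("5a")}
        assert {0.05, 0.5} <= sigmas

    def test_setting1_spacing(self):
        cfgs = build_scenarios("1a")
        assert any(c.schedule == (0.0, 300.0) for c in cfgs)
        assert any(len(c.schedule) == 21 for c in cfgs)  # every 20 weeks

    def test_b_settings_use_spline(self):
        assert all(c.trajectory.kind == "bspline" for c in build_scenarios("1b"))
        assert all(c.trajectory.kind == "linear" for c in build_scenarios("1a"))

    def test_single_parameter_varies(self):
        cfgs = build_scenarios("3a")
        assert len({c.survival.phi for c in cfgs}) == len(cfgs)
        assert len({c.sigma_eps for c in cfgs}) == 1

    def test_unknown_setting(self):
        with pytest.raises(ConfigurationError):
            build_scenarios("9z")

    def test_grid_override(self):
        cfgs = build_scenarios("5a", grid_override=[0.1, 0.2])
        assert [c.sigma_eps for c in cfgs] == [0.1, 0.2]
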