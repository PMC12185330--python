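"""Additive-hazards estimator: reductions, oracle agreement, recovery."""

import subprocess

import numpy as np
import pandas as pd
import pytest

from oracles import nelson_aalen_hazard
from pedrisk.aalen import (
    SurvivalDesign,
    build_design,
    fit_aalen,
    prediction_grid,
    summarize_34y,
)
from pedrisk.scoring import compute_all_scores
from pedrisk.simulate import DISORDER_CODES


@pytest.fixture(scope="module")
def small_scores(small_sim, small_links):
    cfg, bundle, _ = small_sim
    cohort = bundle.persons.loc[
        bundle.cohort_mask(cfg.birth_year_range), "id"
    ].to_numpy(np.int64)
    return compute_all_scores(bundle, small_links, list(DISORDER_CODES), probands=cohort)


def intercept_design(t, d):
    return SurvivalDesign(
        time=np.asarray(t, float), event=np.asarray(d, int),
        X=np.ones((len(t), 1)), columns=["intercept"],
    )


class TestReductions:
    def test_covariate_free_equals_nelson_aalen_exactly(self):
        rng = np.random.default_rng(0)
        t = rng.exponential(100, 800)
        cen = rng.uniform(20, 300, 800)
        time = np.minimum(t, cen)
        event = (t <= cen).astype(int)
        fit = fit_aalen(intercept_design(time, event))
        ev, H = nelson_aalen_hazard(time, event)
        assert np.array_equal(fit.times, ev)
        np.testing.assert_allclose(fit.B[:, 0], H, rtol=0, atol=1e-12)

    def test_binary_covariate_recovers_group_nelson_aalen(self):
        """With one binary covariate and no censoring, B0 tracks the group-0
        hazard and B0+B1 the group-1 hazard, both exactly."""
        rng = np.random.default_rng(1)
        n = 600
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1 / (0.01 + 0.01 * x))
        d = np.ones(n, int)
        des = SurvivalDesign(time=t, event=d, X=np.column_stack([np.ones(n), x]),
                             columns=["intercept", "x"])
        fit = fit_aalen(des)
        ev0, H0 = nelson_aalen_hazard(t[x == 0], d[x == 0])
        ev1, H1 = nelson_aalen_hazard(t[x == 1], d[x == 1])
        B0 = {s: v for s, v in zip(fit.times, fit.B[:, 0])}
        B01 = {s: v0 + v1 for s, v0, v1 in zip(fit.times, fit.B[:, 0], fit.B[:, 1])}
        # at group-0 event times the group-0 path must match exactly, because
        # the two groups' increments separate in the least-squares solution
        for s, h in zip(ev0, H0):
            assert abs(B0[s] - h) < 1e-8
        for s, h in zip(ev1, H1):
            assert abs(B01[s] - h) < 1e-8

    @pytest.mark.parametrize("seed", [11, 12, 13])
    def test_agrees_with_r_survival_aareg(self, seed, tmp_path):
        """survival::aareg is an independent implementation of the same
        least-squares increment estimator; paths must agree to 1e-8."""
        rng = np.random.default_rng(seed)
        n = 250
        x1 = rng.standard_normal(n)
        x2 = rng.integers(0, 2, n).astype(float)
        lam = np.clip(0.02 + 0.01 * x2 + 0.004 * x1, 1e-4, None)
        te = rng.exponential(1 / lam)
        cen = rng.uniform(10, 80, n)
        t = np.minimum(te, cen)
        d = (te <= cen).astype(int)
        infile = tmp_path / "in.csv"
        outfile = tmp_path / "out.csv"
        pd.DataFrame({"time": t, "event": d, "x1": x1, "x2": x2}).to_csv(infile, index=False)
        script = (
            'library(survival); df <- read.csv("%s"); '
            "fit <- aareg(Surv(time, event) ~ x1 + x2, data=df, nmin=1); "
            'write.csv(data.frame(time=fit$times, fit$coefficient), "%s", row.names=FALSE)'
            % (infile, outfile)
        )
        subprocess.run(["Rscript", "-e", script], check=True, capture_output=True)
        ref = pd.read_csv(outfile).groupby("time").sum().cumsum()
        des = SurvivalDesign(time=t, event=d,
                             X=np.column_stack([np.ones(n), x1, x2]),
                             columns=["intercept", "x1", "x2"])
        fit = fit_aalen(des)
        assert len(ref) == len(fit.times)
        assert np.abs(ref.to_numpy() - fit.B).max() < 1e-8

    def test_no_events_raises(self):
        with pytest.raises(ValueError, match="no events"):
            fit_aalen(intercept_design([1.0, 2.0], [0, 0]))


class TestRecovery:
    def test_planted_additive_hazard(self):
        """lambda(t|x) = 0.001 + 0.0005 x per month: the slope of B1 over 408
        months recovers the planted covariate hazard within Monte-Carlo error."""
        rng = np.random.default_rng(5)
        n = 20_000
        x = rng.integers(0, 2, n).astype(float)
        lam = 0.001 + 0.0005 * x
        te = rng.exponential(1 / lam)
        t = np.minimum(te, 408.0)
        d = (te <= 408.0).astype(int)
        des = SurvivalDesign(time=t, event=d, X=np.column_stack([np.ones(n), x]),
                             columns=["intercept", "x"])
        fit = fit_aalen(des)
        slope = fit.cumulative_at(408.0)[1] / 408.0
        assert slope == pytest.approx(0.0005, rel=0.15)

    def test_negative_interaction_detected_in_45_of_50_runs(self):
        """Simulated additive hazard with a negative product term yields a
        negative interaction summary in at least 45/50 seeded replicates."""
        hits = 0
        for seed in range(50):
            rng = np.random.default_rng(1000 + seed)
            n = 10_000
            f = rng.standard_normal(n)
            g = rng.standard_normal(n)
            lam = np.clip(0.004 + 0.0012 * f - 0.0008 * g - 0.0006 * f * g, 1e-6, None)
            te = rng.exponential(1 / lam)
            t = np.minimum(te, 408.0)
            d = (te <= 408.0).astype(int)
            X = np.column_stack([np.ones(n), f, g, f * g])
            des = SurvivalDesign(time=t, event=d, X=X,
                                 columns=["intercept", "F", "G", "FxG"])
            fit = fit_aalen(des)
            if fit.cumulative_at(408.0)[3] < 0:
                hits += 1
        assert hits >= 45

    def test_null_covariate_ci_covers_zero(self):
        """Bootstrap CI for a covariate with no effect covers 0 in >= 90% of
        seeded replicates."""
        covered = 0
        reps = 50
        for seed in range(reps):
            rng = np.random.default_rng(2000 + seed)
            n = 1_500
            x = rng.standard_normal(n)
            te = rng.exponential(1 / 0.004, n)
            t = np.minimum(te, 408.0)
            d = (te <= 408.0).astype(int)
            des = SurvivalDesign(time=t, event=d,
                                 X=np.column_stack([np.ones(n), x]),
                                 columns=["intercept", "x"])
            s = summarize_34y(des, n_boot=60, seed=seed)
            if s.ci_low[1] <= 0 <= s.ci_high[1]:
                covered += 1
        assert covered / reps >= 0.90


class TestSummary:
    def test_plateau_after_last_event(self):
        t = np.array([50.0, 80.0, 100.0, 200.0, 300.0])
        d = np.array([1, 1, 1, 0, 0])
        des = intercept_design(t, d)
        fit = fit_aalen(des)
        s = summarize_34y(des, fit=fit, n_boot=100, seed=0)
        assert s.estimate[0] == pytest.approx(100.0 * fit.B[-1, 0])

    def test_column_scaling_halves_coefficient(self):
        rng = np.random.default_rng(9)
        n = 500
        x = rng.standard_normal(n)
        te = rng.exponential(1 / np.clip(0.01 + 0.002 * x, 1e-4, None))
        t = np.minimum(te, 300.0)
        d = (te <= 300.0).astype(int)
        d1 = SurvivalDesign(time=t, event=d, X=np.column_stack([np.ones(n), x]),
                            columns=["intercept", "x"])
        d2 = SurvivalDesign(time=t, event=d, X=np.column_stack([np.ones(n), 2 * x]),
                            columns=["intercept", "x"])
        f1, f2 = fit_aalen(d1), fit_aalen(d2)
        np.testing.assert_allclose(f2.B[:, 1], f1.B[:, 1] / 2.0, atol=1e-10)

    def test_no_event_before_t_star_raises(self):
        des = intercept_design([500.0, 600.0], [1, 1])
        with pytest.raises(ValueError, match="408"):
            summarize_34y(des, n_boot=100, seed=0)


class TestDesignAndGrid:
    def test_model_c_has_six_columns(self, small_sim, small_scores):
        cfg, bundle, _ = small_sim
        des = build_design(bundle, small_scores, "MD", model="C")
        assert des.X.shape[1] == 6
        assert des.columns == ["intercept", "yob_c", "sex", "FGRS", "GAEA", "FGRSxGAEA"]

    def test_zero_scores_zero_interaction_column(self, small_sim, small_scores):
        cfg, bundle, _ = small_sim
        s = small_scores.copy()
        s.loc[:, ["FGRS_MD", "GAEA"]] = 0.0
        des = build_design(bundle, s, "MD", model="C")
        assert np.all(des.X[:, -1] == 0)

    def test_subjects_censored_at_entry_dropped(self, small_sim, small_scores):
        cfg, bundle, _ = small_sim
        persons = bundle.persons.copy()
        # force one scored subject to die in childhood
        victim = small_scores.index[0]
        persons.loc[persons["id"] == victim, "death_month"] = 100.0
        from pedrisk.simulate import RegistryBundle

        events = bundle.events[bundle.events["id"] != victim]
        b2 = RegistryBundle(persons=persons, pedigree=bundle.pedigree,
                            events=events, cohab=bundle.cohab)
        des = build_design(b2, small_scores, "MD", model="C")
        assert des.n_dropped >= 1

    def test_flat_grid_when_only_intercept_nonzero(self):
        from pedrisk.aalen import AalenFit

        fit = AalenFit(
            times=np.array([100.0]), B=np.array([[0.05, 0, 0, 0, 0, 0.0]]),
            increments=np.array([[0.05, 0, 0, 0, 0, 0.0]]),
            n_at_risk=np.array([10]), n_events=np.array([1]),
            columns=["intercept", "yob_c", "sex", "FGRS", "GAEA", "FGRSxGAEA"],
        )
        grid = prediction_grid(fit)
        assert np.allclose(grid["predicted_rate"], 0.05)

    def test_negative_interaction_gives_fan_shape_and_clamping(self):
        from pedrisk.aalen import AalenFit

        B = np.array([[0.10, 0.0, 0.0, 0.04, -0.02, -0.015]])
        fit = AalenFit(
            times=np.array([100.0]), B=B, increments=B,
            n_at_risk=np.array([10]), n_events=np.array([1]),
            columns=["intercept", "yob_c", "sex", "FGRS", "GAEA", "FGRSxGAEA"],
        )
        grid = prediction_grid(fit)

        def spread(f):
            lo = grid[(grid.fgrs == f) & (grid.gaea_level == -2)].predicted_rate.iloc[0]
            hi = grid[(grid.fgrs == f) & (grid.gaea_level == 2)].predicted_rate.iloc[0]
            return lo - hi

        spreads = [spread(f) for f in (-3, -1, 1, 3)]
        assert all(b >= a - 1e-12 for a, b in zip(spreads, spreads[1:]))
        assert spread(3) > spread(-3)
        assert grid["predicted_rate"].min() >= 0.0  # clamped at zero
        raw_min = min(
            0.10 + 0.04 * f - 0.02 * g - 0.015 * f * g
            for f in np.arange(-3, 3.25, 0.25) for g in (-2, -1, 0, 1, 2)
        )
        assert raw_min < 0  # clamping actually exercised
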