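"""Concordance, Brier/IBS, bootstrap and penalized Cox against oracles."""

import numpy as np
import pandas as pd
import pytest

from milsurv.metrics import (
    bootstrap_ci,
    brier_score,
    build_cox_design,
    cox_predict_survival,
    fit_coxph,
    harrell_cindex,
    integrated_brier,
    run_model_comparison,
    td_cindex,
)
from milsurv.objectives import censoring_survival, hazards_to_survival


def _harrell_oracle(scores, times, events):
    num = den = 0.0
    n = len(times)
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = events[i] and (
                times[i] < times[j]
                or (times[i] == times[j] and not events[j])
            )
            if not comparable:
                continue
            den += 1
            if scores[i] > scores[j]:
                num += 1
            elif scores[i] == scores[j]:
                num += 0.5
    return num / den


class TestHarrell:
    def test_perfect_anticoncordance_of_times(self, rng):
        times = rng.uniform(1, 60, size=30)
        events = np.ones(30, bool)
        assert harrell_cindex(-times, times, events) == 1.0

    def test_random_scores_near_half(self, rng):
        cs = [
            harrell_cindex(rng.uniform(size=2000), rng.uniform(1, 60, 2000),
                           np.ones(2000, bool))
            for _ in range(50)
        ]
        assert np.mean(cs) == pytest.approx(0.5, abs=0.01)

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(5):
            n = 20
            scores = rng.standard_normal(n)
            times = rng.exponential(20, size=n).round(0) + 1
            events = rng.random(n) < 0.6
            assert harrell_cindex(scores, times, events) == pytest.approx(
                _harrell_oracle(scores, times, events), abs=1e-12
            )

    def test_no_comparable_pairs_raises(self):
        with pytest.raises(ValueError):
            harrell_cindex([1.0, 2.0], [5.0, 5.0], [False, False])


def _td_oracle(curves, times, events):
    import math

    n = len(times)
    num = den = 0.0
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            comparable = events[i] and (
                times[i] < times[j]
                or (times[i] == times[j] and not events[j])
            )
            if not comparable:
                continue
            k = min(max(math.ceil(times[i]), 1), 60) - 1
            den += 1
            if curves[i, k] < curves[j, k]:
                num += 1
            elif curves[i, k] == curves[j, k]:
                num += 0.5
    return num / den


class TestTdCindex:
    def test_proportional_ordered_curves_give_one(self, rng):
        n = 25
        risk = np.sort(rng.standard_normal(n))
        etas = 0.01 * np.exp(risk)[:, None] * np.ones((n, 60))
        curves = hazards_to_survival(etas)
        times = np.sort(rng.uniform(1, 59, size=n))[::-1]  # high risk dies first
        assert td_cindex(curves, times, np.ones(n, bool)) == 1.0

    def test_identical_curves_give_half(self, rng):
        curves = np.tile(np.linspace(1, 0.5, 60), (10, 1))
        times = rng.uniform(1, 59, size=10)
        assert td_cindex(curves, times, np.ones(10, bool)) == 0.5

    def test_matches_pairwise_oracle(self, rng):
        for _ in range(5):
            n = 20
            curves = hazards_to_survival(rng.uniform(0.001, 0.05, size=(n, 60)))
            times = rng.uniform(0.5, 70, size=n)
            events = rng.random(n) < 0.7
            from milsurv.objectives import administrative_censor

            t_c, e_c = administrative_censor(times, events)
            assert td_cindex(curves, times, events) == pytest.approx(
                _td_oracle(curves, t_c, e_c), abs=1e-12
            )

    def test_true_model_approaches_analytic_concordance(self):
        """On a large cohort the td C-index of the generating model matches
        the analytic concordance of exponential proportional hazards,
        E[exp(r_max) / (exp(r_i) + exp(r_j))] over random pairs."""
        rng = np.random.default_rng(7)
        n = 10_000
        r = rng.standard_normal(n)
        lam = 0.01 * np.exp(r)
        times = rng.exponential(1.0 / lam)
        events = np.ones(n, bool)
        curves = hazards_to_survival(0.01 * np.exp(r)[:, None] * np.ones((1, 60)))
        # analytic concordance via Monte-Carlo over pairs
        ri, rj = rng.standard_normal((2, 1_000_000))
        analytic = np.mean(np.exp(np.maximum(ri, rj))
                           / (np.exp(ri) + np.exp(rj)))
        observed = td_cindex(curves, times, events)
        assert observed == pytest.approx(analytic, abs=0.01)


class TestBrier:
    def test_constant_half_is_quarter(self, rng):
        times = rng.exponential(80, size=500)
        events = np.ones(500, bool)
        assert brier_score(np.full(500, 0.5), times, events) == 0.25

    def test_oracle_is_zero(self, rng):
        times = rng.exponential(80, size=100)
        events = np.ones(100, bool)
        surv = (times > 60).astype(float)
        assert brier_score(surv, times, events) == 0.0

    def test_censored_hand_example(self):
        """Ten patients, hand-computed Graf weights."""
        times = np.array([10.0, 20.0, 30.0, 40.0, 50.0, 65.0, 70.0, 25.0, 55.0, 80.0])
        events = np.array([True, True, True, False, True, False, False, True, True, False])
        s = np.full(10, 0.4)
        # one censoring before tau at t=40 with risk set {40,50,55,65,70,80}:
        # G drops to 5/6 there; events at 50,55 and the at-risk group at tau
        # are weighted by 6/5
        g = 5 / 6
        w = np.array([1, 1, 1, 0, 1 / g, 1 / g, 1 / g, 1, 1 / g, 1 / g])
        err = np.array([s[0] ** 2] * 10)
        err[[5, 6, 9]] = (1 - 0.4) ** 2
        expected = (w * err).sum() / 10
        assert brier_score(s, times, events) == pytest.approx(expected, abs=1e-12)

    def test_complete_case_variant(self, rng):
        times = rng.exponential(50, size=200)
        events = np.ones(200, bool)
        s = rng.uniform(size=200)
        assert brier_score(s, times, events, ipcw=False) == pytest.approx(
            brier_score(s, times, events, ipcw=True), abs=1e-12
        )


class TestIntegratedBrier:
    def test_constant_half_curves(self, rng):
        times = rng.exponential(80, size=300)
        events = np.ones(300, bool)
        curves = np.full((300, 60), 0.5)
        assert integrated_brier(curves, times, events) == pytest.approx(0.25, abs=1e-12)

    def test_oracle_step_curves_are_zero(self, rng):
        times = rng.uniform(1, 120, size=80)
        events = np.ones(80, bool)
        months = np.arange(1, 61)
        curves = (months[None, :] < times[:, None]).astype(float)
        assert integrated_brier(curves, times, events) == 0.0

    def test_matches_per_month_oracle(self, rng):
        n = 30
        curves = hazards_to_survival(rng.uniform(0.001, 0.05, size=(n, 60)))
        times = rng.uniform(0.5, 90, size=n)
        events = rng.random(n) < 0.7
        G = censoring_survival(times, events)
        bs = []
        for t in np.arange(1, 61, dtype=float):
            total = 0.0
            for i in range(n):
                s_it = curves[i, int(t) - 1]
                if events[i] and times[i] <= t:
                    total += s_it**2 / G(times[i], left=True)
                elif times[i] > t or (times[i] == t and not events[i]):
                    total += (1 - s_it) ** 2 / G(t, left=True)
            bs.append(total / n)
        expected = np.trapezoid(bs, np.arange(1, 61)) / 59
        assert integrated_brier(curves, times, events) == pytest.approx(
            expected, abs=1e-12
        )


def test_brier_and_ibs_match_scikit_survival():
    """Independent cross-check: Graf-weighted Brier at 60 months and the
    trapezoid IBS agree with scikit-survival on tie-free censored data."""
    from sksurv.metrics import brier_score as sk_brier
    from sksurv.metrics import integrated_brier_score as sk_ibs

    rng = np.random.default_rng(3)
    n = 300
    times = rng.uniform(0.3, 120, n)
    events = rng.random(n) < 0.6
    curves = hazards_to_survival(rng.uniform(0.001, 0.04, (n, 60)))
    y = np.array(list(zip(events, times)), dtype=[("e", bool), ("t", float)])
    _, sk60 = sk_brier(y, y, curves[:, 59], np.array([60.0]))
    assert brier_score(curves[:, 59], times, events) == pytest.approx(
        sk60[0], abs=1e-12
    )
    grid = np.arange(1.0, 61.0)
    assert integrated_brier(curves, times, events) == pytest.approx(
        sk_ibs(y, y, curves, grid), abs=1e-12
    )


class TestBootstrap:
    def test_constant_metric_zero_width(self, rng):
        times = rng.uniform(1, 59, size=40)
        events = np.ones(40, bool)
        res = bootstrap_ci(lambda s, t, e: 0.42, (np.zeros(40), times, events),
                          B=100, seed=1)
        assert res.ci_low == res.ci_high == pytest.approx(0.42)

    def test_deterministic_given_seed(self, rng):
        scores = rng.standard_normal(60)
        times = rng.exponential(30, size=60)
        events = rng.random(60) < 0.7
        a = bootstrap_ci(harrell_cindex, (scores, times, events), B=200, seed=5)
        b = bootstrap_ci(harrell_cindex, (scores, times, events), B=200, seed=5)
        assert (a.ci_low, a.ci_high) == (b.ci_low, b.ci_high)

    def test_coverage_of_true_cindex(self):
        """95% CI covers the large-sample C-index in ~95% of replicates."""
        rng = np.random.default_rng(11)
        # population truth: P(higher-risk of a pair dies first) for
        # exponential proportional hazards, by pairwise Monte-Carlo
        r1, r2 = rng.standard_normal((2, 2_000_000))
        truth = float(np.mean(np.exp(np.maximum(r1, r2))
                              / (np.exp(r1) + np.exp(r2))))
        covered = 0
        n_rep = 200
        for rep in range(n_rep):
            r = rng.standard_normal(150)
            t = rng.exponential(1 / (0.02 * np.exp(r)))
            res = bootstrap_ci(harrell_cindex, (r, t, np.ones(150, bool)),
                              B=200, seed=rep)
            covered += res.ci_low <= truth <= res.ci_high
        assert covered / n_rep == pytest.approx(0.95, abs=0.03)


class TestCoxPH:
    def test_recovers_log_two(self, rng):
        n = 5000
        x = (rng.random(n) < 0.5).astype(float)
        times = rng.exponential(1 / (0.01 * 2**x))
        X = pd.DataFrame({"grp": x})
        fit = fit_coxph(X, times, np.ones(n, bool), penalizer=0.0)
        assert 0.65 <= fit.beta[0] <= 0.74

    def test_three_patient_grid_oracle(self):
        X = pd.DataFrame({"x": [1.0, 0.0, 1.0]})
        times = np.array([1.0, 2.0, 3.0])
        events = np.array([True, True, True])
        grid = np.linspace(-4, 4, 4_000_001)
        ll = (grid - np.log(np.exp(grid) + 1 + np.exp(grid))
              - np.log(1 + np.exp(grid)))
        b_star = grid[np.argmax(ll)]
        fit = fit_coxph(X, times, events, penalizer=0.0)
        assert fit.beta[0] == pytest.approx(b_star, abs=1e-6)

    def test_ridge_shrinks_monotonically(self, rng):
        n = 300
        x = rng.standard_normal(n)
        times = rng.exponential(1 / (0.02 * np.exp(0.5 * x)))
        X = pd.DataFrame({"x": x})
        events = np.ones(n, bool)
        betas = [abs(fit_coxph(X, times, events, penalizer=p).beta[0])
                 for p in (0.0, 0.1, 1.0, 10.0, 100.0)]
        assert all(b1 >= b2 for b1, b2 in zip(betas, betas[1:]))
        assert betas[-1] < 0.05

    def test_predict_survival_ph_identity(self, rng):
        n = 200
        x = rng.standard_normal(n)
        times = rng.exponential(1 / (0.02 * np.exp(0.5 * x)))
        fit = fit_coxph(pd.DataFrame({"x": x}), times, np.ones(n, bool))
        s1 = cox_predict_survival(fit, np.array([[1.0]]))[0]
        s2 = cox_predict_survival(fit, np.array([[2.0]]))[0]
        # lp and 2*lp: S2 = S1 ** exp(lp)
        assert np.allclose(s2, s1 ** np.exp(fit.beta[0]), rtol=1e-10)
        assert np.all(np.diff(s1) <= 1e-15)

    def test_baseline_at_reference_level(self, rng):
        n = 150
        x = rng.standard_normal(n)
        times = rng.exponential(1 / (0.02 * np.exp(0.5 * x)))
        fit = fit_coxph(pd.DataFrame({"x": x}), times, np.ones(n, bool))
        s_ref = cox_predict_survival(fit, np.array([[0.0]]))[0]
        h0 = np.asarray(fit.baseline_cumhaz(np.arange(1.0, 61.0)))
        assert np.allclose(s_ref, np.exp(-h0), rtol=1e-12)

    def test_schema_mismatch_raises(self, rng):
        fit = fit_coxph(pd.DataFrame({"x": rng.standard_normal(50)}),
                        rng.exponential(30, 50), np.ones(50, bool))
        with pytest.raises(ValueError):
            cox_predict_survival(fit, pd.DataFrame({"y": [1.0]}))


class TestDesign:
    def test_mx_imputed_and_complete_cases(self):
        frame = pd.DataFrame(
            {
                "age_group": ["<60", "60-69", None, "70-79"],
                "T": ["T2", "T3", "T3", "T4"],
                "N": ["N0", "N1", "N0", "N2"],
                "M": ["M0", "MX", "M0", "M1"],
                "time_months": [10.0, 20.0, 30.0, 40.0],
                "event": [1, 1, 0, 1],
            }
        )
        X, times, events, kept, cats = build_cox_design(
            frame, ("age_group", "T", "N", "M")
        )
        assert list(kept) == [0, 1, 3]  # row 2 dropped (missing age)
        assert "M_M1" in X.columns  # MX collapsed into reference M0
        assert X["M_M1"].tolist() == [0.0, 0.0, 1.0]

    def test_one_hot_reference_is_lowest_level(self):
        frame = pd.DataFrame(
            {"T": ["T2", "T3", "T4"], "time_months": [1.0, 2.0, 3.0],
             "event": [1, 1, 1]}
        )
        X, *_ = build_cox_design(frame, ("T",))
        assert sorted(X.columns) == ["T_T3", "T_T4"]


def test_model_comparison_schema(small_cohort):
    """Output rows cover {clinical, image, combined} x cohorts x strata."""
    from milsurv.scoring import curve_mortality_score

    frame = small_cohort.frame()
    rng = np.random.default_rng(0)
    curves = hazards_to_survival(
        0.01 * np.exp(small_cohort.latent_risk)[:, None] * np.ones((1, 60))
    )
    scores = curve_mortality_score(curves)
    table = run_model_comparison(
        frame, scores, {"siteA": (frame, scores, curves)}, B=20, seed=0
    )
    assert set(table["model"]) == {"clinical", "image", "combined"}
    assert set(table["stratum"]) <= {"CHR", "CLR"}
    assert {"td_cindex", "ci_low", "ci_high"} <= set(table.columns)
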