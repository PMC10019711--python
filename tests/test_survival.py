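import numpy as np
import pandas as pd
import pytest
from scipy import stats

from tonemask import survival
from tonemask.survival import (
    EmmGrid,
    anova_effects,
    categorize,
    check_cld_consistency,
    cox_frailty_fit,
    cox_snell,
    cox_snell_slope,
    dprime_table,
    drop_first_block,
    edge_corrected_rate,
    emmeans_log_hazard,
    flag_high_far_subjects,
    km_nelson_aalen,
    lmm_dprime,
    predict_curves,
    survival_data,
    tukey_cld,
    tukey_pairwise,
)


def make_records(rows):
    base = dict(subject_id="S01", trial_id=0, block=2, uncertainty=29.0,
                similarity=0.0, rate=1.0)
    return pd.DataFrame([{**base, **r} for r in rows])


class TestCategorize:
    def test_fast_response_is_a_guess(self):
        df = make_records([dict(target_present=True, response_time_ms=500.0)])
        assert categorize(df, "I").category.iloc[0] == "guess"

    def test_cutoffs_differ_by_experiment(self):
        df = make_records([dict(target_present=True, response_time_ms=900.0)])
        assert categorize(df, "I").category.iloc[0] == "guess"
        assert categorize(df, "II").category.iloc[0] == "hit"

    def test_catch_without_response_is_correct_rejection(self):
        df = make_records([dict(target_present=False, response_time_ms=np.nan)])
        assert categorize(df, "I").category.iloc[0] == "correct_rejection"

    def test_catch_with_response_is_false_alarm(self):
        df = make_records([dict(target_present=False, response_time_ms=400.0)])
        assert categorize(df, "I").category.iloc[0] == "false_alarm"

    def test_hit_time_measured_from_target_onset(self):
        df = make_records([dict(target_present=True, response_time_ms=5000.0)])
        out = categorize(df, "I")
        assert out.category.iloc[0] == "hit"
        assert out.time_from_onset_ms.iloc[0] == pytest.approx(4400.0)

    def test_unknown_experiment(self):
        with pytest.raises(ValueError):
            categorize(make_records([dict(target_present=True,
                                          response_time_ms=None)]), "IV")


class TestDropFirstBlock:
    def test_removes_block_one_and_is_idempotent(self, small_records):
        df, _ = small_records
        once = drop_first_block(df)
        assert set(once.block) == {2, 3, 4, 5, 6}
        n1 = (df.block == 1).sum()
        assert len(once) == len(df) - n1
        pd.testing.assert_frame_equal(drop_first_block(once), once)


class TestDPrime:
    def test_edge_correction(self):
        assert edge_corrected_rate(10, 10) == pytest.approx(10.5 / 11)
        assert edge_corrected_rate(0, 10) == pytest.approx(0.5 / 11)

    def test_equal_rates_give_zero(self):
        z = stats.norm.ppf
        hr = edge_corrected_rate(30, 100)
        assert z(hr) - z(hr) == 0.0

    def test_dprime_magnitude(self):
        # HR 84/100, FAR 16/100 -> d' about 1.98
        z = stats.norm.ppf
        d = z(edge_corrected_rate(84, 100)) - z(edge_corrected_rate(16, 100))
        assert d == pytest.approx(1.98, abs=0.05)

    def test_antisymmetry_under_hit_false_alarm_swap(self):
        rows = (
            [dict(target_present=True, response_time_ms=5000.0)] * 30
            + [dict(target_present=True, response_time_ms=np.nan)] * 20
            + [dict(target_present=False, response_time_ms=3000.0)] * 10
            + [dict(target_present=False, response_time_ms=np.nan)] * 40
        )
        cat = categorize(make_records(rows), "I")
        d1 = dprime_table(cat).dprime.iloc[0]
        swapped = (
            [dict(target_present=True, response_time_ms=5000.0)] * 10
            + [dict(target_present=True, response_time_ms=np.nan)] * 40
            + [dict(target_present=False, response_time_ms=3000.0)] * 30
            + [dict(target_present=False, response_time_ms=np.nan)] * 20
        )
        cat2 = categorize(make_records(swapped), "I")
        d2 = dprime_table(cat2).dprime.iloc[0]
        assert d1 == pytest.approx(-d2)

    def test_guesses_excluded_from_rates(self):
        rows = (
            [dict(target_present=True, response_time_ms=5000.0)] * 10
            + [dict(target_present=True, response_time_ms=300.0)] * 5
            + [dict(target_present=True, response_time_ms=np.nan)] * 10
            + [dict(target_present=False, response_time_ms=np.nan)] * 10
        )
        tab = dprime_table(categorize(make_records(rows), "I"))
        assert tab.n_target.iloc[0] == 20  # guesses not counted


class TestLmmDPrime:
    @staticmethod
    def balanced_dprime(seed, subj_sd=0.0, effect=(0.0, 0.5, 1.0)):
        rng = np.random.default_rng(seed)
        rows = []
        for s in range(8):
            u0 = rng.normal(0, subj_sd)
            for c, e in zip([29.0, 116.0, 464.0], effect):
                rows.append(dict(subject_id=f"S{s}", uncertainty=c,
                                 dprime=1.0 + e + u0 + rng.normal(0, 0.5)))
        return pd.DataFrame(rows)

    def test_matches_anova_without_subject_variance(self):
        dp = self.balanced_dprime(3, subj_sd=0.0)
        res = lmm_dprime(dp)
        groups = [g.dprime.to_numpy() for _, g in dp.groupby("uncertainty")]
        f_anova = stats.f_oneway(*groups).statistic
        assert res.f_stat == pytest.approx(f_anova, rel=0.1)
        assert res.df1 == 2 and res.df2 == (8 - 1) * (3 - 1)

    def test_invariant_to_constant_shift(self):
        dp = self.balanced_dprime(4, subj_sd=0.4)
        r1 = lmm_dprime(dp)
        dp2 = dp.assign(dprime=dp.dprime + 3.7)
        r2 = lmm_dprime(dp2)
        assert r1.f_stat == pytest.approx(r2.f_stat, rel=1e-4)


class TestKmNelsonAalen:
    def test_product_limit_all_events(self):
        surv, _ = km_nelson_aalen(np.array([1.0, 2.0, 3.0]), np.ones(3))
        vals = surv.set_index("time")["survival"]
        assert vals.loc[1.0] == pytest.approx(2 / 3)
        assert vals.loc[2.0] == pytest.approx(1 / 3)
        assert vals.loc[3.0] == pytest.approx(0.0)

    def test_no_events_flat_survival(self):
        surv, ch = km_nelson_aalen(np.array([1.0, 2.0]), np.zeros(2))
        assert (surv["survival"] == 1.0).all()
        assert (ch["cumhaz"] == 0.0).all()

    def test_nelson_aalen_increments(self):
        # 5 observations: events at 1, 2, 4; censored at 2+, 3+
        times = np.array([1.0, 2.0, 2.0, 3.0, 4.0])
        events = np.array([1, 1, 0, 0, 1])
        _, ch = km_nelson_aalen(times, events)
        vals = ch.set_index("time")["cumhaz"]
        assert vals.loc[1.0] == pytest.approx(1 / 5)
        assert vals.loc[2.0] == pytest.approx(1 / 5 + 1 / 4)
        assert vals.loc[4.0] == pytest.approx(1 / 5 + 1 / 4 + 1 / 1)


def brute_force_cox_beta(times, events, x):
    """Independent maximizer of the written Breslow partial likelihood."""
    times, events, x = map(np.asarray, (times, events, x))

    def nll(b):
        ll = 0.0
        for i in range(len(times)):
            if events[i]:
                risk = times >= times[i]
                ll += b * x[i] - np.log(np.sum(np.exp(b * x[risk])))
        return -ll

    grid = np.linspace(-5, 5, 501)
    b0 = grid[np.argmin([nll(b) for b in grid])]
    from scipy.optimize import minimize_scalar

    opt = minimize_scalar(nll, bounds=(b0 - 0.1, b0 + 0.1), method="bounded",
                          options={"xatol": 1e-12})
    return float(opt.x)


def cox_fixture():
    return pd.DataFrame({
        "time_s": [1.1, 2.3, 3.1, 4.7, 5.2, 6.9],
        "event": [1, 1, 0, 1, 1, 1],
        "x": [1.0, 0.0, 1.0, 0.0, 1.0, 0.0],
    })


class TestCoxFit:
    def test_matches_brute_force_partial_likelihood(self):
        df = cox_fixture()
        fit = cox_frailty_fit(df, ["x"], theta=0.0)
        expected = brute_force_cox_beta(df.time_s, df.event, df.x)
        assert fit.beta.iloc[0] == pytest.approx(expected, abs=1e-5)

    def test_score_vanishes_at_solution(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty", "similarity"],
                              group_col="subject_id")
        assert fit.score_norm < 1e-6
        assert fit.converged

    def test_replication_invariance_with_breslow_ties(self):
        df = cox_fixture()
        fit1 = cox_frailty_fit(df, ["x"], theta=0.0)
        fit2 = cox_frailty_fit(pd.concat([df, df], ignore_index=True),
                               ["x"], theta=0.0)
        assert fit1.beta.iloc[0] == pytest.approx(fit2.beta.iloc[0], abs=1e-6)

    def test_null_model_baseline_is_nelson_aalen(self):
        df = cox_fixture()
        fit = cox_frailty_fit(df, [])
        assert len(fit.beta) == 0
        _, ch = km_nelson_aalen(df.time_s.to_numpy(), df.event.to_numpy())
        na = ch.set_index("time")["cumhaz"]
        np.testing.assert_allclose(fit.baseline_cumhaz,
                                   na.loc[fit.baseline_times].to_numpy())

    def test_baseline_cumhaz_monotone_from_zero(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"], theta=0.0)
        assert fit.cumhaz_at(np.array([0.0]))[0] == 0.0
        assert np.all(np.diff(fit.baseline_cumhaz) > 0)

    def test_frailty_variance_continuity(self, small_survdata):
        plain = cox_frailty_fit(small_survdata, ["uncertainty", "similarity"],
                                theta=0.0)
        tiny = cox_frailty_fit(small_survdata, ["uncertainty", "similarity"],
                               group_col="subject_id", theta=1e-8)
        assert np.max(np.abs(plain.beta.to_numpy()
                             - tiny.beta.to_numpy())) < 1e-4

    def test_frailty_terms_average_to_unity(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"],
                              group_col="subject_id", theta=0.3)
        # penalized stationarity: e^xi = (1/theta + d_i) / (1/theta + A_i),
        # so fitted frailties stay near mean 1
        w = np.exp(fit.frailty.to_numpy())
        assert 0.5 < w.mean() < 1.5

    def test_requires_events(self):
        df = cox_fixture().assign(event=0)
        with pytest.raises(ValueError):
            cox_frailty_fit(df, ["x"])


class TestAnovaEffects:
    def test_plain_interaction_df_counts_contrasts(self, small_survdata):
        tab = anova_effects(small_survdata,
                            ["uncertainty", "similarity",
                             ("uncertainty", "similarity")])
        tab = tab.set_index("term")
        assert tab.loc["uncertainty", "df"] == pytest.approx(2.0)
        assert tab.loc["similarity", "df"] == pytest.approx(4.0)
        assert tab.loc["uncertainty:similarity", "df"] == pytest.approx(8.0)

    def test_frailty_row_and_noninteger_df(self, small_survdata):
        tab = anova_effects(small_survdata, ["uncertainty", "similarity"],
                            group_col="subject_id")
        assert "frailty" in set(tab.term)
        assert ((tab.p >= 0) & (tab.p <= 1)).all()
        assert (tab.df > 0).all()


class TestEmmeans:
    def test_single_factor_emmeans_equal_coefficients(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"], theta=0.0)
        emm = emmeans_log_hazard(fit, ["uncertainty"])
        np.testing.assert_allclose(
            emm.table.emmean.to_numpy(),
            np.concatenate([[0.0], fit.beta.to_numpy()]))

    def test_reference_cell_pinned_at_zero(self, small_survdata):
        fit = cox_frailty_fit(
            small_survdata,
            ["uncertainty", "similarity", ("uncertainty", "similarity")],
            theta=0.0)
        emm = emmeans_log_hazard(fit, ["uncertainty", "similarity"])
        ref = emm.table.iloc[0]
        assert ref.uncertainty == min(emm.table.uncertainty)
        assert ref.similarity == min(emm.table.similarity)
        assert ref.emmean == 0.0 and ref.se == 0.0

    def test_asymptotic_limits(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"], theta=0.0)
        emm = emmeans_log_hazard(fit, ["uncertainty"])
        z = stats.norm.ppf(0.975)
        np.testing.assert_allclose(emm.table.asymp_lcl,
                                   emm.table.emmean - z * emm.table.se)


def emm_fixture(means, ses):
    t = pd.DataFrame({"cell": range(len(means)), "emmean": means, "se": ses})
    z = stats.norm.ppf(0.975)
    t["asymp_lcl"] = t.emmean - z * t.se
    t["asymp_ucl"] = t.emmean + z * t.se
    return EmmGrid(table=t, cov=np.diag(np.square(ses)), factors=["cell"])


class TestTukeyCld:
    def test_identical_cells_share_one_letter(self):
        emm = emm_fixture([1.0, 1.0, 1.0], [0.2, 0.2, 0.2])
        out, _ = tukey_cld(emm)
        assert set(out[".group"]) == {"a"}

    def test_huge_separation_gets_disjoint_letters(self):
        emm = emm_fixture([0.0, 50.0], [0.1, 0.1])
        out, pairs = tukey_cld(emm)
        assert set(out[".group"]) == {"a", "b"}
        assert (pairs.p_adj < 1e-10).all()

    def test_two_cluster_fixture(self):
        emm = emm_fixture([0.0, 0.1, 2.0, 2.1], [0.05] * 4)
        out, pairs = tukey_cld(emm)
        g = out[".group"].tolist()
        assert g[0] == g[1] and g[2] == g[3] and g[0] != g[2]

    def test_letters_match_significance_graph(self, rng):
        # randomized fixtures: letters must cover exactly the
        # non-significant pairs and never join a significant one
        for k in [3, 5, 8, 12, 15]:
            emm = emm_fixture(rng.normal(0, 1, k), rng.uniform(0.1, 0.5, k))
            out, pairs = tukey_cld(emm, alpha=0.05)
            sig = {(int(r.i), int(r.j)) for r in pairs.itertuples()
                   if r.p_adj < 0.05}
            groups = out[".group"].tolist()
            for i in range(k):
                for j in range(i + 1, k):
                    share = bool(set(groups[i]) & set(groups[j]))
                    assert share == ((i, j) not in sig)

    def test_adjusted_exceeds_unadjusted_p(self, rng):
        emm = emm_fixture(rng.normal(0, 1, 6), rng.uniform(0.2, 0.4, 6))
        pairs = tukey_pairwise(emm)
        for r in pairs.itertuples():
            if np.isfinite(r.z) and r.z > 0:
                raw = 2 * stats.norm.sf(r.z)
                assert r.p_adj >= raw - 1e-12

    def test_rejects_single_cell(self):
        with pytest.raises(ValueError):
            tukey_pairwise(emm_fixture([1.0], [0.1]))


class TestCoxSnell:
    def test_residuals_nonnegative_and_censored_definition(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"],
                              group_col="subject_id", theta=0.3)
        res = cox_snell(fit, small_survdata)
        assert (res.residual >= 0).all()
        censored = small_survdata[small_survdata.event == 0].iloc[0]
        eta = (fit.linear_predictor(censored.to_dict())
               + fit.frailty[censored.subject_id])
        expected = np.exp(eta) * fit.cumhaz_at(
            np.array([censored.time_s]))[0]
        idx = small_survdata.reset_index(drop=True).index[
            (small_survdata.event == 0).to_numpy()][0]
        assert res.residual.iloc[idx] == pytest.approx(expected)
        assert res.event.iloc[idx] == 0

    def test_well_specified_slope_near_one(self, rng):
        n = 1500
        x = rng.integers(0, 2, n).astype(float)
        t = rng.exponential(1.0 / np.exp(0.7 * x))
        event = (t < 2.5).astype(int)
        df = pd.DataFrame({"time_s": np.minimum(t, 2.5), "event": event,
                           "x": x})
        fit = cox_frailty_fit(df, ["x"], theta=0.0)
        slope = cox_snell_slope(cox_snell(fit, df))
        assert 0.85 < slope < 1.15


class TestPredictCurves:
    def test_cdf_axioms(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"],
                              group_col="subject_id")
        pattern = dict(uncertainty=small_survdata.uncertainty.min())
        out = predict_curves(fit, pattern)
        assert out.cdf.iloc[0] == pytest.approx(0.0, abs=1e-12)
        assert np.all(np.diff(out.cdf) >= -1e-12)
        assert out.cdf.max() <= 1.0
        assert (out.hazard >= 0).all()

    def test_proportional_hazards_scaling(self, small_survdata):
        fit = cox_frailty_fit(small_survdata, ["uncertainty"], theta=0.0)
        lo = dict(uncertainty=sorted(fit.design.levels["uncertainty"])[0])
        hi = dict(uncertainty=sorted(fit.design.levels["uncertainty"])[2])
        a = predict_curves(fit, lo, conditional=True)
        b = predict_curves(fit, hi, conditional=True)
        ratio = np.exp(fit.linear_predictor(hi) - fit.linear_predictor(lo))
        mask = a.hazard > 1e-8
        np.testing.assert_allclose(b.hazard[mask] / a.hazard[mask], ratio,
                                   rtol=1e-8)

    def test_flat_hazard_for_exponential_null(self, rng):
        t = rng.exponential(1 / 0.3, 3000)
        df = pd.DataFrame({"time_s": np.minimum(t, 10.0),
                           "event": (t < 10.0).astype(int)})
        fit = cox_frailty_fit(df, [])
        out = predict_curves(fit, {}, t_grid=np.linspace(0, 10, 201))
        inner = out[(out.time_s > 2) & (out.time_s < 7)]
        assert np.abs(inner.hazard - 0.3).max() < 0.06


class TestOutlierRule:
    def test_flags_high_far_subject(self, rng):
        # 12 ordinary subjects plus one with a flawed (very high) FAR;
        # the rule needs enough subjects for a 2-SD excursion to exist
        dp = pd.DataFrame({
            "subject_id": [f"S{i:02d}" for i in range(12)] + ["S99"],
            "far": np.concatenate([0.2 + 0.05 * rng.standard_normal(12),
                                   [0.9]]),
        })
        assert flag_high_far_subjects(dp) == ["S99"]

    def test_no_flags_for_homogeneous_subjects(self, rng):
        dp = pd.DataFrame({
            "subject_id": [f"S{i:02d}" for i in range(10)],
            "far": 0.2 + 0.02 * rng.standard_normal(10),
        })
        assert flag_high_far_subjects(dp) == []


def test_survival_data_uses_onset_origin(small_records):
    df, _ = small_records
    sd = survival_data(categorize(df, "I"))
    assert sd.time_s.max() <= survival.HORIZON_S + 1e-9
    assert sd.time_s.min() > 0
    censored = sd[sd.event == 0]
    assert (censored.time_s == survival.HORIZON_S).all()
    assert set(sd.columns) >= {"time_s", "event", "uncertainty", "similarity"}
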