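"""Mixed models, penalized smooths, adherence logit, FDR, recovery."""

from __future__ import annotations

import numpy as np
import pandas as pd
import pytest

import medema as m
from medema import models as md
from medema.synthetic import ConfigError

from _brute import brute_bh


class TestFdrAdjust:
    def test_hand_computed_example(self):
        np.testing.assert_allclose(m.fdr_adjust([0.01, 0.02, 0.03]),
                                   [0.03, 0.03, 0.03])

    def test_single_pvalue_unchanged(self):
        assert m.fdr_adjust([0.2])[0] == pytest.approx(0.2)

    def test_ties_map_to_common_value(self):
        np.testing.assert_allclose(m.fdr_adjust([0.05, 0.05, 0.05]), [0.05] * 3)

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            m.fdr_adjust([0.5, 1.2])
        with pytest.raises(ValueError):
            m.fdr_adjust([-0.1])

    def test_matches_brute_force_step_up(self, rng):
        for _ in range(200):
            p = rng.random(rng.integers(1, 30))
            np.testing.assert_allclose(m.fdr_adjust(p), brute_bh(list(p)),
                                       atol=1e-12)

    def test_q_at_least_p_and_order_preserving(self, rng):
        p = rng.random(50)
        q = m.fdr_adjust(p)
        assert (q >= p - 1e-12).all()
        order = np.argsort(p)
        assert (np.diff(q[order]) >= -1e-12).all()


def _linear_table(n_users=80, seed=13, **cfg_kwargs):
    cfg = m.SimConfig(n_users=n_users, mean_sessions_per_user=12, max_sessions=30,
                      seed=seed, **cfg_kwargs)
    users, sessions, _ = m.simulate_streams(cfg)
    return m.build_feature_table(sessions, users, trim=False)


class TestLinearMixed:
    def test_intercept_only_balanced_equals_grand_mean(self):
        # balanced single-level design: GLS intercept is the grand mean
        rng = np.random.default_rng(3)
        df = pd.DataFrame({
            "user_id": np.repeat(np.arange(20), 6),
            "continent": "Europe",
            "outcome_mood": rng.normal(3.0, 0.5, size=120),
        })
        res = m.fit_linear_mixed(df, m.ModelSpec(outcome="outcome_mood"))
        assert res.table.loc[0, "estimate"] == pytest.approx(
            df["outcome_mood"].mean(), abs=1e-6)

    def test_nested_solver_matches_mixedlm(self):
        # independent route: statsmodels MixedLM with user variance
        # components inside continent groups
        table = _linear_table(n_users=60, session_effect=0.01)
        spec = m.ModelSpec(outcome="outcome_mood",
                           fixed_terms=("session_count", "days_per_week"))
        a = m.fit_linear_mixed(table, spec, engine="nested")
        b = m.fit_linear_mixed(table, spec, engine="mixedlm")
        for col in ("estimate", "ci_low", "ci_high"):
            np.testing.assert_allclose(a.table[col].to_numpy(),
                                       b.table[col].to_numpy(), atol=5e-3)
        assert a.random_effects["residual_var"] == pytest.approx(
            b.random_effects["residual_var"], rel=0.02)
        assert a.random_effects["user_intercept_var"] == pytest.approx(
            b.random_effects["user_intercept_var"], rel=0.15, abs=0.01)

    def test_positive_effect_recovered_with_positive_sign(self):
        table = _linear_table(n_users=200, session_effect=0.02, seed=17)
        spec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count",))
        res = m.fit_linear_mixed(table, spec)
        row = res.table.set_index("term").loc["session_count"]
        assert row["estimate"] > 0
        assert row["ci_low"] < row["estimate"] < row["ci_high"]

    def test_zero_variance_column_named(self):
        table = _linear_table()
        table["flat"] = 1.0
        spec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count", "flat"))
        with pytest.raises(ConfigError, match="flat"):
            m.fit_linear_mixed(table, spec)

    def test_rank_deficient_design_named(self):
        table = _linear_table()
        table["dup"] = 2.0 * table["session_count"]
        spec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count", "dup"))
        with pytest.raises(ConfigError, match="rank-deficient"):
            m.fit_linear_mixed(table, spec)

    def test_unknown_term_rejected(self):
        table = _linear_table()
        spec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("no_such_column",))
        with pytest.raises(ConfigError, match="no_such_column"):
            m.fit_linear_mixed(table, spec)

    def test_too_few_users_rejected(self):
        table = _linear_table().query("user_id == 0")
        with pytest.raises(ConfigError, match="2 users"):
            m.fit_linear_mixed(table, m.ModelSpec(outcome="outcome_mood"))

    def test_missing_ratio_rows_kept_with_indicator(self):
        table = _linear_table(n_users=120, seed=23)
        assert table["extero_intero_ratio"].isna().any()
        spec = m.ModelSpec(outcome="outcome_mood",
                           fixed_terms=("session_count", "extero_intero_ratio"))
        res = m.fit_linear_mixed(table, spec)
        assert res.n_rows == len(table)
        assert "ratio_missing_ind" in set(res.table["term"])
        res_cc = m.fit_linear_mixed(table, spec, ratio_missing="complete")
        assert res_cc.n_rows == int(table["extero_intero_ratio"].notna().sum())

    def test_irrelevant_covariate_barely_moves_estimate(self):
        table = _linear_table(n_users=150, session_effect=0.015, seed=31)
        table["noise_cov"] = np.random.default_rng(0).normal(size=len(table))
        spec0 = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count",))
        spec1 = m.ModelSpec(outcome="outcome_mood",
                            fixed_terms=("session_count", "noise_cov"))
        r0 = m.fit_linear_mixed(table, spec0).table.set_index("term").loc["session_count"]
        r1 = m.fit_linear_mixed(table, spec1).table.set_index("term").loc["session_count"]
        se0 = (r0["ci_high"] - r0["ci_low"]) / (2 * 1.96)
        assert abs(r1["estimate"] - r0["estimate"]) < se0

    def test_deterministic_given_table(self):
        table = _linear_table()
        spec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count",))
        a = m.fit_linear_mixed(table, spec).table
        b = m.fit_linear_mixed(table, spec).table
        pd.testing.assert_frame_equal(a, b)


class TestNonlinear:
    def test_zero_noise_zero_effect_flat_smooth(self):
        cfg = m.SimConfig(n_users=40, mean_sessions_per_user=20, noise_sd=0.0,
                          baseline_latent_sd=0.0, max_sessions=20,
                          churn_hazard=0.0, seed=5)
        users, sessions, _ = m.simulate_streams(cfg)
        table = m.build_feature_table(sessions, users, trim=False)
        spec = m.ModelSpec(outcome="outcome_mood", basis_df=6, alpha=1.0,
                           smooth_terms=(("session_count", None),),
                           support_cutoff=0.0)
        res = m.fit_nonlinear_mixed(table, spec)
        grid = res.smooths["s(session_count)"]
        assert np.max(np.abs(grid["fit"] - grid["fit"].mean())) < 1e-6

    def test_linear_truth_agrees_with_linear_fit(self):
        table = _linear_table(n_users=300, session_effect=0.02, seed=37)
        lspec = m.ModelSpec(outcome="outcome_mood", fixed_terms=("session_count",))
        lin = m.fit_linear_mixed(table, lspec).table.set_index("term")
        spec = m.ModelSpec(outcome="outcome_mood", basis_df=8,
                           smooth_terms=(("session_count", None),),
                           support_cutoff=0.001)
        res = m.fit_nonlinear_mixed(table, spec)
        grid = res.smooths["s(session_count)"]
        x = grid["session_count"].to_numpy()
        # the smooth is parameterized as a contrast against the axis origin,
        # so anchor both curves at the first grid point
        linear_pred = lin.loc["session_count", "estimate"] * (x - x[0])
        anchored = grid["fit"] - grid["fit"].iloc[0]
        half_ci = (grid["ci_high"] - grid["ci_low"]) / 2
        assert (np.abs(anchored - linear_pred) <= half_ci + 0.02).all()

    def test_by_factor_produces_per_level_curves(self):
        table = _linear_table(n_users=250, session_effect=0.02, seed=41)
        spec = m.ModelSpec(outcome="outcome_mood", basis_df=6,
                           smooth_terms=(("session_count", "days_per_week_level"),),
                           min_level_rows=30, support_cutoff=0.001)
        res = m.fit_nonlinear_mixed(table, spec)
        assert len(res.smooths) >= 2
        for grid in res.smooths.values():
            assert {"fit", "ci_low", "ci_high"} <= set(grid.columns)

    def test_insufficient_support_levels_dropped(self):
        table = _linear_table(n_users=40, seed=43)
        spec = m.ModelSpec(outcome="outcome_mood", basis_df=6,
                           smooth_terms=(("session_count", "days_per_week_level"),),
                           min_level_rows=10**6)
        with pytest.raises(ConfigError, match="support"):
            m.fit_nonlinear_mixed(table, spec)


class TestAdherenceLogit:
    def test_odds_ratio_recovered_single_fit(self):
        cohort = m.simulate_adherence_cohort(2000, seed=3)
        spec = m.ModelSpec(outcome="adherent", family="binomial",
                           fixed_terms=("days_per_week_level", "length_bin",
                                        "practice_types_bin", "baseline_mood"))
        res = m.fit_adherence_logit(cohort, spec)
        row = res.table.set_index("term").loc[
            "C(days_per_week_level, Treatment('1'))[T.4-7]"]
        assert 1.6 <= row["odds_ratio"] <= 2.5
        assert row["or_ci_low"] <= 2.0 <= row["or_ci_high"]

    def test_null_labels_rarely_significant(self):
        # FDR control under the global null across seeded replicates
        spec = m.ModelSpec(outcome="adherent", family="binomial",
                           fixed_terms=("days_per_week_level", "length_bin"))
        n_sig = 0
        reps = 40
        for s in range(reps):
            cohort = m.simulate_adherence_cohort(
                500, days_per_week_effects={}, seed=1000 + s)
            res = m.fit_adherence_logit(cohort, spec)
            body = res.table[res.table["term"] != "Intercept"]
            if (body["q"] < 0.05).any():
                n_sig += 1
        assert n_sig <= 0.05 * reps + 2

    def test_single_class_rejected(self):
        cohort = m.simulate_adherence_cohort(200, seed=1)
        cohort["adherent"] = True
        spec = m.ModelSpec(outcome="adherent", family="binomial")
        with pytest.raises(ConfigError, match="classes"):
            m.fit_adherence_logit(cohort, spec)

    def test_zero_variance_factor_named(self):
        cohort = m.simulate_adherence_cohort(200, seed=1)
        cohort["length_bin"] = pd.Categorical(["5-10"] * len(cohort),
                                              categories=["5-10", "11-20", "21-30"])
        spec = m.ModelSpec(outcome="adherent", family="binomial",
                           fixed_terms=("days_per_week_level", "length_bin"))
        with pytest.raises(ConfigError, match="length_bin"):
            m.fit_adherence_logit(cohort, spec)

    def test_complete_separation_flagged_not_raised(self):
        rng = np.random.default_rng(2)
        x = rng.normal(size=200)
        df = pd.DataFrame({"x": x, "adherent": x > 0})
        spec = m.ModelSpec(outcome="adherent", family="binomial", fixed_terms=("x",))
        res = m.fit_adherence_logit(df, spec)
        assert not res.converged
        assert res.diagnostic != ""


class TestRecoveryReport:
    def _reps(self, est, lo, hi, n=25):
        return [{"theta": (est, lo, hi)} for _ in range(n)]

    def test_perfect_estimator(self):
        rep = m.recovery_report({"theta": 1.5}, self._reps(1.5, 1.4, 1.6))
        row = rep.per_parameter.iloc[0]
        assert row["coverage"] == 1.0
        assert row["bias"] == 0.0
        assert row["rmse"] == 0.0

    def test_offset_estimator_bias_exact(self):
        rep = m.recovery_report({"theta": 2.0}, self._reps(2.3, 2.2, 2.4))
        row = rep.per_parameter.iloc[0]
        assert row["bias"] == pytest.approx(0.3)
        assert row["coverage"] == 0.0

    def test_requires_twenty_replicates(self):
        with pytest.raises(ConfigError, match="20"):
            m.recovery_report({"theta": 1.0}, self._reps(1.0, 0.9, 1.1, n=5))

    def test_wellspecified_coverage_near_nominal_small(self):
        # scaled-down replicate study keeps the full path honest; the
        # full-size study runs in the acceptance suite
        rep = m.linear_recovery_study(n_replicates=25, n_users=120, seed=99)
        cov = rep.per_parameter.iloc[0]["coverage"]
        assert cov >= 0.8
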