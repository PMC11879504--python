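"""Cohort statistics: scoring, winsorization, correlations, FDR, regression."""

import itertools

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from statsmodels.stats.multitest import multipletests

from emovis.stats import (
    MssbScores,
    SingularDesignError,
    bh_fdr,
    correlation_table,
    cronbach_alpha,
    default_item_map,
    detect_and_winsorize,
    effect_gate,
    ols_fit,
    pearson_ci,
    robust_fit,
    score_mssb,
)
from emovis.synthetic import CohortSpec, simulate_cohort


class TestScoreMssb:
    def test_all_endorsed_reaches_subscale_ceilings(self):
        responses = {f"q{i}": 1 for i in range(1, 39)}
        s = score_mssb(responses)
        assert (s.positive, s.negative, s.disorganized) == (13, 13, 12)
        assert s.overall == 38

    def test_none_endorsed_scores_zero(self):
        responses = {f"q{i}": 0 for i in range(1, 39)}
        s = score_mssb(responses)
        assert (s.positive, s.negative, s.disorganized, s.overall) == (0, 0, 0, 0)

    def test_wrong_partition_is_config_error(self):
        bad = default_item_map()
        bad["q14"] = "positive"  # 14 positive / 12 negative
        with pytest.raises(ValueError, match="partition"):
            score_mssb({f"q{i}": 0 for i in range(1, 39)}, bad)

    def test_missing_items_rejected_no_imputation(self):
        responses = {f"q{i}": 0 for i in range(1, 38)}  # q38 missing
        with pytest.raises(ValueError, match="missing"):
            score_mssb(responses)

    def test_nonbinary_response_rejected(self):
        responses = {f"q{i}": 0 for i in range(1, 39)}
        responses["q5"] = 3
        with pytest.raises(ValueError, match="non-binary"):
            score_mssb(responses)

    def test_overall_is_sum_of_subscales(self):
        assert MssbScores(3, 4, 5).overall == 12


class TestWinsorize:
    def test_single_far_high_point_replaced_with_next_largest(self):
        vals = np.array([1.0, 1.1, 1.2, 1.3, 1.25, 1.15, 9.0])
        out, n_rep, idx = detect_and_winsorize(vals)
        assert n_rep == 1 and list(idx) == [6]
        assert out[6] == 1.3  # next-largest original value
        assert np.array_equal(out[:6], vals[:6])

    def test_no_outliers_leaves_values_unchanged(self):
        vals = np.array([1.0, 1.1, 1.2, 1.3, 1.4])
        out, n_rep, idx = detect_and_winsorize(vals)
        assert n_rep == 0 and np.array_equal(out, vals)

    def test_identical_values_degenerate_iqr_unchanged(self):
        vals = np.full(10, 2.5)
        out, n_rep, _ = detect_and_winsorize(vals)
        assert n_rep == 0 and np.array_equal(out, vals)

    def test_low_side_outlier_replaced_with_smallest_kept(self):
        vals = np.array([5.0, 5.1, 5.2, 5.3, 5.15, -40.0])
        out, n_rep, _ = detect_and_winsorize(vals)
        assert n_rep == 1 and out[5] == 5.0

    def test_too_few_values_rejected(self):
        with pytest.raises(ValueError):
            detect_and_winsorize([1.0, 2.0])


class TestPearsonCi:
    def test_perfect_correlation(self):
        x = np.arange(10.0)
        res = pearson_ci(x, 2 * x + 1)
        assert res.r == pytest.approx(1.0)

    def test_fisher_z_interval_at_r041_n37(self):
        # plant r = 0.41 exactly via orthogonal construction at n = 37
        rng = np.random.default_rng(0)
        x = rng.standard_normal(37)
        e = rng.standard_normal(37)
        x -= x.mean()
        e -= e.mean()
        e -= e @ x / (x @ x) * x  # orthogonalize against centred x
        x /= x.std()
        e /= e.std()
        y = 0.41 * x + np.sqrt(1 - 0.41**2) * e
        res = pearson_ci(x, y)
        assert res.r == pytest.approx(0.41, abs=1e-6)
        # Fisher-z arithmetic: tanh(atanh(.41) +/- 1.96/sqrt(34))
        assert res.ci_low == pytest.approx(0.0992, abs=0.002)
        assert res.ci_high == pytest.approx(0.648, abs=0.002)
        assert res.passes_effect_gate

    def test_type_i_error_calibration(self):
        rng = np.random.default_rng(1)
        n, reps = 200, 1000
        hits = sum(
            pearson_ci(rng.standard_normal(n), rng.standard_normal(n)).p < 0.05
            for _ in range(reps)
        )
        assert hits / reps == pytest.approx(0.05, abs=0.02)

    def test_zero_variance_is_undefined(self):
        with pytest.raises(ValueError, match="variance"):
            pearson_ci(np.ones(10), np.arange(10.0))


class TestEffectGate:
    @pytest.mark.parametrize(
        "r,expected", [(0.41, True), (0.26, False), (-0.30, True), (0.0, False)]
    )
    def test_medium_effect_threshold(self, r, expected):
        assert effect_gate(r) is expected

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            effect_gate(1.5)


def _bh_oracle(p, q):
    """Direct evaluation of the step-up definition, one rank at a time."""
    p = np.asarray(p, dtype=float)
    m = len(p)
    order = np.argsort(p, kind="stable")
    sorted_p = p[order]
    adj_sorted = [
        min(min(sorted_p[j] * m / (j + 1) for j in range(i, m)), 1.0) for i in range(m)
    ]
    adj = np.empty(m)
    adj[order] = adj_sorted
    return adj, adj <= q


class TestBhFdr:
    def test_single_p_is_unchanged(self):
        adj, flags = bh_fdr([0.03])
        assert adj[0] == 0.03 and flags[0]

    def test_hand_computed_step_up(self):
        adj, _ = bh_fdr([0.01, 0.02, 0.03, 0.04])
        assert np.allclose(adj, [0.04, 0.04, 0.04, 0.04])

    def test_ties_get_identical_adjusted_values(self):
        adj, _ = bh_fdr([0.02, 0.02, 0.02])
        assert adj[0] == adj[1] == adj[2]

    def test_input_order_stability(self):
        p = [0.04, 0.001, 0.3, 0.02]
        adj, _ = bh_fdr(p)
        perm = [1, 3, 0, 2]
        adj2, _ = bh_fdr([p[i] for i in perm])
        assert np.allclose([adj[i] for i in perm], adj2)

    def test_matches_brute_force_oracle_on_exhaustive_small_cases(self):
        grid = [0.001, 0.008, 0.02, 0.049, 0.051, 0.2, 0.6, 1.0]
        for size in range(1, 5):
            for combo in itertools.combinations_with_replacement(grid, size):
                p = np.array(combo)
                adj, flags = bh_fdr(p, q=0.05)
                adj_o, flags_o = _bh_oracle(p, 0.05)
                assert np.allclose(adj, adj_o), combo
                assert np.array_equal(flags, flags_o), combo

    @given(st.lists(st.floats(0, 1), min_size=1, max_size=12))
    @settings(max_examples=100, deadline=None)
    def test_matches_statsmodels_reference(self, p):
        adj, flags = bh_fdr(p, q=0.05)
        ref_flags, ref_adj, _, _ = multipletests(p, alpha=0.05, method="fdr_bh")
        assert np.allclose(adj, ref_adj)
        assert np.array_equal(flags, ref_flags)

    def test_invalid_p_rejected(self):
        with pytest.raises(ValueError):
            bh_fdr([0.5, 1.2])

    def test_adjusted_never_below_raw(self):
        p = np.linspace(0.001, 0.9, 9)
        adj, _ = bh_fdr(p)
        assert np.all(adj >= p - 1e-12)


class TestRegression:
    def _cohort(self, n=37, seed=0):
        rng = np.random.default_rng(seed)
        X = rng.standard_normal((n, 3))
        y = 1.0 + X @ [0.5, -0.3, 0.2] + rng.standard_normal(n)
        return y, X

    def test_exact_linear_data_r2_one(self):
        rng = np.random.default_rng(2)
        X = rng.standard_normal((20, 2))
        y = 3.0 + X @ [1.0, 2.0]
        res = ols_fit(y, X)
        assert res.r_squared == pytest.approx(1.0)

    def test_df_bookkeeping_n37_three_predictors(self):
        res = ols_fit(*self._cohort())
        assert (res.df_model, res.df_resid) == (3, 33)
        assert res.df_model + res.df_resid + 1 == 37

    def test_rank_deficient_design_rejected(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((30, 2))
        X = np.column_stack([X, X[:, 0] * 2.0])
        with pytest.raises(SingularDesignError):
            ols_fit(rng.standard_normal(30), X)

    def test_coefficient_recovery_within_three_ses(self):
        import statsmodels.api as sm

        rng = np.random.default_rng(4)
        misses = 0
        reps = 200
        for _ in range(reps):
            n = 500
            X = rng.standard_normal((n, 3))
            beta = rng.normal(0, 1, 3)
            y = X @ beta + rng.standard_normal(n)
            fit = sm.OLS(y, sm.add_constant(X)).fit()
            misses += np.any(np.abs(fit.params[1:] - beta) > 3 * fit.bse[1:])
        assert misses / reps <= 0.05

    def test_robust_matches_ols_on_clean_data(self):
        y, X = self._cohort(n=200, seed=5)
        o = ols_fit(y, X)
        r = robust_fit(y, X)
        for key in o.betas:
            assert r.betas[key] == pytest.approx(o.betas[key], abs=0.05)

    def test_robust_slope_bounded_influence_under_gross_outlier(self):
        rng = np.random.default_rng(6)
        n = 50
        x = rng.standard_normal(n)
        y = 2.0 * x + 0.2 * rng.standard_normal(n)
        o_clean = ols_fit(y, x.reshape(-1, 1))
        y_out = y.copy()
        y_out[0] += 50.0
        o_dirty = ols_fit(y_out, x.reshape(-1, 1))
        r_dirty = robust_fit(y_out, x.reshape(-1, 1))
        key = [k for k in o_clean.betas if k != "const"][0]
        ols_shift = abs(o_dirty.betas[key] - o_clean.betas[key])
        robust_shift = abs(r_dirty.betas[key] - o_clean.betas[key])
        assert robust_shift < 0.2 * ols_shift

    def test_robust_fit_deterministic(self):
        y, X = self._cohort(seed=7)
        a, b = robust_fit(y, X), robust_fit(y, X)
        assert a.betas == b.betas and a.beta_p == b.beta_p

    def test_residual_qq_flag_on_normal_residuals(self):
        res = ols_fit(*self._cohort(n=200, seed=8))
        assert res.residual_qq_ok


class TestCohortPipeline:
    def test_planted_r041_recovered_and_gated_at_n2000(self):
        spec = CohortSpec(
            n_participants=2000,
            target_correlations={("disorganized", "va_neg_arcmin"): 0.41},
            seed=21,
        )
        df = simulate_cohort(spec)
        tab = correlation_table(df, ["disorganized"], ["va_neg_arcmin"])
        row = tab.iloc[0]
        band = 1.96 / np.sqrt(2000 - 3)
        assert abs(np.arctanh(row.r) - np.arctanh(0.41)) <= band
        assert row.gate and row.significant

    def test_null_cohort_rarely_fires_gate(self):
        fires = 0
        reps = 200
        for i in range(reps):
            df = simulate_cohort(CohortSpec(n_participants=2000, seed=1000 + i))
            tab = correlation_table(df, ["disorganized"], ["va_neg_arcmin"])
            fires += bool(tab.iloc[0].significant)
        assert fires / reps <= 0.07

    def test_family_wise_fdr_applied_per_outcome_group(self):
        df = simulate_cohort(CohortSpec(n_participants=100, seed=2))
        fams = {"va_neg_arcmin": "va", "t1_ms": "saccadic", "isl_ms": "saccadic"}
        tab = correlation_table(
            df, ["positive", "disorganized"], ["va_neg_arcmin", "t1_ms", "isl_ms"], fams
        )
        assert set(tab["family"]) == {"va", "saccadic"}
        assert (tab["p_fdr"] >= tab["p"] - 1e-12).all()


def test_cronbach_alpha_on_parallel_items():
    rng = np.random.default_rng(9)
    latent = rng.standard_normal(500)
    items = np.column_stack([latent + rng.standard_normal(500) for _ in range(10)])
    assert 0.6 < cronbach_alpha(items) < 0.95
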