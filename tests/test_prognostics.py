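import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy import stats
from scipy.stats import hypergeom

from dwma.prognostics import (
    ContingencyTable,
    PrognosticsError,
    bootstrap_bca_ci,
    classify_global_abnormality,
    cohen_kappa,
    cohen_kappa_from_table,
    dichotomize_severe,
    exact_binomial_ci,
    fisher_exact,
    logistic_fit,
    ols_fit,
    prognostic_properties,
)


class TestGlobalCategories:
    @pytest.mark.parametrize(
        "score,expected",
        [(0, "normal"), (3, "normal"), (4, "mild"), (7, "mild"),
         (8, "moderate"), (11, "moderate"), (12, "severe"), (30, "severe")],
    )
    def test_category_boundaries(self, score, expected):
        assert classify_global_abnormality(score) == expected

    def test_negative_rejected(self):
        with pytest.raises(PrognosticsError):
            classify_global_abnormality(-1)


class TestDichotomize:
    def test_ten_distinct_values_flag_one(self):
        flags = dichotomize_severe(np.arange(10.0))
        assert flags.sum() == 1 and flags[-1]

    def test_all_equal_flags_none(self):
        assert not dichotomize_severe([0.5] * 20).any()

    @given(st.lists(st.floats(0, 1, allow_nan=False), min_size=1, max_size=60))
    def test_matches_sort_based_oracle(self, values):
        values = np.asarray(values)
        n = len(values)
        # linear-interpolation percentile computed from sorted order statistics
        s = np.sort(values)
        h = (n - 1) * 0.9
        lo = int(np.floor(h))
        cut = s[lo] + (h - lo) * (s[min(lo + 1, n - 1)] - s[lo])
        np.testing.assert_array_equal(dichotomize_severe(values), values > cut)

    def test_empty_rejected(self):
        with pytest.raises(PrognosticsError):
            dichotomize_severe([])


class TestPrognosticProperties:
    """2x2 prognostic test properties of DWMA and sMRI predictors of CP."""

    def test_objective_severe_dwma_row(self):
        p = prognostic_properties(ContingencyTable(4, 2, 4, 72))
        assert p.sensitivity * 100 == pytest.approx(66.7, abs=0.05)
        assert p.specificity * 100 == pytest.approx(94.7, abs=0.05)
        assert p.lr_pos == pytest.approx(12.7, abs=0.05)
        assert p.lr_neg == pytest.approx(0.35, abs=0.005)
        assert p.fisher_p < 0.001

    def test_global_abnormality_row(self):
        p = prognostic_properties(ContingencyTable(3, 3, 3, 73))
        assert p.lr_pos == pytest.approx(12.7, abs=0.05)
        assert p.lr_neg == pytest.approx(0.52, abs=0.005)

    def test_visual_severe_dwma_row(self):
        p = prognostic_properties(ContingencyTable(1, 5, 10, 66))
        assert p.lr_pos == pytest.approx(1.27, abs=0.005)
        assert p.lr_neg == pytest.approx(0.96, abs=0.005)
        assert p.fisher_p == pytest.approx(1.0, abs=1e-6)

    def test_perfect_specificity_gives_infinite_lr(self):
        p = prognostic_properties(ContingencyTable(3, 1, 0, 10))
        assert np.isinf(p.lr_pos)

    def test_missing_outcome_class_rejected(self):
        with pytest.raises(PrognosticsError):
            prognostic_properties(ContingencyTable(0, 0, 5, 5))


class TestExactBinomialCI:
    def test_table_printed_bounds(self):
        lo, hi = exact_binomial_ci(4, 6)
        assert lo * 100 == pytest.approx(22.3, abs=0.05)
        assert hi * 100 == pytest.approx(95.7, abs=0.05)
        assert exact_binomial_ci(1, 6)[0] == pytest.approx(0.0042, abs=5e-5)

    def test_degenerate_endpoints(self):
        assert exact_binomial_ci(0, 10)[0] == 0.0
        assert exact_binomial_ci(10, 10)[1] == 1.0

    @given(n=st.integers(1, 40), frac=st.floats(0, 1))
    def test_endpoints_satisfy_tail_equations(self, n, frac):
        x = int(round(frac * n))
        lo, hi = exact_binomial_ci(x, n)
        if 0 < x:
            assert 1 - stats.binom.cdf(x - 1, n, lo) == pytest.approx(0.025, abs=1e-9)
        if x < n:
            assert stats.binom.cdf(x, n, hi) == pytest.approx(0.025, abs=1e-9)

    def test_invalid_counts(self):
        with pytest.raises(PrognosticsError):
            exact_binomial_ci(5, 4)


def _fisher_enumeration(tp, fn, fp, tn):
    """Sum hypergeometric probabilities of tables at most as probable."""
    row1, col1, n = tp + fn, tp + fp, tp + fn + fp + tn
    p_obs = hypergeom.pmf(tp, n, row1, col1)
    total = 0.0
    for a in range(max(0, row1 + col1 - n), min(row1, col1) + 1):
        p = hypergeom.pmf(a, n, row1, col1)
        if p <= p_obs * (1 + 1e-7):
            total += p
    return min(total, 1.0)


class TestFisherExact:
    def test_symmetric_table(self):
        assert fisher_exact(ContingencyTable(1, 1, 1, 1)) == pytest.approx(1.0)

    def test_severe_dwma_table_significant(self):
        assert fisher_exact(ContingencyTable(4, 2, 4, 72)) < 0.001

    @given(
        st.tuples(
            st.integers(0, 30), st.integers(0, 30),
            st.integers(0, 70), st.integers(0, 70),
        ).filter(lambda t: sum(t) > 0)
    )
    def test_equals_enumeration_oracle(self, counts):
        table = ContingencyTable(*counts)
        assert fisher_exact(table) == pytest.approx(
            _fisher_enumeration(*counts), abs=1e-9
        )


class TestKappa:
    def test_intra_rater_worked_example(self):
        res = cohen_kappa(0.60, 0.31)
        assert res.kappa == pytest.approx(0.42, abs=0.005)

    def test_degenerate_values(self):
        assert cohen_kappa(0.5, 0.5).kappa == 0.0
        assert cohen_kappa(1.0, 0.3).kappa == 1.0

    def test_table_form_equals_formula_form(self, rng):
        m = rng.integers(0, 20, size=(4, 4))
        m[0, 0] += 1  # non-empty
        res = cohen_kappa_from_table(m)
        total = m.sum()
        p_o = np.trace(m) / total
        p_e = sum(m[i, :].sum() * m[:, i].sum() for i in range(4)) / total**2
        assert res.kappa == pytest.approx(cohen_kappa(p_o, p_e).kappa, rel=1e-12)

    def test_invalid_inputs(self):
        with pytest.raises(PrognosticsError):
            cohen_kappa(0.5, 1.0)
        with pytest.raises(PrognosticsError):
            cohen_kappa_from_table(np.zeros((2, 3)))


class TestOLS:
    def test_exact_linear_data(self, rng):
        X = rng.normal(size=(30, 2))
        y = 1.0 + 2.0 * X[:, 0] - 3.0 * X[:, 1]
        res = ols_fit(X, y, ["a", "b"])
        assert res.r2 == pytest.approx(1.0)
        np.testing.assert_allclose(res.coef, [1.0, 2.0, -3.0], atol=1e-10)

    def test_matches_normal_equations_oracle(self, rng):
        X = rng.normal(size=(20, 3))
        y = rng.normal(size=20)
        res = ols_fit(X, y, list("abc"), add_intercept=False)
        beta = np.linalg.solve(X.T @ X, X.T @ y)
        np.testing.assert_allclose(res.coef, beta, atol=1e-8)
        # classical SEs from the oracle too
        resid = y - X @ beta
        s2 = resid @ resid / (20 - 3)
        se = np.sqrt(np.diag(s2 * np.linalg.inv(X.T @ X)))
        np.testing.assert_allclose(res.se, se, atol=1e-8)

    def test_adjusted_r2_relation(self, rng):
        X = rng.normal(size=(50, 3))
        y = X[:, 0] + rng.normal(size=50)
        res = ols_fit(X, y)
        n, p = 50, 3
        expect = 1 - (1 - res.r2) * (n - 1) / (n - p - 1)
        assert res.r2_adj == pytest.approx(expect, rel=1e-10)
        assert res.r2_adj <= res.r2

    def test_rank_deficiency_rejected(self, rng):
        x = rng.normal(size=20)
        X = np.column_stack([x, 2 * x])
        with pytest.raises(PrognosticsError, match="rank"):
            ols_fit(X, rng.normal(size=20))


class TestLogistic:
    def test_null_effect_ci_coverage(self):
        covered = 0
        for seed in range(50):
            r = np.random.default_rng(seed)
            x = r.normal(size=2000)
            y = r.integers(0, 2, size=2000)
            res = logistic_fit(x, y, ["x"])
            i = res.names.index("x")
            covered += res.or_ci_low[i] <= 1.0 <= res.or_ci_high[i]
        assert covered >= 45

    def test_single_class_rejected(self):
        with pytest.raises(PrognosticsError):
            logistic_fit(np.arange(20.0), np.zeros(20))

    def test_complete_separation_rejected(self):
        x = np.concatenate([-np.arange(1, 20.0), np.arange(1, 20.0)])
        y = (x > 0).astype(float)
        with pytest.raises(PrognosticsError, match="separation"):
            logistic_fit(x, y)


class TestBootstrap:
    def test_constant_statistic_returns_point(self, rng):
        sample = rng.normal(size=30)
        with pytest.warns(UserWarning, match="degenerate"):
            lo, hi = bootstrap_bca_ci(sample, lambda s: 7.0, B=1000, seed=0)
        assert lo == hi == 7.0

    def test_same_seed_identical(self, rng):
        sample = rng.normal(size=40)
        a = bootstrap_bca_ci(sample, np.mean, B=2000, seed=5)
        b = bootstrap_bca_ci(sample, np.mean, B=2000, seed=5)
        assert a == b

    def test_mean_interval_coverage(self):
        hits = 0
        reps = 300
        for seed in range(reps):
            r = np.random.default_rng(seed)
            sample = r.normal(0.0, 1.0, 50)
            lo, hi = bootstrap_bca_ci(sample, np.mean, B=1000, seed=seed + 1)
            hits += lo <= 0.0 <= hi
        assert 0.90 * reps <= hits <= 0.99 * reps

    def test_bca_option_close_to_bc_for_symmetric_statistic(self, rng):
        sample = rng.normal(size=60)
        bc = bootstrap_bca_ci(sample, np.mean, B=2000, seed=3, method="bc")
        bca = bootstrap_bca_ci(sample, np.mean, B=2000, seed=3, method="bca")
        assert bc[0] == pytest.approx(bca[0], abs=0.1)

    def test_small_sample_rejected(self, rng):
        with pytest.raises(PrognosticsError):
            bootstrap_bca_ci(rng.normal(size=5), np.mean, seed=0)
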