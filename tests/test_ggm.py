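"""Correlation estimation, Fisher-z significance and stability diagnostics."""

import math

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from ggmetab.ggm import (
    DegenerateDataError,
    GaussianGraphicalModel,
    IllConditionedError,
    bonferroni_alpha,
    bootstrap_stability,
    edge_table,
    fisher_pvalue,
    fit_ggm,
    low_order_partial,
    partial_matrix,
    pearson_matrix,
    significance_cutoff,
    subsample_stability,
)

from conftest import chain_precision, mvn_from_precision


def residual_partial_oracle(X: np.ndarray) -> np.ndarray:
    """Independent oracle: partial correlation as the Pearson correlation of
    the residuals from regressing each pair of columns on all the others."""
    n, m = X.shape
    Z = np.eye(m)
    Xc = X - X.mean(axis=0)
    for i in range(m):
        for j in range(i + 1, m):
            rest = [k for k in range(m) if k not in (i, j)]
            A = Xc[:, rest]
            ri = Xc[:, i] - A @ np.linalg.lstsq(A, Xc[:, i], rcond=None)[0]
            rj = Xc[:, j] - A @ np.linalg.lstsq(A, Xc[:, j], rcond=None)[0]
            Z[i, j] = Z[j, i] = np.corrcoef(ri, rj)[0, 1]
    return Z


class TestPearson:
    def test_duplicated_column_perfect_correlation(self):
        rng = np.random.default_rng(0)
        x = rng.normal(size=100)
        X = np.column_stack([x, x, rng.normal(size=100)])
        P = pearson_matrix(X)
        assert P[0, 1] == pytest.approx(1.0)

    def test_negated_column_anticorrelated(self):
        rng = np.random.default_rng(1)
        x = rng.normal(size=100)
        P = pearson_matrix(np.column_stack([x, -x]))
        assert P[0, 1] == pytest.approx(-1.0)

    def test_independent_columns_near_zero(self):
        rng = np.random.default_rng(2)
        P = pearson_matrix(rng.standard_normal((10_000, 4)))
        off = P[~np.eye(4, dtype=bool)]
        assert np.all(np.abs(off) < 0.05)  # 3 / sqrt(n) bound

    def test_zero_variance_column_named(self):
        X = pd.DataFrame({"a": [1.0, 2.0, 3.0, 4.0], "flat": [1.0, 1.0, 1.0, 1.0]})
        with pytest.raises(DegenerateDataError, match="flat"):
            pearson_matrix(X)


class TestPartialMatrix:
    def test_two_variables_partial_equals_pearson(self):
        rng = np.random.default_rng(3)
        X = rng.standard_normal((200, 2))
        P = pearson_matrix(X)
        Z = partial_matrix(P)
        assert Z[0, 1] == pytest.approx(P[0, 1], abs=1e-12)

    def test_matches_regression_residual_oracle(self):
        rng = np.random.default_rng(4)
        for _ in range(10):
            X = rng.standard_normal((200, 10))
            Z = partial_matrix(pearson_matrix(X))
            np.testing.assert_allclose(Z, residual_partial_oracle(X), atol=1e-8)

    def test_ill_conditioned_matrix_rejected(self):
        rng = np.random.default_rng(5)
        X = rng.standard_normal((6, 10))  # n < m: singular correlation matrix
        with pytest.raises(IllConditionedError):
            partial_matrix(pearson_matrix(X))

    def test_chain_ensemble_discriminates_direct_edges(self, chain_reversible_ensemble):
        res = fit_ggm(chain_reversible_ensemble)
        a, b, c = 0, 1, 2
        assert res.p_partial[a, b] <= res.alpha_adj and res.Z[a, b] > 0
        assert res.p_partial[b, c] <= res.alpha_adj and res.Z[b, c] > 0
        assert abs(res.Z[a, c]) < min(res.Z[a, b], res.Z[b, c]) / 3


class TestLowOrderPartial:
    def test_three_variables_order_one_equals_full(self):
        X = mvn_from_precision(chain_precision(3, 0.4), 800, seed=6)
        Z1, _ = low_order_partial(X, q=1)
        Zf = partial_matrix(pearson_matrix(X))
        np.testing.assert_allclose(Z1, Zf, atol=1e-10)

    def test_order_one_formula(self):
        # against the printed first-order recursion on the correlation matrix
        X = mvn_from_precision(chain_precision(4, 0.3), 500, seed=7)
        P = pearson_matrix(X)
        Z1, _ = low_order_partial(X, q=1)
        i, j = 0, 1
        vals = []
        for k in (2, 3):
            vals.append(
                (P[i, j] - P[i, k] * P[j, k])
                / math.sqrt((1 - P[i, k] ** 2) * (1 - P[j, k] ** 2))
            )
        assert Z1[i, j] == pytest.approx(min(vals, key=abs), abs=1e-12)

    def test_uncorrelated_conditioners_reduce_to_pearson(self):
        # if rho_ik = rho_jk = 0 for every k, the order-1 value equals rho_ij
        rng = np.random.default_rng(8)
        z = rng.standard_normal(20000)
        x = z + 0.5 * rng.standard_normal(20000)
        y = z + 0.5 * rng.standard_normal(20000)
        w = rng.standard_normal(20000)  # independent of all
        X = np.column_stack([x, y, w])
        P = pearson_matrix(X)
        Z1, _ = low_order_partial(X, q=1)
        assert Z1[0, 1] == pytest.approx(P[0, 1], abs=0.02)

    def test_diamond_motif_differs_from_full_order(self):
        # parallel-branch structure: conditioning on a single node cannot
        # block both paths, so low-order and full-order edge sets differ
        omega = np.eye(4)
        for i, j in [(0, 1), (0, 2), (1, 3), (2, 3)]:
            omega[i, j] = omega[j, i] = -0.35
        X = mvn_from_precision(omega, 4000, seed=9)
        alpha_adj = bonferroni_alpha(0.01, 6)
        Z1, keep1 = low_order_partial(X, q=1, alpha_adj=alpha_adj)
        res = fit_ggm(X)
        full_edges = res.significant_partial("both")
        assert not np.array_equal(keep1, full_edges)
        assert keep1[0, 3] or keep1[1, 2]  # indirect pair survives low order

    def test_invalid_order_rejected(self):
        X = np.random.default_rng(0).standard_normal((50, 4))
        with pytest.raises(ValueError):
            low_order_partial(X, q=3)  # q >= m - 1


class TestFisherSignificance:
    def test_zero_correlation_p_one(self):
        assert fisher_pvalue(0.0, 100, 0) == 1.0

    @settings(deadline=None, derandomize=True)
    @given(st.floats(-0.999, 0.999), st.integers(20, 5000), st.integers(0, 10))
    def test_two_sided_symmetry_and_range(self, zeta, n, q):
        p = fisher_pvalue(zeta, n, q)
        assert 0.0 <= p <= 1.0
        assert p == pytest.approx(fisher_pvalue(-zeta, n, q), abs=1e-15)

    def test_against_independent_erfc_oracle(self):
        # frozen value computed with math.erfc on the closed form
        assert fisher_pvalue(0.1, 1020, 149) == pytest.approx(
            0.0031159249433244025, abs=1e-10
        )

    def test_perfect_correlation_exact_zero(self):
        assert fisher_pvalue(1.0, 100, 0) == 0.0

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            fisher_pvalue(0.5, 10, 8)

    def test_bonferroni_printed_example(self):
        # 151 metabolites: 11325 pairs, 0.01 -> 8.83e-7
        assert 151 * 150 // 2 == 11325
        assert bonferroni_alpha(0.01, 11325) == pytest.approx(8.83e-7, rel=1e-3)
        assert bonferroni_alpha(0.37, 1) == 0.37

    def test_cutoff_roundtrip_identity(self):
        for alpha_adj, n, q in [(8.83e-7, 1020, 149), (0.01, 200, 3), (0.5, 50, 0)]:
            zeta = significance_cutoff(alpha_adj, n, q)
            assert fisher_pvalue(zeta, n, q) == pytest.approx(alpha_adj, abs=1e-10)

    def test_cutoff_monotone_decreasing_in_n(self):
        cuts = [significance_cutoff(1e-6, n, 10) for n in (100, 500, 2000)]
        assert cuts[0] > cuts[1] > cuts[2]

    def test_cutoff_cohort_scale_value(self):
        # frozen value from independent inversion of the closed form
        assert significance_cutoff(8.83e-7, 1020, 149) == pytest.approx(0.16533, abs=5e-5)

    def test_alpha_near_one_cutoff_near_zero(self):
        assert significance_cutoff(0.999, 1000, 0) < 1e-3


class TestEstimator:
    def test_sklearn_params_round_trip(self):
        est = GaussianGraphicalModel(alpha=0.05, order=1)
        params = est.get_params()
        est2 = GaussianGraphicalModel().set_params(**params)
        assert est2.alpha == 0.05 and est2.order == 1

    def test_fitted_attributes(self, gaussian_chain_data):
        est = GaussianGraphicalModel().fit(gaussian_chain_data)
        m = gaussian_chain_data.shape[1]
        assert est.partial_.shape == (m, m)
        assert est.order_q_ == m - 2
        assert est.feature_names_ == list(gaussian_chain_data.columns)
        res = est.to_result()
        assert res.alpha_adj == pytest.approx(0.01 / (m * (m - 1) / 2))

    def test_pvalue_calibration_under_null(self):
        # fraction of significant partial p-values under independence stays
        # within binomial 3 sigma of alpha
        rng = np.random.default_rng(10)
        alpha, reps, n, m = 0.05, 200, 2000, 5
        hits, total = 0, 0
        for _ in range(reps):
            X = rng.standard_normal((n, m))
            res = GaussianGraphicalModel(alpha=alpha, correction="none").fit_result(X)
            off = ~np.eye(m, dtype=bool)
            hits += int((res.p_partial[off] <= alpha).sum()) // 2
            total += m * (m - 1) // 2
        frac = hits / total
        sigma = math.sqrt(alpha * (1 - alpha) / total)
        assert abs(frac - alpha) < 3 * sigma

    def test_edge_table_shape_and_flags(self, gaussian_chain_data):
        res = fit_ggm(gaussian_chain_data)
        tab = edge_table(res)
        assert len(tab) == 10
        sig_pairs = tab[tab.significant]
        # chain neighbours are the significant pairs at n=2000, strength 0.4
        assert set(map(tuple, sig_pairs[["met_a", "met_b"]].values)) == {
            ("A", "B"), ("B", "C"), ("C", "D"), ("D", "E"),
        }


class TestStability:
    def test_bootstrap_nonnegative_and_deterministic(self, gaussian_chain_data):
        r1 = bootstrap_stability(gaussian_chain_data, B=20, seed=3)
        r2 = bootstrap_stability(gaussian_chain_data, B=20, seed=3)
        assert r1.mean >= 0 and r1.mean == r2.mean and r1.sd == r2.sd

    def test_bootstrap_difference_shrinks_with_n(self):
        omega = chain_precision(5, 0.4)
        small = pd.DataFrame(mvn_from_precision(omega, 200, seed=11))
        large = pd.DataFrame(mvn_from_precision(omega, 2000, seed=12))
        r_small = bootstrap_stability(small, B=100, seed=0)
        r_large = bootstrap_stability(large, B=100, seed=0)
        assert r_large.mean < r_small.mean

    def test_subsample_full_size_zero_difference(self, gaussian_chain_data):
        tab = subsample_stability(gaussian_chain_data, sizes=[2000], reps=2, seed=0)
        assert tab.loc[0, "mean"] == pytest.approx(0.0, abs=1e-14)

    def test_subsample_monotone_in_size(self, gaussian_chain_data):
        tab = subsample_stability(gaussian_chain_data, sizes=[100, 400, 1600], reps=100, seed=1)
        means = tab["mean"].to_numpy()
        ses = tab["sd"].to_numpy() / np.sqrt(tab["n_replicates"].to_numpy())
        for i in range(2):
            pooled = math.hypot(ses[i], ses[i + 1])
            assert means[i] >= means[i + 1] - 2 * pooled

    def test_subsample_sizes_at_or_below_m_skipped(self, gaussian_chain_data):
        tab = subsample_stability(gaussian_chain_data, sizes=[4], reps=5, seed=2)
        assert tab.loc[0, "n_skipped"] == 5 and tab.loc[0, "n_replicates"] == 0
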