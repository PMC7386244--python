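"""Count filtering, Pearson residuals, and ICA-initialized NMF."""

import numpy as np
import pytest
import scipy.sparse as sp

import spotstack as st
from spotstack.factors import nmf_ica_init


def _cm(values, genes=None):
    values = np.asarray(values)
    genes = genes or [f"g{i}" for i in range(values.shape[0])]
    spots = [(f"b{j}", "S") for j in range(values.shape[1])]
    return st.CountMatrix(genes=genes, spots=spots, values=sp.csr_matrix(values))


class TestFilterCounts:
    def test_zero_thresholds_identity(self):
        cm = _cm([[1, 0], [2, 3]])
        out = st.filter_counts(cm, 0, 0)
        np.testing.assert_array_equal(out.dense(), cm.dense())

    def test_gene_totals_thresholded(self):
        cm = _cm([[0, 0, 0], [2, 2, 1], [50, 30, 20]])
        out = st.filter_counts(cm, min_counts_gene=1, min_counts_spot=0)
        assert out.genes == ["g1", "g2"]

    def test_gene_first_order_dependence(self):
        # spot b1's total of 5 comes entirely from the low-count gene g0;
        # after g0 is dropped its total is 0 and it falls below the spot cut
        cm = _cm([[5, 0], [0, 9]])
        out = st.filter_counts(cm, min_counts_gene=6, min_counts_spot=1)
        assert out.genes == ["g1"]
        assert [b for b, _ in out.spots] == ["b1"]

    def test_all_spots_removed_rejected(self):
        with pytest.raises(ValueError):
            st.filter_counts(_cm([[1, 1]]), 0, 10)


class TestPearsonResiduals:
    def test_counts_equal_to_expectation_give_zero(self):
        # rank-1 count table: x = outer(row, col)/total exactly equals mu
        X = np.outer([2, 4], [1, 3, 6])
        r = st.pearson_residuals(_cm(X), theta=50.0)
        np.testing.assert_allclose(r.values, 0.0, atol=1e-12)

    def test_hand_computed_oracle_3x3(self):
        X = np.array([[4.0, 0, 2], [1, 3, 0], [0, 2, 6]])
        r = st.pearson_residuals(_cm(X), theta=10.0, clip=np.inf)
        tot = X.sum()
        for g in range(3):
            for s in range(3):
                mu = X[g].sum() * X[:, s].sum() / tot
                expect = (X[g, s] - mu) / np.sqrt(mu + mu**2 / 10.0)
                assert r.values[g, s] == pytest.approx(expect, abs=1e-10)

    def test_infinite_theta_is_poisson_residual(self, rng):
        X = rng.integers(0, 20, (6, 8)).astype(float)
        X[0, 0] += 1  # ensure nonzero
        r_nb = st.pearson_residuals(_cm(X), theta=1e12, clip=np.inf)
        tot = X.sum()
        mu = np.outer(X.sum(1), X.sum(0)) / tot
        poisson = np.where(mu > 0, (X - mu) / np.sqrt(np.where(mu > 0, mu, 1)), 0.0)
        np.testing.assert_allclose(r_nb.values, poisson, atol=1e-9)

    def test_default_clip_is_sqrt_n_spots(self, rng):
        X = rng.integers(0, 50, (5, 16)).astype(float)
        X[0] = [1000] + [0] * 15  # extreme cell to trigger clipping
        r = st.pearson_residuals(_cm(X))
        assert r.clip == pytest.approx(4.0)
        assert np.abs(r.values).max() <= 4.0

    def test_zero_total_rejected(self):
        with pytest.raises(ValueError):
            st.pearson_residuals(np.zeros((3, 3)))

    def test_multinomial_null_residual_means_near_zero(self):
        rng = np.random.default_rng(7)
        rates = rng.gamma(3.0, 2.0, 50)
        X = rng.poisson(np.tile(rates[:, None], (1, 200)))
        r = st.pearson_residuals(_cm(X), theta=100.0)
        expressed = X.sum(axis=1) >= 50
        means = r.values[expressed].mean(axis=1)
        assert np.abs(means).max() < 0.2


class TestNonnegTransform:
    def test_clip_and_shift_modes(self, rng):
        X = rng.normal(0, 2, (10, 10))
        clipped = st.nonneg_transform(X)
        np.testing.assert_array_equal(clipped, np.maximum(X, 0))
        shifted = st.nonneg_transform(X, mode="shift")
        np.testing.assert_allclose(shifted, X - X.min())
        positive = np.abs(X)
        np.testing.assert_array_equal(st.nonneg_transform(positive), positive)


class TestICAInit:
    def test_block_structure_concentrates_components(self):
        rng = np.random.default_rng(0)
        X = np.zeros((40, 60))
        X[:20, :30] = rng.gamma(4, 1, (20, 30))
        X[20:, 30:] = rng.gamma(4, 1, (20, 30))
        W0, H0, method = nmf_ica_init(X, k=2, seed=0)
        assert method == "ica"
        for c in range(2):
            top = np.square(W0[:20, c]).sum()
            bottom = np.square(W0[20:, c]).sum()
            frac = max(top, bottom) / (top + bottom)
            assert frac > 0.7

    def test_deterministic_given_seed(self, rng):
        X = rng.gamma(2, 1, (30, 40))
        a = nmf_ica_init(X, 3, seed=5)
        b = nmf_ica_init(X, 3, seed=5)
        np.testing.assert_array_equal(a[0], b[0])
        np.testing.assert_array_equal(a[1], b[1])

    def test_k_bounds_checked(self, rng):
        X = rng.random((5, 6))
        with pytest.raises(ValueError):
            nmf_ica_init(X, 0, seed=0)
        with pytest.raises(ValueError):
            nmf_ica_init(X, 6, seed=0)


class TestFitNMF:
    def test_exact_rank3_factorization_recovered(self):
        rng = np.random.default_rng(1)
        W_true = rng.gamma(2, 1, (50, 3))
        H_true = rng.gamma(2, 1, (3, 80))
        X = W_true @ H_true
        model = st.fit_nmf(X, k=3, max_iter=10_000, tol=1e-12, seed=1)
        rel = np.linalg.norm(X - model.W @ model.H) / np.linalg.norm(X)
        assert rel < 1e-3

    def test_rank1_closed_form_limit(self):
        rng = np.random.default_rng(2)
        X = np.outer(rng.gamma(2, 1, 30), rng.gamma(2, 1, 40))
        model = st.fit_nmf(X, k=1, max_iter=2000, tol=1e-14, seed=2)
        rel = np.linalg.norm(X - model.W @ model.H) / np.linalg.norm(X)
        assert rel < 1e-6

    def test_objective_trace_non_increasing_and_nonneg(self, rng):
        X = rng.gamma(2, 1, (40, 60))
        model = st.fit_nmf(X, k=4, seed=3)
        assert (np.diff(model.objective_trace) <= 1e-8).all()
        assert (model.W >= 0).all() and (model.H >= 0).all()

    def test_w_columns_unit_norm(self, rng):
        X = rng.gamma(2, 1, (40, 60))
        model = st.fit_nmf(X, k=4, seed=3)
        np.testing.assert_allclose(np.linalg.norm(model.W, axis=0), 1.0, atol=1e-9)

    def test_same_seed_bitwise_identical(self, rng):
        X = rng.gamma(2, 1, (30, 50))
        a = st.fit_nmf(X, k=3, seed=9)
        b = st.fit_nmf(X, k=3, seed=9)
        np.testing.assert_array_equal(a.W, b.W)
        np.testing.assert_array_equal(a.H, b.H)


class TestTopDrivers:
    def test_direct_sort_with_ties(self):
        model = st.FactorModel(
            W=np.array([[0.9, 0.0], [0.1, 0.5], [0.0, 0.5]]),
            H=np.zeros((2, 4)), k=2, objective_trace=[1.0],
            genes=["g1", "g2", "g3"],
        )
        assert st.top_drivers(model, 0, 2) == ["g1", "g2"]
        assert st.top_drivers(model, 1, 2) == ["g2", "g3"]  # tie broken by name
        assert st.top_drivers(model, 0, 99) == ["g1", "g2", "g3"]

    def test_invalid_index_rejected(self):
        model = st.FactorModel(W=np.ones((3, 2)), H=np.ones((2, 3)), k=2,
                               objective_trace=[])
        with pytest.raises(IndexError):
            st.top_drivers(model, 2)


def test_planted_factor_recovery_end_to_end():
    """Drivers of recovered factors come from the planted gene sets."""
    from scipy.optimize import linear_sum_assignment

    spots = st.synth.make_hex_grid(20, 20)
    counts, truth = st.synth.simulate_counts(spots, n_genes=120, k=3,
                                             effect=3.0, theta=10.0, seed=4)
    model = st.run_nmf(counts, k=3, seed=4)
    P = truth.factor_patterns
    sim = np.array([
        [P[j] @ model.H[i] / (np.linalg.norm(P[j]) * np.linalg.norm(model.H[i]) + 1e-12)
         for j in range(3)] for i in range(3)
    ])
    ri, ci = linear_sum_assignment(-sim)
    assert sim[ri, ci].mean() >= 0.8
    for i, j in zip(ri, ci):
        drivers = set(st.top_drivers(model, i, 10))
        assert len(drivers & truth.factor_gene_sets[j]) >= 8
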