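import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from scmmst.glmm import FamilySpec, NullModelFit
from scmmst.io_norm import CellDesign
from scmmst.score import (
    NullProjection,
    bh_adjust,
    e_matrix,
    mixture_chisq_pvalue,
    run_de,
    score_statistic,
)
from scmmst.score import test_gene as run_single_gene_test


def make_fit(mu0, v_diag, phi_diag, sigma_b2, tau=1.0):
    """Assemble a NullModelFit directly for oracle tests."""
    return NullModelFit(
        alpha_hat=0.0,
        b_hat=np.zeros(1),
        sigma_b2_hat=sigma_b2,
        mu0_hat=np.asarray(mu0, float),
        theta_hat=None,
        tau_hat=tau,
        v_diag=np.asarray(v_diag, float),
        phi_diag=np.asarray(phi_diag, float),
        converged=True,
        n_iter=1,
        family=FamilySpec("poisson"),
    )


def random_instance(rng, n, p):
    design = CellDesign(
        batch=[f"b{i % p}" for i in range(n)],
        group=["g1" if rng.random() < 0.5 else "g2" for i in range(n)],
    )
    g = rng.integers(0, 2, n).astype(float)
    v = rng.uniform(0.2, 3.0, n)
    phi = rng.uniform(0.3, 1.0, n)
    mu0 = rng.uniform(1.0, 20.0, n)
    y = mu0 + rng.normal(0, 1, n)
    sigma_b2 = rng.uniform(0.0, 1.0)
    w = rng.uniform(0.1, 1.0, n)
    return design, g, v, phi, mu0, y, sigma_b2, w


def dense_sigma_inv(v, sigma_b2, design):
    B = design.batch_onehot
    return np.linalg.inv(np.diag(v) + sigma_b2 * B @ B.T)


def dense_p_matrix(v, sigma_b2, design):
    Si = dense_sigma_inv(v, sigma_b2, design)
    one = np.ones(len(v))
    return Si - Si @ np.outer(one, one) @ Si / (one @ Si @ one)


def dense_gb(design, g, w=None):
    M = design.batch_onehot * g[:, None]
    if w is not None:
        M = M * w[:, None]
    return M


class TestDenseOracle:
    """The O(n p) Woodbury path must match brute-force dense linear algebra."""

    @pytest.mark.parametrize("seed,n,p", [(0, 12, 2), (1, 25, 3), (2, 50, 5), (3, 40, 4)])
    def test_sigma_inverse_and_projection(self, seed, n, p):
        rng = np.random.default_rng(seed)
        design, g, v, phi, mu0, y, sigma_b2, w = random_instance(rng, n, p)
        proj = NullProjection(v, sigma_b2, design.batch_index, design.n_batches)
        Si = dense_sigma_inv(v, sigma_b2, design)
        X = rng.normal(size=(n, 3))
        np.testing.assert_allclose(proj.sigma_inv_apply(X), Si @ X, atol=1e-8)
        P = dense_p_matrix(v, sigma_b2, design)
        np.testing.assert_allclose(proj.p_apply(X), P @ X, atol=1e-8)

    @pytest.mark.parametrize("seed,n,p", [(4, 20, 2), (5, 30, 3), (6, 50, 5)])
    def test_statistic_and_e_matrix(self, seed, n, p):
        rng = np.random.default_rng(seed)
        design, g, v, phi, mu0, y, sigma_b2, w = random_instance(rng, n, p)
        fit = make_fit(mu0, v, phi, sigma_b2)

        r = y - mu0
        GB = dense_gb(design, g)
        t_dense = r @ np.diag(phi) @ GB @ GB.T @ np.diag(phi) @ r
        assert score_statistic(y, fit, design, g) == pytest.approx(t_dense, rel=1e-10)

        P = dense_p_matrix(v, sigma_b2, design)
        np.testing.assert_allclose(e_matrix(fit, design, g), GB.T @ P @ GB, atol=1e-8)

        # weighted variants: T_w and E'_w = GB' W P W GB
        WGB = dense_gb(design, g, w)
        tw_dense = r @ np.diag(phi * w) @ GB @ GB.T @ np.diag(phi * w) @ r
        assert score_statistic(y, fit, design, g, weights=w) == pytest.approx(
            tw_dense, rel=1e-10
        )
        np.testing.assert_allclose(
            e_matrix(fit, design, g, weights=w), WGB.T @ P @ WGB, atol=1e-8
        )

    def test_unit_weights_reduce_to_unweighted(self):
        rng = np.random.default_rng(7)
        design, g, v, phi, mu0, y, sigma_b2, _ = random_instance(rng, 30, 3)
        fit = make_fit(mu0, v, phi, sigma_b2)
        ones = np.ones(30)
        assert score_statistic(y, fit, design, g, weights=ones) == pytest.approx(
            score_statistic(y, fit, design, g)
        )
        np.testing.assert_allclose(
            e_matrix(fit, design, g, weights=ones), e_matrix(fit, design, g)
        )

    def test_trace_equals_eigenvalue_sum(self):
        rng = np.random.default_rng(8)
        design, g, v, phi, mu0, y, sigma_b2, _ = random_instance(rng, 40, 5)
        fit = make_fit(mu0, v, phi, sigma_b2)
        E = e_matrix(fit, design, g)
        assert np.trace(E) == pytest.approx(np.linalg.eigvalsh(E).sum(), abs=1e-10)

    def test_boundary_sigma_b2_zero_is_diagonal_sigma(self):
        rng = np.random.default_rng(9)
        design, g, v, phi, mu0, y, _, _ = random_instance(rng, 20, 2)
        proj = NullProjection(v, 0.0, design.batch_index, design.n_batches)
        x = rng.normal(size=20)
        np.testing.assert_allclose(proj.sigma_inv_apply(x), x / v, rtol=1e-12)


class TestScoreStatisticExamples:
    def test_hand_computed_two_by_two(self):
        design = CellDesign(batch=["b1", "b2", "b1", "b2"], group=["g1", "g1", "g2", "g2"])
        y = np.array([2.0, 0.0, 3.0, 1.0])
        mu0 = y - np.array([1.0, -1.0, 2.0, 0.0])  # residuals (1,-1,2,0)
        g = np.array([1.0, 1.0, 0.0, 0.0])
        fit = make_fit(mu0, np.ones(4), np.ones(4), 0.0)
        # G_B' r = (1, -1) so T = 2
        assert score_statistic(y, fit, design, g) == pytest.approx(2.0)

    def test_zero_group_indicator_gives_zero(self):
        design = CellDesign(batch=["b1", "b2"] * 3, group=["g1"] * 6)
        fit = make_fit(np.ones(6), np.ones(6), np.ones(6), 0.1)
        assert score_statistic(np.ones(6), fit, design, np.zeros(6)) == 0.0

    def test_tau_scale_equivariance(self):
        rng = np.random.default_rng(10)
        design, g, v, phi, mu0, y, sigma_b2, _ = random_instance(rng, 30, 3)
        t1 = score_statistic(y, make_fit(mu0, v, phi, sigma_b2, tau=1.0), design, g)
        t3 = score_statistic(y, make_fit(mu0, v, phi, sigma_b2, tau=3.0), design, g)
        assert t3 == pytest.approx(t1 / 3.0, rel=1e-12)


class TestMixtureChisq:
    def test_single_eigenvalue_matches_chi2(self):
        p, backend = mixture_chisq_pvalue(np.array([1.0]), 3.841459)
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_equal_pair_closed_form(self):
        # 0.5 * chi2_2 has tail exp(-t), so t = ln 20 gives exactly 0.05
        p, backend = mixture_chisq_pvalue(np.array([0.5, 0.5]), np.log(20.0))
        assert p == pytest.approx(0.05, abs=1e-4)

    def test_zero_statistic_gives_one(self):
        assert mixture_chisq_pvalue(np.array([1.0, 2.0]), 0.0)[0] == 1.0

    def test_empty_after_clipping_warns(self):
        with pytest.warns(UserWarning):
            p, _ = mixture_chisq_pvalue(np.array([0.0, 0.0]), 1.0)
        assert p == 1.0

    def test_negative_statistic_rejected(self):
        with pytest.raises(ValueError):
            mixture_chisq_pvalue(np.array([1.0]), -1.0)

    @pytest.mark.parametrize("seed", range(5))
    def test_monte_carlo_agreement(self, seed):
        rng = np.random.default_rng(seed)
        m = int(rng.integers(2, 6))
        xi = rng.uniform(0.05, 2.0, m)
        t = float(rng.uniform(0.2, 2.5) * xi.sum())
        p, _ = mixture_chisq_pvalue(xi, t)
        draws = (xi[None, :] * rng.chisquare(1, (400_000, m))).sum(axis=1)
        mc = float(np.mean(draws >= t))
        se = np.sqrt(mc * (1 - mc) / 400_000)
        assert abs(p - mc) <= 3 * se


class TestBH:
    def test_textbook_step_up(self):
        np.testing.assert_allclose(
            bh_adjust(np.array([0.01, 0.02, 0.03, 0.04])), [0.04, 0.04, 0.04, 0.04]
        )

    def test_constant_and_singleton(self):
        np.testing.assert_allclose(bh_adjust(np.full(5, 0.2)), 0.2)
        np.testing.assert_allclose(bh_adjust(np.array([0.7])), [0.7])

    def test_out_of_range_rejected(self):
        with pytest.raises(ValueError):
            bh_adjust(np.array([0.5, 1.5]))

    @settings(max_examples=30, deadline=None, derandomize=True)
    @given(st.lists(st.floats(0.0, 1.0), min_size=1, max_size=40))
    def test_monotone_in_p_rank_and_capped(self, pvals):
        p = np.array(pvals)
        adj = bh_adjust(p)
        assert np.all(adj <= 1.0) and np.all(adj >= p - 1e-12)
        order = np.argsort(p, kind="stable")
        assert np.all(np.diff(adj[order]) >= -1e-12)

    def test_hand_step_up_oracle(self):
        rng = np.random.default_rng(11)
        p = rng.uniform(size=25)
        n = p.size
        order = np.argsort(p)
        adj_sorted = p[order] * n / np.arange(1, n + 1)
        adj_sorted = np.minimum.accumulate(adj_sorted[::-1])[::-1]
        expected = np.empty(n)
        expected[order] = np.minimum(adj_sorted, 1.0)
        np.testing.assert_allclose(bh_adjust(p), expected, rtol=1e-12)


class TestTestGene:
    def _design(self, n=60, p=3):
        return CellDesign(
            batch=[f"b{i % p}" for i in range(n)],
            group=["g1" if (i // p) % 2 == 0 else "g2" for i in range(n)],
        )

    def test_all_zero_gene_flagged_p_one(self):
        design = self._design()
        res = run_single_gene_test(
            np.zeros(60), design, design.group_indicator("g1"), FamilySpec("poisson")
        )
        assert res.failed and res.p_value == 1.0

    def test_constant_gene_has_vanishing_statistic(self):
        design = self._design()
        res = run_single_gene_test(
            np.full(60, 7.0), design, design.group_indicator("g1"), FamilySpec("poisson")
        )
        assert res.statistic < 1e-8
        assert res.p_value > 0.999


class TestRunDE:
    def _null_data(self, seed=12, G=60):
        from scmmst.simulate import SimParams, simulate_null_dataset

        params = SimParams(
            n_genes=G, n_cells=100, n_batches=4, family="poisson",
            sigma_b2=0.1, mu0=2.0, mu_pi=20, de_prop=0, seed=seed,
        )
        return simulate_null_dataset(params)

    def test_unknown_target_lists_levels(self):
        cm, design, _ = self._null_data()
        with pytest.raises(ValueError, match="g1"):
            run_de(cm, design, "bogus", FamilySpec("poisson"))

    def test_output_shape_and_adjustment_monotone(self):
        cm, design, _ = self._null_data()
        res = run_de(cm, design, "g1", FamilySpec("poisson"), weight_method="none")
        assert len(res) == cm.n_genes
        order = np.argsort(res["p_value"].to_numpy(), kind="stable")
        assert np.all(np.diff(res["p_adj"].to_numpy()[order]) >= -1e-12)

    def test_gene_permutation_equivariance(self):
        from scmmst.io_norm import CountMatrix

        cm, design, _ = self._null_data()
        res = run_de(cm, design, "g1", FamilySpec("poisson"), weight_method="none")
        rng = np.random.default_rng(0)
        perm = rng.permutation(cm.n_genes)
        cm2 = CountMatrix(cm.values[perm], [cm.gene_ids[i] for i in perm], cm.cell_ids)
        res2 = run_de(cm2, design, "g1", FamilySpec("poisson"), weight_method="none")
        merged = res.set_index("gene_id").loc[res2["gene_id"]]
        np.testing.assert_allclose(
            merged["p_value"].to_numpy(), res2["p_value"].to_numpy(), rtol=1e-10
        )
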