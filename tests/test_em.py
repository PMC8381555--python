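"""Mixture model and EM: kernels, E/M steps, objective ascent, enumeration oracles."""

import numpy as np
import pytest
from scipy.stats import dirichlet as scipy_dirichlet

from dofinemap.datamodel import EditDistanceCounts
from dofinemap.em import (
    FitConfig,
    ModelParams,
    Responsibilities,
    causal_loglik,
    estep,
    fit,
    model_data_from_counts,
    mstep,
    null_loglik,
    objective,
)
from dofinemap.prior import GenePrior


def prior_for(data, pi_per_gene):
    return [GenePrior(gene_id=g, pi=np.asarray(pi), components=np.zeros((len(pi), 4)))
            for g, pi in zip(data.gene_ids, pi_per_gene)]


def params_for(data, a0, a1, b0, b1, gamma, theta_per_gene):
    return ModelParams(a0=np.array(a0), a1=np.array(a1), b0=np.array(b0),
                       b1=np.array(b1), gamma=gamma,
                       theta=np.concatenate([np.asarray(t, float) for t in theta_per_gene]))


class TestLikelihoodKernels:
    def test_perfect_match_product(self):
        c = EditDistanceCounts(n=(5, 0, 0), m=(3, 0, 0))
        ll = causal_loglik(c, (0.8, 0.15, 0.05), (0.7, 0.2, 0.1))
        assert ll == pytest.approx(np.log(0.8**5 * 0.7**3))
        assert ll == pytest.approx(-2.1857, abs=1e-3)

    def test_uniform_kernel_depends_only_on_trials(self):
        u = (1 / 3, 1 / 3, 1 / 3)
        for n, m in [((5, 0, 0), (3, 0, 0)), ((1, 2, 2), (0, 2, 1))]:
            c = EditDistanceCounts(n=n, m=m)
            assert causal_loglik(c, u, u) == pytest.approx(8 * np.log(1 / 3))

    def test_zero_probability_cell_with_count(self):
        c = EditDistanceCounts(n=(4, 1, 0), m=(3, 0, 0))
        assert causal_loglik(c, (1.0, 0.0, 0.0), (1.0, 0.0, 0.0)) == -np.inf

    def test_null_kernel_mirrors_causal(self):
        c = EditDistanceCounts(n=(3, 2, 0), m=(2, 1, 0))
        assert null_loglik(c, (0.5, 0.3, 0.2), (0.6, 0.3, 0.1)) == pytest.approx(
            causal_loglik(c, (0.5, 0.3, 0.2), (0.6, 0.3, 0.1))
        )


class TestEstep:
    def test_single_candidate_two_term_enumeration(self):
        # one gene, one candidate, identical causal and null counts; the
        # posterior reduces to a two-term Bayes computation
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        data = model_data_from_counts(["g1"], [counts], counts.copy())
        params = params_for(data, a0=(1/3, 1/3, 1/3), a1=(0.8, 0.15, 0.05),
                            b0=(1/3, 1/3, 1/3), b1=(0.7, 0.2, 0.1),
                            gamma=0.5, theta_per_gene=[[1.0]])
        resp = estep(data, params)
        l1 = 0.8**5 * 0.7**3
        l0 = (1 / 3) ** 8
        expected = 0.5 * l1 / (0.5 * l1 + 0.5 * l0)
        assert resp.v_hat[0] == pytest.approx(expected, abs=1e-12)
        assert expected == pytest.approx(0.9986, abs=1e-4)

    def test_gamma_near_zero_forces_null(self):
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        data = model_data_from_counts(["g1"], [counts], counts.copy())
        params = params_for(data, (1/3,)*3, (0.8, .15, .05), (1/3,)*3, (0.7, .2, .1),
                            gamma=1e-12, theta_per_gene=[[1.0]])
        resp = estep(data, params)
        assert resp.w_null[0] == pytest.approx(1.0, abs=1e-6)

    def test_identical_candidates_share_weight(self):
        counts = np.array([[4, 1, 0, 3, 0, 0], [4, 1, 0, 3, 0, 0]], dtype=float)
        data = model_data_from_counts(["g1"], [counts], np.array([[2, 2, 1, 1, 1, 1.]]))
        params = params_for(data, (1/3,)*3, (0.8, .15, .05), (1/3,)*3, (0.7, .2, .1),
                            gamma=0.5, theta_per_gene=[[0.5, 0.5]])
        resp = estep(data, params)
        assert resp.w[0] == pytest.approx(resp.w[1])
        assert resp.w_null[0] + resp.w.sum() == pytest.approx(1.0, abs=1e-10)

    def test_normalization_per_gene(self):
        rng = np.random.default_rng(0)
        blocks, nulls, ids = [], [], []
        for g in range(5):
            p = rng.integers(1, 6)
            cc = rng.multinomial(5, [0.7, 0.2, 0.1], size=p)
            mm = rng.multinomial(3, [0.7, 0.2, 0.1], size=p)
            blocks.append(np.hstack([cc, mm]).astype(float))
            nulls.append(np.concatenate([rng.multinomial(5, [0.6, 0.3, 0.1]),
                                         rng.multinomial(3, [0.6, 0.3, 0.1])]))
            ids.append(f"g{g}")
        data = model_data_from_counts(ids, blocks, np.array(nulls, dtype=float))
        theta = [np.full(b.shape[0], 1.0 / b.shape[0]) for b in blocks]
        params = params_for(data, (0.5, 0.3, 0.2), (0.8, 0.15, 0.05),
                            (0.5, 0.3, 0.2), (0.7, 0.2, 0.1), 0.4, theta)
        resp = estep(data, params)
        for g in range(5):
            sl = slice(data.offsets[g], data.offsets[g] + data.p[g])
            total = resp.w[sl].sum() + resp.w_null[g]
            assert total == pytest.approx(1.0, abs=1e-10)


class TestMstep:
    def test_pseudocount_only_null_data(self):
        # all genes fully null: causal sums reduce to the pseudocounts,
        # whose per-gene p_g factor cancels in the ratio
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        blocks = [counts.copy() for _ in range(4)]
        data = model_data_from_counts([f"g{i}" for i in range(4)], blocks,
                                      np.tile(counts, (4, 1)))
        resp = Responsibilities(w=np.zeros(4), w_null=np.ones(4), v_hat=np.zeros(4))
        params = mstep(data, resp, np.ones(4), lam=(0.1, 0.01, 0.0))
        np.testing.assert_allclose(params.a1, np.array([0.1, 0.01, 0.0]) / 0.11, atol=1e-12)
        np.testing.assert_allclose(params.b1, np.array([0.1, 0.01, 0.0]) / 0.11, atol=1e-12)

    def test_hard_single_gene_pure_counts(self):
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        data = model_data_from_counts(["g1"], [counts], counts.copy())
        resp = Responsibilities(w=np.ones(1), w_null=np.zeros(1), v_hat=np.ones(1))
        params = mstep(data, resp, np.ones(1), lam=(0.0, 0.0, 0.0))
        np.testing.assert_allclose(params.a1, [1, 0, 0])
        np.testing.assert_allclose(params.b1, [1, 0, 0])

    def test_map_theta_matches_dirichlet_mode_and_grid(self):
        counts = np.array([[5, 0, 0, 3, 0, 0], [3, 2, 0, 2, 1, 0]], dtype=float)
        data = model_data_from_counts(["g1"], [counts], counts[:1].copy())
        w = np.array([1.0, 0.0])
        resp = Responsibilities(w=w, w_null=np.zeros(1), v_hat=np.ones(1))
        pi = np.array([2.0, 1.5])
        params = mstep(data, resp, pi, lam=(0.1, 0.01, 0.0))
        np.testing.assert_allclose(params.theta, [0.8, 0.2], atol=1e-12)
        # independent oracle: grid maximizer of the Dirichlet(pi + w) density
        alpha = pi + w
        grid = np.linspace(1e-6, 1 - 1e-6, 200_001)
        dens = scipy_dirichlet.logpdf(np.vstack([grid, 1 - grid]), alpha)
        best = grid[np.argmax(dens)]
        assert params.theta[0] == pytest.approx(best, abs=1e-5)

    def test_gamma_is_mean_responsibility(self):
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        blocks = [counts.copy() for _ in range(4)]
        data = model_data_from_counts([f"g{i}" for i in range(4)], blocks,
                                      np.tile(counts, (4, 1)))
        v = np.array([1.0, 0.5, 0.25, 0.0])
        resp = Responsibilities(w=v.copy(), w_null=1 - v, v_hat=v)
        params = mstep(data, resp, np.ones(4))
        assert params.gamma == pytest.approx(v.mean())


class TestFit:
    @staticmethod
    def small_dataset(seed=0, G=40, p=3):
        rng = np.random.default_rng(seed)
        blocks, nulls, ids, pis = [], [], [], []
        for g in range(G):
            causal = rng.random() < 0.5
            cc = rng.multinomial(5, [0.9, 0.08, 0.02], size=p)
            mm = rng.multinomial(3, [0.85, 0.1, 0.05], size=p)
            blocks.append(np.hstack([cc, mm]).astype(float))
            if causal:
                nulls.append(np.array([2, 3, 0, 1, 2, 0.0]))
            else:
                nulls.append(np.concatenate([rng.multinomial(5, [0.85, 0.12, 0.03]),
                                             rng.multinomial(3, [0.85, 0.12, 0.03])]))
            ids.append(f"g{g}")
            pis.append(np.full(p, 1.5))
        data = model_data_from_counts(ids, blocks, np.array(nulls))
        return data, prior_for(data, pis)

    def test_objective_ascends_every_restart(self):
        data, priors = self.small_dataset()
        res = fit(data, priors, FitConfig(restarts=4, max_iter=100, seed=1))
        for trace in res.all_traces:
            diffs = np.diff(trace)
            floor = -1e-9 * (np.abs(np.array(trace[:-1])) + 1.0)
            assert np.all(diffs >= floor)

    def test_same_seed_is_bitwise_identical(self):
        data, priors = self.small_dataset()
        r1 = fit(data, priors, FitConfig(restarts=3, max_iter=50, seed=7))
        r2 = fit(data, priors, FitConfig(restarts=3, max_iter=50, seed=7))
        assert r1.objective_trace == r2.objective_trace
        np.testing.assert_array_equal(r1.responsibilities.w, r2.responsibilities.w)
        np.testing.assert_array_equal(r1.params.theta, r2.params.theta)
        assert r1.best_restart == r2.best_restart

    def test_duplicated_genes_leave_estimates_unchanged(self):
        data, priors = self.small_dataset(G=30)
        blocks = [data.cand_counts[data.offsets[g]:data.offsets[g] + data.p[g]]
                  for g in range(data.n_genes)]
        data2 = model_data_from_counts(
            data.gene_ids + [f"{g}_dup" for g in data.gene_ids],
            blocks + blocks,
            np.vstack([data.null_counts, data.null_counts]),
        )
        priors2 = priors + priors
        r1 = fit(data, priors, FitConfig(restarts=2, max_iter=200, seed=3))
        r2 = fit(data2, priors2, FitConfig(restarts=2, max_iter=200, seed=3))
        assert r1.params.gamma == pytest.approx(r2.params.gamma, abs=5e-3)
        np.testing.assert_allclose(r1.params.a1, r2.params.a1, atol=5e-3)
        np.testing.assert_allclose(r1.params.a0, r2.params.a0, atol=5e-3)

    def test_pseudocount_ordering_on_null_data(self):
        # lam0 >> lam1 >> lam2 keeps the causal triple ordered even when
        # no gene is causal
        counts = np.array([[5, 0, 0, 3, 0, 0]], dtype=float)
        blocks = [counts.copy() for _ in range(30)]
        nulls = np.tile(np.array([[5, 0, 0, 3, 0, 0.0]]), (30, 1))
        data = model_data_from_counts([f"g{i}" for i in range(30)], blocks, nulls)
        priors = prior_for(data, [np.ones(1)] * 30)
        res = fit(data, priors, FitConfig(restarts=2, max_iter=50, seed=0,
                                          lam=(0.1, 0.01, 0.0)))
        a1 = res.params.a1
        assert a1[0] >= a1[1] >= a1[2]

    def test_hard_em_runs_and_assigns_binary_responsibilities(self):
        data, priors = self.small_dataset(G=20)
        res = fit(data, priors, FitConfig(restarts=2, max_iter=50, seed=2, em_mode="hard"))
        assert set(np.round(res.responsibilities.w_null, 10)) <= {0.0, 1.0}


class TestEnumerationOracle:
    def test_fixed_point_posteriors_match_exhaustive_enumeration(self):
        # two genes, p <= 3: compare the E-step at the EM fixed point with
        # a direct enumeration of all (V, Z) configurations
        blocks = [np.array([[5, 0, 0, 3, 0, 0], [3, 2, 0, 2, 1, 0], [2, 2, 1, 1, 1, 1]],
                           dtype=float),
                  np.array([[4, 1, 0, 2, 1, 0], [1, 3, 1, 0, 2, 1]], dtype=float)]
        nulls = np.array([[4, 1, 0, 3, 0, 0], [2, 3, 0, 1, 2, 0]], dtype=float)
        data = model_data_from_counts(["g1", "g2"], blocks, nulls)
        priors = prior_for(data, [np.array([2.0, 1.3, 1.1]), np.array([1.7, 1.2])])
        res = fit(data, priors, FitConfig(restarts=3, max_iter=500, tol=1e-12, seed=5))
        params = res.params

        def kernel(counts, a, b):
            out = 1.0
            for i in range(3):
                out *= a[i] ** counts[i] * b[i] ** counts[i + 3]
            return out

        for g in range(2):
            sl = slice(data.offsets[g], data.offsets[g] + data.p[g])
            theta = params.theta[sl]
            weights = []
            for k in range(data.p[g]):  # V=1, Z=k configurations
                weights.append(params.gamma * theta[k]
                               * kernel(data.cand_counts[sl][k], params.a1, params.b1))
            weights.append((1 - params.gamma)
                           * kernel(data.null_counts[g], params.a0, params.b0))
            weights = np.array(weights) / np.sum(weights)
            np.testing.assert_allclose(res.responsibilities.w[sl], weights[:-1], atol=1e-8)
            assert res.responsibilities.w_null[g] == pytest.approx(weights[-1], abs=1e-8)

    def test_objective_matches_direct_enumeration_single_gene(self):
        blocks = [np.array([[5, 0, 0, 3, 0, 0], [2, 3, 0, 1, 2, 0]], dtype=float)]
        nulls = np.array([[3, 2, 0, 2, 1, 0]], dtype=float)
        data = model_data_from_counts(["g1"], blocks, nulls)
        pi = np.array([2.0, 1.5])
        theta = np.array([0.7, 0.3])
        params = params_for(data, (0.6, 0.3, 0.1), (0.8, 0.15, 0.05),
                            (0.6, 0.3, 0.1), (0.7, 0.2, 0.1), 0.4, [theta])
        lam = (0.0, 0.0, 0.0)
        got = objective(data, params, pi, lam)
        l1 = [0.8**5 * 0.7**3, 0.8**2 * 0.15**3 * 0.7 * 0.2**2]
        l0 = 0.6**3 * 0.3**2 * 0.6**2 * 0.3
        mix = np.log(0.4 * (theta[0] * l1[0] + theta[1] * l1[1]) + 0.6 * l0)
        dirichlet_term = scipy_dirichlet.logpdf(theta, pi)
        assert got == pytest.approx(mix + dirichlet_term, abs=1e-10)

    def test_objective_invariant_to_gene_order(self):
        data, priors = TestFit.small_dataset(G=10)
        pi_flat = np.concatenate([gp.pi for gp in priors])
        theta = [np.full(data.p[g], 1 / data.p[g]) for g in range(10)]
        params = params_for(data, (0.6, 0.3, 0.1), (0.8, 0.15, 0.05),
                            (0.6, 0.3, 0.1), (0.7, 0.2, 0.1), 0.4, theta)
        obj = objective(data, params, pi_flat)
        order = list(range(10))[::-1]
        blocks = [data.cand_counts[data.offsets[g]:data.offsets[g] + data.p[g]]
                  for g in order]
        data2 = model_data_from_counts([data.gene_ids[g] for g in order], blocks,
                                       data.null_counts[order])
        pi2 = np.concatenate([priors[g].pi for g in order])
        theta2 = [theta[g] for g in order]
        params2 = params_for(data2, (0.6, 0.3, 0.1), (0.8, 0.15, 0.05),
                             (0.6, 0.3, 0.1), (0.7, 0.2, 0.1), 0.4, theta2)
        assert objective(data2, params2, pi2) == pytest.approx(obj, abs=1e-10)
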