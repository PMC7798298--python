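import math

import numpy as np
import pytest
from scipy import optimize, stats

from zinbmix import (
    CountMatrix,
    InitStrategy,
    ModelParams,
    Responsibilities,
    e_step,
    fit_em,
    initialize_params,
    m_step,
    multi_restart_fit,
    dataset_log_likelihood,
)
from zinbmix.em_fit import fit_weighted_nb, params_from_labels
from zinbmix.model_core import unit_scalers

from conftest import make_params


class TestEStep:
    def test_symmetry_gives_uniform_gamma(self, toy_counts):
        p = make_params(K=1, L=2, G=2, seed=4)
        sym = ModelParams(
            2, 2, np.array([0.5, 0.5]),
            np.repeat(p.q, 2, axis=1),
            np.repeat(p.alpha, 2, axis=1),
            np.repeat(p.beta, 2, axis=1),
        )
        resp = e_step(toy_counts, sym, unit_scalers(3))
        assert np.allclose(resp.gamma, 0.5)

    def test_dropout_posterior_zero_for_positive_counts(self, toy_counts, toy_params):
        resp = e_step(toy_counts, toy_params, unit_scalers(3))
        pos = toy_counts.counts > 0
        assert np.all(resp.comp_post[..., 0][pos[:, :, None].repeat(2, axis=2)] == 0)

    def test_rows_sum_to_one(self, toy_counts, toy_params):
        resp = e_step(toy_counts, toy_params, unit_scalers(3))
        assert np.allclose(resp.gamma.sum(axis=1), 1.0, atol=1e-8)
        assert np.allclose(resp.comp_post.sum(axis=-1), 1.0, atol=1e-8)

    def test_bayes_rule_oracle(self, toy_counts):
        p = make_params(K=2, L=2, G=2, seed=6)
        resp = e_step(toy_counts, p, unit_scalers(3))
        for c in range(3):
            # direct Bayes arithmetic with scipy nbinom in long double
            joint = np.zeros(2, dtype=np.longdouble)
            for k in range(2):
                term = np.longdouble(p.pi[k])
                for g in range(2):
                    x = toy_counts.counts[c, g]
                    a, b = p.alpha[g, k, 0], p.beta[g, k, 0]
                    fx = p.q[g, k, 0] * (x == 0) + p.q[g, k, 1] * stats.nbinom.pmf(
                        x, a, b / (b + 1.0)
                    )
                    term *= np.longdouble(fx)
                joint[k] = term
            expect = joint / joint.sum()
            assert np.allclose(resp.gamma[c], expect.astype(float), atol=1e-10)


class TestMStep:
    def test_pi_from_hard_labels(self, toy_counts, toy_params):
        resp = e_step(toy_counts, toy_params, unit_scalers(3))
        onehot = np.zeros((3, 2))
        onehot[[0, 1, 2], [0, 0, 1]] = 1.0
        hard = Responsibilities(onehot, resp.comp_post, resp.log_joint, resp.cell_loglik)
        new = m_step(toy_counts, hard, toy_params, unit_scalers(3))
        assert np.allclose(new.pi, [2 / 3, 1 / 3], atol=1e-9)

    def test_all_mass_on_expressed_component(self, toy_counts, toy_params):
        resp = e_step(toy_counts, toy_params, unit_scalers(3))
        comp = np.zeros_like(resp.comp_post)
        comp[..., 1] = 1.0
        forced = Responsibilities(resp.gamma, comp, resp.log_joint, resp.cell_loglik)
        new = m_step(toy_counts, forced, toy_params, unit_scalers(3))
        assert np.allclose(new.q[..., 1], 1.0, atol=1e-8)

    def test_single_gene_nb_mle_oracle(self):
        # K=1, L=1: the weighted problem with unit weights is plain NB MLE;
        # compare against an independent derivative-free optimizer.
        rng = np.random.default_rng(3)
        x = rng.negative_binomial(4.0, 4.0 / (4.0 + 2.5), size=800)
        counts = CountMatrix(x[:, None])
        p0 = make_params(K=1, L=1, G=1, seed=0)
        resp = e_step(counts, p0, unit_scalers(800))
        new = m_step(counts, resp, p0, unit_scalers(800), max_inner=200)

        def negll(theta):
            a, b = np.exp(theta)
            return -stats.nbinom.logpmf(x, a, b / (b + 1.0)).sum()

        ref = optimize.minimize(negll, [0.0, 0.0], method="Nelder-Mead",
                                options={"xatol": 1e-10, "fatol": 1e-10})
        a_ref, b_ref = np.exp(ref.x)
        # one EM M-step from a cold start may not reach the optimum; iterate
        for _ in range(60):
            resp = e_step(counts, new, unit_scalers(800))
            new = m_step(counts, resp, new, unit_scalers(800), max_inner=200)
        assert new.alpha[0, 0, 0] == pytest.approx(a_ref, rel=1e-4)
        assert new.beta[0, 0, 0] == pytest.approx(b_ref, rel=1e-4)

    def test_objective_non_decreasing(self, two_gene_dataset):
        ds = two_gene_dataset
        p = make_params(K=2, L=2, G=2, seed=8)
        s = ds.scalers
        ll0 = dataset_log_likelihood(ds.counts, p, s)
        resp = e_step(ds.counts, p, s)
        p1 = m_step(ds.counts, resp, p, s)
        ll1 = dataset_log_likelihood(ds.counts, p1, s)
        assert ll1 >= ll0 - 1e-6


class TestFitWeightedNb:
    def test_recovers_generating_values(self):
        rng = np.random.default_rng(5)
        a, b = 6.0, 1.5
        x = rng.negative_binomial(a, b / (b + 1.0), size=20_000)
        ah, bh = fit_weighted_nb(x, np.ones_like(x, dtype=float),
                                 np.ones_like(x, dtype=float), 3.0, 1.0,
                                 max_inner=100)
        assert ah == pytest.approx(a, rel=0.1)
        assert bh == pytest.approx(b, rel=0.1)

    def test_zero_weights_keep_start(self):
        ah, bh = fit_weighted_nb(np.array([1.0, 2.0]), np.zeros(2),
                                 np.ones(2), 2.0, 3.0)
        assert (ah, bh) == (2.0, 3.0)


class TestInitializeParams:
    def test_random_determinism(self, two_gene_dataset):
        ds = two_gene_dataset
        strat = InitStrategy("random", "none", seed=9)
        p1 = initialize_params(ds.counts, 2, 2, strat, scalers=ds.scalers)
        p2 = initialize_params(ds.counts, 2, 2, strat, scalers=ds.scalers)
        assert np.array_equal(p1.pi, p2.pi)
        assert np.array_equal(p1.alpha, p2.alpha)

    def test_kmeans_on_separable_clusters(self):
        rng = np.random.default_rng(0)
        lo = rng.poisson(2.0, size=(60, 2))
        hi = rng.poisson(80.0, size=(40, 2))
        counts = CountMatrix(np.vstack([lo, hi]))
        p = initialize_params(counts, 2, 2, InitStrategy("kmeans", "none", 0),
                              scalers=unit_scalers(100))
        assert sorted(np.round(p.pi, 6)) == [0.4, 0.6]

    def test_params_valid(self, two_gene_dataset):
        ds = two_gene_dataset
        for method in ("random", "kmeans"):
            p = initialize_params(ds.counts, 2, 2,
                                  InitStrategy(method, "log1p", 1),
                                  scalers=ds.scalers)
            p.validate()

    def test_k_too_large_errors(self):
        counts = CountMatrix(np.array([[1, 1], [1, 1], [2, 2]]))
        with pytest.raises(ValueError, match="distinct"):
            initialize_params(counts, 3, 2, InitStrategy("random", "none", 0))

    def test_spectral_falls_back(self):
        # tiny instance: spectral either works or falls back to kmeans
        counts = CountMatrix(np.array([[0, 1], [1, 0], [9, 9], [8, 9]]))
        p = initialize_params(counts, 2, 2, InitStrategy("spectral", "log1p", 0),
                              scalers=unit_scalers(4))
        p.validate()


class TestFitEm:
    def test_max_iter_one(self, two_gene_dataset):
        ds = two_gene_dataset
        fr = fit_em(ds.counts, 2, 2, max_iter=1, seed=0, scalers=ds.scalers)
        assert fr.n_iter == 1
        assert not fr.converged

    def test_monotone_trace(self, two_gene_dataset):
        ds = two_gene_dataset
        fr = fit_em(ds.counts, 2, 2, seed=1, scalers=ds.scalers, max_iter=40)
        diffs = np.diff(fr.loglik_trace)
        assert np.all(diffs >= -1e-6)
        assert fr.n_iter == len(fr.loglik_trace)

    def test_label_switching_equivalence(self, two_gene_dataset):
        ds = two_gene_dataset
        init = make_params(K=2, L=2, G=2, seed=13)
        f1 = fit_em(ds.counts, 2, 2, init=init, scalers=ds.scalers, max_iter=60)
        f2 = fit_em(ds.counts, 2, 2, init=init.permute_clusters([1, 0]),
                    scalers=ds.scalers, max_iter=60)
        assert f1.loglik == pytest.approx(f2.loglik, abs=1e-6 * abs(f1.loglik))
        assert np.allclose(np.sort(f1.params.pi), np.sort(f2.params.pi), atol=1e-6)

    def test_degenerate_gene_handled(self):
        rng = np.random.default_rng(2)
        x = rng.poisson(5.0, size=(200, 2))
        x[:, 1] = 0
        counts = CountMatrix(x)
        fr = fit_em(counts, 1, 2, seed=0, scalers=unit_scalers(200), max_iter=30)
        assert fr.params.q[1, 0, 0] > 0.99  # pinned to dropout
        fr.params.validate()

    def test_l1_matches_independent_per_gene_nb_fits(self):
        # dropout-free single-cluster model == independent per-gene NB MLEs
        rng = np.random.default_rng(9)
        x = np.column_stack([
            rng.negative_binomial(3.0, 3.0 / 4.0, size=600),
            rng.negative_binomial(8.0, 8.0 / 9.0, size=600),
        ])
        counts = CountMatrix(x)
        s = unit_scalers(600)
        joint = fit_em(counts, 1, 1, seed=0, scalers=s, max_iter=80, tol=1e-9)
        for g in range(2):
            single = fit_em(counts.subset_genes([g]), 1, 1, seed=0, scalers=s,
                            max_iter=80, tol=1e-9)
            assert joint.params.alpha[g, 0, 0] == pytest.approx(
                single.params.alpha[0, 0, 0], rel=1e-3)
            assert joint.params.beta[g, 0, 0] == pytest.approx(
                single.params.beta[0, 0, 0], rel=1e-3)


class TestMultiRestart:
    def test_single_restart_equals_fit_em(self, two_gene_dataset):
        ds = two_gene_dataset
        strat = InitStrategy("random", "none", 5)
        direct = fit_em(ds.counts, 2, 2, init=strat, seed=5, scalers=ds.scalers,
                        max_iter=40)
        multi = multi_restart_fit(ds.counts, 2, 2, strategies=[strat],
                                  scalers=ds.scalers, max_iter=40)
        assert multi.loglik == pytest.approx(direct.loglik)

    def test_identical_seeds_identical_winner(self, two_gene_dataset):
        ds = two_gene_dataset
        kw = dict(strategies=[InitStrategy("random", "none", 3)] * 2,
                  scalers=ds.scalers, max_iter=30)
        f1 = multi_restart_fit(ds.counts, 2, 2, **kw)
        f2 = multi_restart_fit(ds.counts, 2, 2, **kw)
        assert f1.loglik == f2.loglik

    def test_winner_dominates_candidates(self, two_gene_dataset):
        ds = two_gene_dataset
        fr = multi_restart_fit(ds.counts, 2, 2, n_random_restarts=3, seed=0,
                               scalers=ds.scalers, max_iter=40)
        assert all(fr.loglik >= ll for _, ll in fr.candidate_logliks)

    def test_no_restarts_errors(self, two_gene_dataset):
        with pytest.raises(ValueError):
            multi_restart_fit(two_gene_dataset.counts, 2, 2,
                              strategies=[], n_random_restarts=0)


class TestParamsFromLabels:
    def test_moment_seed_tracks_group_means(self, two_gene_dataset):
        ds = two_gene_dataset
        p = params_from_labels(ds.counts, ds.true_labels.labels, 2, 2,
                               refine=False, scalers=ds.scalers)
        # alpha seeded at group mean counts with beta = 1
        for k in range(2):
            mask = ds.true_labels.labels == k
            mu = ds.counts.counts[mask].mean(axis=0)
            assert np.allclose(p.alpha[:, k, 0], mu, rtol=1e-12)
        assert np.allclose(p.beta, 1.0)
        assert np.allclose(p.q[..., 0], 0.1)
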