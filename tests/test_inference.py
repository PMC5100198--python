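import numpy as np
import pytest

from sparsesem import (FpcColumn, GenotypeData, PathTest, SemFit,
                       SparseSemError, adjust_pvalues, coef_covariance,
                       stability_selection)
from sparsesem.inference import test_gene as gene_block_test
from sparsesem.inference import test_single as single_coef_test
from sparsesem.inference import _restricted_design
from sparsesem.solver import EquationDesign


def _design(rng, n=200, p=3, k=5, beta=None):
    X = rng.normal(size=(n, k))
    W = X[:, :p].copy()
    beta = np.zeros(p) if beta is None else np.asarray(beta, float)
    y = W @ beta + 0.3 * rng.normal(size=n)
    return EquationDesign(y=y, W=W, instrument=X,
                          col_names=[f"c{j}" for j in range(p)], n_pheno_cols=0)


def _null_fit(M=2, K=3, col_ids=None):
    return SemFit(Gamma=-np.eye(M), B=np.zeros((K, M)), sigma2=np.ones(M),
                  lam=np.zeros(M), support_gamma=np.zeros((M, M), bool),
                  support_b=np.zeros((K, M), bool),
                  phenotype_names=[f"P{i+1}" for i in range(M)],
                  column_ids=col_ids or [f"x{k+1}" for k in range(K)])


class TestCoefCovariance:
    def test_scalar_case_matches_simple_regression_variance(self, rng):
        # single column, W = instrument column: classical sigma^2/(w'w)
        n = 150
        x = rng.normal(size=(n, 1))
        y = 0.8 * x[:, 0] + 0.2 * rng.normal(size=n)
        d = EquationDesign(y=y, W=x, instrument=x, col_names=["w"], n_pheno_cols=0)
        delta, Sigma, sigma_ii = coef_covariance(d, np.array([True]))
        resid = y - x[:, 0] * delta[0]
        assert sigma_ii == pytest.approx(resid @ resid / n)
        assert Sigma[0, 0] == pytest.approx(sigma_ii / (x[:, 0] @ x[:, 0]))

    def test_scale_equivariance(self, rng):
        d = _design(rng, beta=[1.0, 0.0, -0.5])
        supp = np.array([True, False, True])
        _, Sigma, s2 = coef_covariance(d, supp)
        d2 = EquationDesign(y=2 * d.y, W=d.W, instrument=d.instrument,
                            col_names=d.col_names, n_pheno_cols=0)
        _, Sigma2, s2_2 = coef_covariance(d2, supp)
        assert s2_2 == pytest.approx(4 * s2)
        assert np.allclose(Sigma2, 4 * Sigma)

    def test_empty_support_raises(self, rng):
        d = _design(rng)
        with pytest.raises(SparseSemError, match="empty"):
            coef_covariance(d, np.zeros(3, bool))

    def test_covariance_tracks_sampling_variance(self):
        # Monte Carlo: empirical covariance of the refit estimates matches
        # the analytic Sigma on average
        reps, n = 300, 250
        rng = np.random.default_rng(5)
        beta = np.array([0.7, -0.4])
        deltas, Sigmas = [], []
        for _ in range(reps):
            X = rng.normal(size=(n, 4))
            W = X[:, :2] + 0.2 * rng.normal(size=(n, 2))
            y = W @ beta + 0.5 * rng.normal(size=n)
            d = EquationDesign(y=y, W=W, instrument=X, col_names=["a", "b"],
                               n_pheno_cols=0)
            delta, Sigma, _ = coef_covariance(d, np.array([True, True]))
            deltas.append(delta)
            Sigmas.append(Sigma)
        emp = np.cov(np.array(deltas), rowvar=False)
        mean_Sigma = np.mean(Sigmas, axis=0)
        assert np.all(np.abs(np.diag(emp) / np.diag(mean_Sigma) - 1) < 0.25)


class TestSingleCoefficientTest:
    def test_zero_coefficient_gives_p_one(self, rng):
        X = rng.normal(size=(50, 2))
        noise = rng.normal(size=50)
        # make the response exactly orthogonal to the instruments so that
        # the refit coefficient is exactly zero
        Xc = X - X.mean(0)
        nc = noise - noise.mean()
        Y = np.column_stack([nc - Xc @ np.linalg.lstsq(Xc, nc, rcond=None)[0],
                             rng.normal(size=50)])
        t = single_coef_test(Y, X, _null_fit(M=2, K=2), "x1", "P1")
        assert t.statistic == pytest.approx(0.0, abs=1e-12)
        assert t.p_value == pytest.approx(1.0)

    def test_invariant_to_column_rescaling(self, rng):
        X = rng.normal(size=(120, 3))
        Y = np.column_stack([X[:, 0] * 0.5 + 0.2 * rng.normal(size=120),
                             rng.normal(size=120)])
        t1 = single_coef_test(Y, X, _null_fit(M=2, K=3), "x1", "P1")
        X2 = X.copy()
        X2[:, 0] *= 13.7
        t2 = single_coef_test(Y, X2, _null_fit(M=2, K=3), "x1", "P1")
        assert t1.statistic == pytest.approx(t2.statistic, rel=1e-8)

    def test_phenotype_edge_testable(self, rng):
        X = rng.normal(size=(200, 2))
        y1 = X[:, 0] + 0.1 * rng.normal(size=200)
        y2 = 0.9 * y1 + 0.1 * rng.normal(size=200)
        Y = np.column_stack([y1, y2])
        t = single_coef_test(Y, X, _null_fit(M=2, K=2), "P1", "P2")
        assert t.p_value < 1e-6


class TestGeneTest:
    def _eta(self, rng, n=200, G=3):
        vals = rng.normal(size=(n, G))
        return GenotypeData(values=vals,
                            columns=[FpcColumn("g", l + 1) for l in range(G)],
                            sample_ids=[f"s{i}" for i in range(n)],
                            gene_blocks={"g": slice(0, G)})

    def test_single_component_equals_single_test(self, rng):
        eta = self._eta(rng, G=1)
        Y = np.column_stack([eta.values[:, 0] * 0.4 + 0.3 * rng.normal(size=200),
                             rng.normal(size=200)])
        fit = _null_fit(M=2, K=1, col_ids=["g:pc1"])
        tg = gene_block_test(Y, eta, fit, "g", "P1")
        tc = single_coef_test(Y, eta, fit, "g:pc1", "P1")
        assert tg.df == 1
        assert tg.statistic == pytest.approx(tc.statistic, rel=1e-10)

    def test_signal_detected(self, rng):
        eta = self._eta(rng)
        Y = np.column_stack([eta.values @ [0.5, -0.3, 0.2] + 0.2 * rng.normal(size=200),
                             rng.normal(size=200)])
        t = gene_block_test(Y, eta, fit=_null_fit(M=2, K=3,
                                            col_ids=[f"g:pc{l}" for l in (1, 2, 3)]),
                      gene="g", outcome="P1")
        assert t.df == 3
        assert t.p_value < 1e-8


class TestAdjustment:
    def test_single_test_unchanged(self):
        tests = [PathTest("P1", "g", 1.0, 1, 0.04)]
        assert adjust_pvalues(tests, "bonferroni")[0].adjusted_p == pytest.approx(0.04)

    def test_bonferroni_triple(self):
        tests = [PathTest("P1", f"g{i}", 1.0, 1, p) for i, p in
                 enumerate([0.01, 0.02, 0.03])]
        adj = [t.adjusted_p for t in adjust_pvalues(tests, "bonferroni")]
        assert adj == pytest.approx([0.03, 0.06, 0.09])

    def test_bh_step_up_triple(self):
        tests = [PathTest("P1", f"g{i}", 1.0, 1, p) for i, p in
                 enumerate([0.01, 0.02, 0.03])]
        adj = [t.adjusted_p for t in adjust_pvalues(tests, "bh")]
        assert adj == pytest.approx([0.03, 0.03, 0.03])

    def test_bh_monotone_in_raw_order(self, rng):
        ps = rng.uniform(size=25)
        tests = [PathTest("P", f"g{i}", 1.0, 1, p) for i, p in enumerate(ps)]
        adjust_pvalues(tests, "bh")
        order = np.argsort(ps)
        adj = np.array([tests[i].adjusted_p for i in order])
        assert np.all(np.diff(adj) >= -1e-12)

    def test_unknown_method_raises(self):
        with pytest.raises(ValueError):
            adjust_pvalues([], "holm")


class TestStabilitySelection:
    def _edge_fit(self, on: bool):
        Gamma = -np.eye(2)
        if on:
            Gamma[0, 1] = 0.5
        return SemFit(Gamma=Gamma, B=np.zeros((1, 2)), sigma2=np.ones(2),
                      lam=np.zeros(2),
                      support_gamma=(Gamma != 0) & ~np.eye(2, dtype=bool),
                      support_b=np.zeros((1, 2), bool),
                      phenotype_names=["P1", "P2"], column_ids=["x1"])

    def test_frequency_boundary(self, rng):
        # 79/100 resample selections with p=0.001 -> dropped at 0.8;
        # 80/100 -> kept
        for n_hits, kept in [(79, False), (80, True)]:
            calls = {"i": -1}  # call 0 is the full-data fit

            def fit_fn(Yv, Xv):
                calls["i"] += 1
                return self._edge_fit(calls["i"] == 0 or calls["i"] <= n_hits)

            out = stability_selection(rng.normal(size=(20, 2)),
                                      rng.normal(size=(20, 1)), fit_fn,
                                      n_resamples=100,
                                      tests={("P1", "P2"): 0.001})
            (edge,) = out
            assert edge["stability"] == pytest.approx(n_hits / 100)
            assert edge["kept"] is kept

    def test_p_value_gate(self, rng):
        out = stability_selection(rng.normal(size=(20, 2)),
                                  rng.normal(size=(20, 1)),
                                  lambda Yv, Xv: self._edge_fit(True),
                                  n_resamples=20,
                                  tests={("P1", "P2"): 0.2}, p_thresh=0.05)
        assert out[0]["stability"] == 1.0 and out[0]["kept"] is False

    def test_true_edges_more_stable_than_null(self, small_system):
        from sparsesem import fit_s2sem

        Y, X = small_system["Y"], small_system["X"]
        lam = 3.0
        out = stability_selection(Y.values, X.values,
                                  lambda Yv, Xv: fit_s2sem(Yv, Xv, lam),
                                  n_resamples=25, seed=1)
        truth = {(f"P{j+1}", f"P{i+1}") for j, i in small_system["gamma_edges"]} | \
                {(f"x{k+1}", f"P{i+1}") for k, i in small_system["b_edges"]}
        stab_true = [e["stability"] for e in out if (e["source"], e["target"]) in truth]
        stab_null = [e["stability"] for e in out if (e["source"], e["target"]) not in truth]
        if stab_true and stab_null:
            assert np.mean(stab_true) > np.mean(stab_null)


def test_restricted_design_keeps_names(small_system):
    d = _restricted_design(small_system["Y"], small_system["X"], 1)
    assert d.col_names[:2] == ["P1", "P3"]
    assert d.col_names[2] == "snp1"
    assert abs(d.y.mean()) < 1e-10
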