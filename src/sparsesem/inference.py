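"""Tests for path coefficients, multiplicity adjustment, stability selection.

After support selection, coefficients are re-estimated without penalty on
the selected columns (classical two-stage least squares), giving the
covariance

    Sigma_i = sigma_ii [W_i' X (X'X)^{-1} X' W_i]^{-1},
    sigma_ii = ||y_i - W_i Delta_hat_i||^2 / n,

restricted to the selected columns.  The gene-level statistic for the block
of G FPC coefficients b_ji is T_g = b_ji' Lambda_i^{-1} b_ji ~ chi2(G) under
the null, and the single-coefficient statistic is T_c = Delta_il^2 /
var(Delta_il) ~ chi2(1).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import stats
from statsmodels.stats.multitest import multipletests

from .datamodel import GenotypeData, PhenotypeMatrix, SemFit, SparseSemError
from .solver import EquationDesign, build_design, normal_matrices

_center = lambda a: a - a.mean(axis=0, keepdims=True)  # noqa: E731


@dataclass
class PathTest:
    """Result of a path-coefficient hypothesis test."""

    outcome: str
    causal: str
    statistic: float
    df: int
    p_value: float
    estimate: np.ndarray | float | None = None
    adjusted_p: float | None = None
    stability: float | None = None


def _restricted_design(Y, X, i: int) -> EquationDesign:
    """Equation design on mean-centred data, keeping column names."""
    Yv = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, float)
    Xv = X.values if isinstance(X, GenotypeData) else np.asarray(X, float)
    design = build_design(Y, X, i)  # for the names
    return EquationDesign(y=_center(Yv[:, i]), W=_center(design.W),
                          instrument=_center(Xv), col_names=design.col_names,
                          n_pheno_cols=design.n_pheno_cols)


def coef_covariance(design: EquationDesign, support: np.ndarray,
                    ridge: float = 0.0):
    """Unpenalised refit on the selected columns and its covariance.

    Returns ``(delta, Sigma, sigma_ii)`` for the columns flagged in
    ``support`` (boolean mask over the design's columns).
    """
    support = np.asarray(support, dtype=bool)
    if not support.any():
        raise SparseSemError("empty support: nothing to test")
    Ws = design.W[:, support]
    sub = EquationDesign(y=design.y, W=Ws, instrument=design.instrument,
                         col_names=[c for c, s in zip(design.col_names, support) if s],
                         n_pheno_cols=int(support[:design.n_pheno_cols].sum()))
    A, M, b = normal_matrices(sub, ridge)
    bracket = A.T @ M @ A
    evals = np.linalg.eigvalsh(bracket)
    if evals[0] <= 1e-10 * max(evals[-1], 1e-300):
        raise SparseSemError(
            "singular covariance bracket on the selected support; reduce the "
            "support or increase the sample size")
    delta = np.linalg.solve(bracket, A.T @ (M @ b))
    resid = sub.y - Ws @ delta
    n = sub.y.size
    sigma_ii = float(resid @ resid) / n
    Sigma = sigma_ii * np.linalg.inv(bracket)
    return delta, Sigma, sigma_ii


def _support_vector(fit: SemFit, i: int) -> np.ndarray:
    others = [j for j in range(fit.M) if j != i]
    return np.concatenate([fit.support_gamma[others, i], fit.support_b[:, i]])


def _refit_with_fallback(design, support, must_cols, ridge):
    """Unpenalised refit for testing; shrink to essentials if singular.

    The selected support plus the tested block can exceed the number of
    effective instruments.  In that case the refit falls back to the
    equation's phenotype support plus the tested columns, which is the
    smallest refit that still adjusts for the phenotype network.
    """
    try:
        delta, Sigma, _ = coef_covariance(design, support, ridge)
        return delta, Sigma, support
    except SparseSemError:
        fallback = np.zeros_like(support)
        fallback[:design.n_pheno_cols] = support[:design.n_pheno_cols]
        fallback[list(must_cols)] = True
        delta, Sigma, _ = coef_covariance(design, fallback, ridge)
        return delta, Sigma, fallback


def test_single(Y, X, fit: SemFit, column: str, outcome: str,
                ridge: float = 0.0) -> PathTest:
    """Chi-square(1) test of one path coefficient in one equation.

    ``column`` names either another phenotype or an exogenous column.  The
    tested column is added to the selected support before the unpenalised
    refit, so coefficients dropped by the lasso can still be tested.
    """
    i = fit.phenotype_names.index(outcome)
    design = _restricted_design(Y, X, i)
    l = design.col_names.index(column)
    support = _support_vector(fit, i)
    support[l] = True
    delta, Sigma, support = _refit_with_fallback(design, support, [l], ridge)
    pos = int(support[:l].sum())
    var = Sigma[pos, pos]
    if var <= 0:
        raise SparseSemError(f"zero variance for coefficient {column} -> {outcome}")
    T = float(delta[pos] ** 2 / var)
    return PathTest(outcome=outcome, causal=column, statistic=T, df=1,
                    p_value=float(stats.chi2.sf(T, 1)), estimate=float(delta[pos]))


def test_gene(Y, eta, fit, gene: str, outcome: str, ridge: float = 0.0) -> PathTest:
    """Chi-square(G) test of a gene's whole FPC coefficient block.

    Accepts an :class:`~sparsesem.fsem.FsemFit` or a plain :class:`SemFit`
    together with a design carrying ``gene_blocks``.  The gene's block is
    always included in the unpenalised refit, alongside the selected
    support of the equation.
    """
    sem = getattr(fit, "sem", fit)
    blocks = getattr(fit, "gene_blocks", None) or getattr(eta, "gene_blocks", None)
    if blocks is None or gene not in blocks:
        raise SparseSemError(f"gene {gene} has no column block in the design")
    i = sem.phenotype_names.index(outcome)
    design = _restricted_design(Y, eta, i)
    block = blocks[gene]
    n_ph = design.n_pheno_cols
    support = _support_vector(sem, i)
    block_cols = np.arange(n_ph + block.start, n_ph + block.stop)
    support[block_cols] = True
    delta, Sigma, support = _refit_with_fallback(design, support, block_cols, ridge)
    pos = np.array([int(support[:c].sum()) for c in block_cols])
    b = delta[pos]
    Lam = Sigma[np.ix_(pos, pos)]
    T = float(b @ np.linalg.solve(Lam, b))
    G = b.size
    return PathTest(outcome=outcome, causal=gene, statistic=T, df=G,
                    p_value=float(stats.chi2.sf(T, G)), estimate=b)


def adjust_pvalues(tests: list[PathTest], method: str = "bh") -> list[PathTest]:
    """Attach multiplicity-adjusted p-values (Bonferroni or BH step-up)."""
    if method not in ("bonferroni", "bh"):
        raise ValueError(f"unknown adjustment method {method!r}")
    pvals = np.array([t.p_value for t in tests])
    if pvals.size == 0:
        return tests
    adj = multipletests(pvals, method="bonferroni" if method == "bonferroni"
                        else "fdr_bh")[1]
    for t, a in zip(tests, adj):
        t.adjusted_p = float(a)
    return tests


def stability_selection(Y, X, fit_procedure, n_resamples: int = 100,
                        p_thresh: float = 0.05, freq_thresh: float = 0.8,
                        scheme: str = "bootstrap", seed: int = 0,
                        tests: dict | None = None):
    """Edge selection by resampling frequency combined with a p-value gate.

    ``fit_procedure(Yv, Xv)`` must return a :class:`SemFit` (or FsemFit) on
    the given arrays.  The full-data fit defines candidate edges and their
    p-values (``tests`` maps (source, target) -> p-value; candidates with
    no entry pass the p gate).  An edge is kept iff its full-data p-value
    is below ``p_thresh`` and it is selected in at least ``freq_thresh`` of
    the resampled fits.  Resampling is a bootstrap of size n (or n/2
    subsampling without replacement when ``scheme='subsample'``).

    Returns a list of dicts with source, target, coefficient, p_value,
    stability and kept.
    """
    if not (0 < p_thresh <= 1 and 0 < freq_thresh <= 1):
        raise ValueError("thresholds must lie in (0, 1]")
    Yv = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, float)
    Xv = X.values if isinstance(X, GenotypeData) else np.asarray(X, float)
    n = Yv.shape[0]
    rng = np.random.default_rng(seed)

    full = fit_procedure(Yv, Xv)
    full_sem = getattr(full, "sem", full)
    edges = {(s, t): c for s, t, c in full_sem.gamma_edges() + full_sem.b_edges()}
    counts = {e: 0 for e in edges}
    for _ in range(n_resamples):
        if scheme == "bootstrap":
            idx = rng.integers(0, n, size=n)
        elif scheme == "subsample":
            idx = rng.permutation(n)[: n // 2]
        else:
            raise ValueError(f"unknown resampling scheme {scheme!r}")
        try:
            refit = fit_procedure(Yv[idx], Xv[idx])
        except SparseSemError as exc:
            warnings.warn(f"resample dropped: {exc}")
            continue
        sem = getattr(refit, "sem", refit)
        seen = {(s, t) for s, t, _ in sem.gamma_edges() + sem.b_edges()}
        for e in counts:
            if e in seen:
                counts[e] += 1

    tests = tests or {}
    out = []
    for (s, t), coef in sorted(edges.items()):
        freq = counts[(s, t)] / n_resamples
        p = tests.get((s, t), np.nan)
        kept = (np.isnan(p) or p < p_thresh) and freq >= freq_thresh
        out.append({"source": s, "target": t, "coefficient": coef,
                    "p_value": p, "stability": freq, "kept": bool(kept)})
    return out
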