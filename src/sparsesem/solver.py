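"""Sparse two-stage least squares estimation of structural equation models.

Each structural equation  y_i = W_i @ Delta_i + e_i  with W_i = [Y_{-i}, X]
is estimated by generalised least squares using the exogenous matrix X as
instruments,

    Delta_hat_i = [W_i' X (X'X)^{-1} X' W_i]^{-1} W_i' X (X'X)^{-1} X' y_i,

which coincides with the classical two-stage procedure (regress Y_{-i} on X,
then regress y_i on [Yhat_{-i}, X]).  Sparsity in Gamma and B is obtained by
minimising the GLS criterion plus an L1 penalty,

    f(Delta) + lambda * ||Delta||_1,
    f(Delta) = (X'y - X'W Delta)' (X'X)^{-1} (X'y - X'W Delta),

solved per equation with a scaled-form ADMM: writing A = X'W, M = (X'X)^{-1}
and b = X'y, the quadratic update solves (2A'MA + rho I) Delta = 2A'Mb +
rho (z - u), the z-update is elementwise soft-thresholding at lambda/rho,
and u accumulates the scaled dual residual.  The returned solution is z,
whose zeros are exact.  The penalty is selected per equation by K-fold
cross-validation on the held-out GLS criterion.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy import linalg

from .datamodel import GenotypeData, PhenotypeMatrix, SemFit, SparseSemError

_EIG_FLOOR = 1e-10  # relative eigenvalue floor for (X'X)^{-1}


@dataclass
class AdmmConfig:
    """ADMM settings: augmented-Lagrangian rho, iteration cap, tolerances."""

    rho: float = 1.0
    max_iter: int = 2000
    tol_abs: float = 1e-6
    tol_rel: float = 1e-4
    lam: float = 0.0

    def __post_init__(self) -> None:
        if self.rho <= 0 or self.tol_abs <= 0 or self.tol_rel <= 0:
            raise ValueError("rho and tolerances must be positive")


@dataclass
class EquationDesign:
    """One structural equation in regression form.

    ``W`` stacks the other phenotypes first, then the exogenous columns;
    ``instrument`` is the full exogenous matrix X (or the FPC score matrix
    eta), used both as regressors and as instruments.
    """

    y: np.ndarray
    W: np.ndarray
    instrument: np.ndarray
    col_names: list[str]
    n_pheno_cols: int  # leading columns of W that are endogenous


def build_design(Y, X, i: int) -> EquationDesign:
    """Design for equation ``i`` (0-based): W_i = [Y_{-i}, X].

    With a single phenotype the design degenerates to W = X.
    """
    Yv = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, float)
    Xv = X.values if isinstance(X, GenotypeData) else np.asarray(X, float)
    pnames = Y.phenotype_names if isinstance(Y, PhenotypeMatrix) else [
        f"P{j+1}" for j in range(Yv.shape[1])]
    xnames = X.column_ids if isinstance(X, GenotypeData) else [
        f"x{k+1}" for k in range(Xv.shape[1])]
    n, M = Yv.shape
    if not (0 <= i < M):
        raise IndexError(f"equation index {i} out of range for M={M}")
    if Xv.shape[0] != n:
        raise SparseSemError("Y and X row counts differ")
    others = [j for j in range(M) if j != i]
    W = np.column_stack([Yv[:, others], Xv]) if others else Xv.copy()
    names = [pnames[j] for j in others] + list(xnames)
    return EquationDesign(y=Yv[:, i].copy(), W=W, instrument=Xv,
                          col_names=names, n_pheno_cols=len(others))


def _inv_psd(S: np.ndarray, ridge: float = 0.0):
    """Inverse of a symmetric PSD matrix via eigendecomposition with floor."""
    S = S + ridge * np.eye(S.shape[0])
    evals, evecs = np.linalg.eigh(S)
    floor = _EIG_FLOOR * max(np.trace(S), 1e-300)
    evals = np.maximum(evals, floor)
    return (evecs / evals) @ evecs.T


def normal_matrices(design: EquationDesign, ridge: float = 0.0):
    """A = X'W, M = (X'X + ridge I)^{-1}, b = X'y for the GLS criterion."""
    X = design.instrument
    A = X.T @ design.W
    b = X.T @ design.y
    M = _inv_psd(X.T @ X, ridge)
    return A, M, b


def gls_objective(delta, A, M, b) -> float:
    """f(Delta) = (b - A Delta)' M (b - A Delta)."""
    r = b - A @ delta
    return float(r @ M @ r)


def gls_estimate(design: EquationDesign, ridge: float = 0.0) -> np.ndarray:
    """Unpenalised GLS / two-stage least squares estimate of Delta_i.

    Raises when the bracket W'X(X'X)^{-1}X'W is rank deficient and no ridge
    is supplied (more regressors than instruments): the advice then is to
    pass a positive ridge or to reduce dimension (gene-level FPC scores).
    """
    A, M, b = normal_matrices(design, ridge)
    bracket = A.T @ M @ A
    rhs = A.T @ (M @ b)
    evals = np.linalg.eigvalsh(bracket)
    if evals[0] <= _EIG_FLOOR * max(evals[-1], 1e-300):
        if ridge == 0.0:
            raise SparseSemError(
                "singular GLS bracket (more regressors than effective "
                "instruments); supply ridge > 0 or reduce dimension with "
                "gene-level FPC scores")
        bracket = bracket + ridge * np.eye(bracket.shape[0])
    return np.linalg.solve(bracket, rhs)


def lambda_max(design: EquationDesign, ridge: float = 0.0) -> float:
    """Smallest penalty shrinking the whole equation to zero: 2||A'Mb||_inf."""
    A, M, b = normal_matrices(design, ridge)
    return 2.0 * float(np.max(np.abs(A.T @ (M @ b)))) if A.size else 0.0


def _soft(v, k):
    return np.sign(v) * np.maximum(np.abs(v) - k, 0.0)


class _AdmmWorkspace:
    """Factorisations of the quadratic update, cached per rho value."""

    def __init__(self, A, M, b, rho):
        self.A, self.M, self.b, self.rho0 = A, M, b, rho
        MA = M @ A
        self.AtMA = A.T @ MA
        self.Atmb = A.T @ (M @ b)
        self.p = A.shape[1]
        self._chol_cache: dict[float, tuple] = {}

    def _chol(self, rho):
        f = self._chol_cache.get(rho)
        if f is None:
            f = linalg.cho_factor(2.0 * self.AtMA + rho * np.eye(self.p))
            self._chol_cache[rho] = f
        return f

    def solve(self, lam, config: AdmmConfig, z0=None, u0=None):
        # scaled-form ADMM with residual-balancing rho updates
        rho = self.rho0
        p = self.p
        z = np.zeros(p) if z0 is None else z0.copy()
        u = np.zeros(p) if u0 is None else u0.copy()
        q0 = 2.0 * self.Atmb
        converged = False
        it = 0
        for it in range(1, config.max_iter + 1):
            delta = linalg.cho_solve(self._chol(rho), q0 + rho * (z - u))
            z_old = z
            z = _soft(delta + u, lam / rho)
            u = u + delta - z
            r_norm = np.linalg.norm(delta - z)
            s_norm = np.linalg.norm(rho * (z - z_old))
            eps_pri = np.sqrt(p) * config.tol_abs + config.tol_rel * max(
                np.linalg.norm(delta), np.linalg.norm(z))
            eps_dual = np.sqrt(p) * config.tol_abs + config.tol_rel * np.linalg.norm(rho * u)
            if r_norm <= eps_pri and s_norm <= eps_dual:
                converged = True
                break
            if r_norm > 10.0 * s_norm:
                rho *= 2.0
                u /= 2.0
            elif s_norm > 10.0 * r_norm:
                rho /= 2.0
                u *= 2.0
        return z, u, it, converged


def admm_lasso(design: EquationDesign, config: AdmmConfig, ridge: float = 0.0):
    """Minimise f(Delta) + lam ||Delta||_1 for one equation by ADMM.

    Returns ``(delta, iterations, converged)``; ``delta`` is the z iterate,
    so shrunken entries are exactly zero.  At lam = 0 the solution matches
    :func:`gls_estimate` (when the GLS bracket is nonsingular).
    """
    A, M, b = normal_matrices(design, ridge)
    ws = _AdmmWorkspace(A, M, b, config.rho)
    z, _, it, converged = ws.solve(config.lam, config)
    if not converged:
        warnings.warn(f"ADMM did not converge in {config.max_iter} iterations "
                      f"(lambda={config.lam:g})")
    return z, it, converged


def _center(a):
    return a - a.mean(axis=0, keepdims=True)


def _standardize(a):
    """Centre and scale columns to unit sd; returns (scaled, scale)."""
    c = _center(a)
    s = c.std(axis=0)
    s[s == 0] = 1.0
    return c / s, s


def _as_arrays(Y, X):
    Yv = Y.values if isinstance(Y, PhenotypeMatrix) else np.asarray(Y, float)
    Xv = X.values if isinstance(X, GenotypeData) else np.asarray(X, float)
    pnames = Y.phenotype_names if isinstance(Y, PhenotypeMatrix) else [
        f"P{j+1}" for j in range(Yv.shape[1])]
    xnames = X.column_ids if isinstance(X, GenotypeData) else [
        f"x{k+1}" for k in range(Xv.shape[1])]
    if isinstance(Y, PhenotypeMatrix) and isinstance(X, GenotypeData):
        from .io import check_sample_alignment

        check_sample_alignment(X.sample_ids, Y.sample_ids)
    return Yv, Xv, pnames, xnames


def fit_s2sem(Y, X, lam, config: AdmmConfig | None = None, ridge: float = 0.0,
              standardize: bool = True) -> SemFit:
    """Fit the sparse SEM: per-equation ADMM lasso on the GLS criterion.

    ``lam`` may be a scalar or a length-M sequence of per-equation
    penalties.  Columns of Y and X are mean-centred before fitting (the
    structural system has no intercepts); ``standardize`` additionally
    scales columns to unit variance (coefficients are mapped back to the
    original scale).
    """
    config = config or AdmmConfig()
    Yv, Xv, pnames, xnames = _as_arrays(Y, X)
    n, M = Yv.shape
    K = Xv.shape[1]
    lam_vec = np.broadcast_to(np.asarray(lam, float), (M,)).copy()

    if standardize:
        Yc, y_scale = _standardize(Yv)
        Xc, x_scale = _standardize(Xv)
    else:
        Yc, Xc = _center(Yv), _center(Xv)
        y_scale, x_scale = np.ones(M), np.ones(K)

    Gamma = -np.eye(M)
    B = np.zeros((K, M))
    sigma2 = np.zeros(M)
    conv = np.zeros(M, dtype=bool)
    for i in range(M):
        design = build_design(Yc, Xc, i)
        cfg = AdmmConfig(rho=config.rho, max_iter=config.max_iter,
                         tol_abs=config.tol_abs, tol_rel=config.tol_rel,
                         lam=float(lam_vec[i]))
        try:
            delta, _, ok = admm_lasso(design, cfg, ridge=ridge)
        except SparseSemError as exc:  # continue with remaining equations
            warnings.warn(f"equation {pnames[i]}: {exc}")
            delta = np.zeros(design.W.shape[1])
            ok = False
        conv[i] = ok
        others = [j for j in range(M) if j != i]
        gam = delta[:design.n_pheno_cols]
        beta = delta[design.n_pheno_cols:]
        for pos, j in enumerate(others):  # undo standardisation: y_i scale
            Gamma[j, i] = gam[pos] * y_scale[i] / y_scale[j]
        B[:, i] = beta * y_scale[i] / x_scale
        resid = Yc[:, i] - design.W @ delta
        sigma2[i] = float(resid @ resid) / n * y_scale[i] ** 2
    return SemFit(Gamma=Gamma, B=B, sigma2=sigma2, lam=lam_vec,
                  support_gamma=(np.abs(Gamma) > 0) & ~np.eye(M, dtype=bool),
                  support_b=B != 0, phenotype_names=list(pnames),
                  column_ids=list(xnames), converged=conv)


def lambda_grid(Y, X, n_points: int = 10, min_ratio: float = 0.02,
                ridge: float = 0.0, standardize: bool = True) -> np.ndarray:
    """Descending log-spaced grid from the largest per-equation lambda_max.

    The floor at ``min_ratio`` times lambda_max plays the role of glmnet's
    small-lambda cutoff: because each equation has more candidate columns
    than instruments, the held-out GLS criterion cannot penalise movement
    in the unidentified directions and keeps decreasing as lambda -> 0, so
    the grid floor bounds the density of the cross-validated solution.
    """
    Yv, Xv, _, _ = _as_arrays(Y, X)
    Yc = _standardize(Yv)[0] if standardize else _center(Yv)
    Xc = _standardize(Xv)[0] if standardize else _center(Xv)
    lmax = max(lambda_max(build_design(Yc, Xc, i), ridge)
               for i in range(Yv.shape[1]))
    if lmax <= 0:
        lmax = 1.0
    return np.geomspace(lmax, lmax * min_ratio, n_points)


def cross_validate_lambda(Y, X, grid, folds: int = 5, seed: int = 0,
                          config: AdmmConfig | None = None,
                          ridge: float = 0.0, standardize: bool = True) -> np.ndarray:
    """Per-equation penalty minimising the mean held-out GLS criterion.

    Folds are assigned by a seeded permutation, so the split is
    deterministic given ``seed``.  Columns are standardised within each
    training/validation fold to match the fitting convention.  Ties are
    broken toward the largest (sparsest) penalty.
    """
    config = config or AdmmConfig()
    grid = np.sort(np.asarray(grid, float))[::-1]
    if grid.size == 0 or np.any(grid < 0):
        raise ValueError("lambda grid must be non-empty and nonnegative")
    Yv, Xv, _, _ = _as_arrays(Y, X)
    n, M = Yv.shape
    if n < folds:
        raise SparseSemError(f"n={n} samples cannot be split into {folds} folds")
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    fold_of = np.empty(n, dtype=int)
    for f, chunk in enumerate(np.array_split(perm, folds)):
        fold_of[chunk] = f

    scores = np.zeros((M, grid.size))
    prep = (lambda a: _standardize(a)[0]) if standardize else _center
    for f in range(folds):
        tr, te = fold_of != f, fold_of == f
        Ytr, Xtr = prep(Yv[tr]), prep(Xv[tr])
        Yte, Xte = prep(Yv[te]), prep(Xv[te])
        for i in range(M):
            d_tr = build_design(Ytr, Xtr, i)
            d_te = build_design(Yte, Xte, i)
            A, Mm, b = normal_matrices(d_tr, ridge)
            At, Mt, bt = normal_matrices(d_te, ridge)
            ws = _AdmmWorkspace(A, Mm, b, config.rho)
            z = u = None
            for g, lam in enumerate(grid):  # warm-started path, dense last
                z, u, _, _ = ws.solve(lam, config, z0=z, u0=u)
                scores[i, g] += gls_objective(z, At, Mt, bt)
    scores /= folds
    best = np.zeros(M)
    for i in range(M):
        g = int(np.argmin(scores[i]))  # first index = largest lambda on ties
        best[i] = grid[g]
    return best
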