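"""Functional principal component representation of genotype profiles.

Coded genotypes of the SNPs in a gene are viewed as irregular observations
of a genotype function x_i(t) over genomic position t.  Positions are
rescaled to [0, 1] and the Karhunen-Loeve expansion is computed directly on
that grid: eigenfunctions of the empirical profile covariance under
trapezoid quadrature weights, orthonormal in the weighted inner product
<f, g> = sum_k w_k f(t_k) g(t_k).  The per-sample scores

    eta_il = sum_k w_k (x_i(t_k) - xbar(t_k)) phi_l(t_k)

compress a gene's multi-SNP information (including linkage disequilibrium)
into a handful of columns used as exogenous variables in the functional SEM.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import FpcColumn, GenotypeData, PhenotypeMatrix, SparseSemError


@dataclass
class FpcBasis:
    """Per-gene eigenfunctions, eigenvalues and sample scores."""

    gene_id: str
    grid: np.ndarray           # m rescaled positions in [0, 1]
    weights: np.ndarray        # trapezoid quadrature weights
    mean_profile: np.ndarray   # m values
    eigenfunctions: np.ndarray  # m x L, orthonormal under the weights
    eigenvalues: np.ndarray    # L, descending
    scores: np.ndarray         # n x L
    var_explained: np.ndarray = field(default=None)  # cumulative fraction

    @property
    def L(self) -> int:
        return self.eigenvalues.size

    @property
    def n(self) -> int:
        return self.scores.shape[0]


def rescale_positions(positions) -> np.ndarray:
    """Map strictly increasing genomic positions onto [0, 1].

    A single position maps to 0.5.  Duplicate positions are jittered
    deterministically (by multiples of one part in 10^6 of the span) with
    a warning, then rescaled.  Any affine transform of the raw positions
    yields the same grid, so downstream scores do not depend on units.
    """
    pos = np.asarray(positions, dtype=float)
    if pos.size == 1:
        return np.array([0.5])
    if np.any(np.diff(pos) < 0):
        raise SparseSemError("positions must be non-decreasing")
    if np.any(np.diff(pos) == 0):
        warnings.warn("duplicate SNP positions; applying deterministic jitter")
        span = max(pos[-1] - pos[0], 1.0)
        for k in range(1, pos.size):
            if pos[k] <= pos[k - 1]:
                pos[k] = pos[k - 1] + 1e-6 * span
    return (pos - pos[0]) / (pos[-1] - pos[0])


def trapezoid_weights(grid: np.ndarray) -> np.ndarray:
    """Quadrature weights for the (possibly irregular) grid; [1] for m=1."""
    if grid.size == 1:
        return np.ones(1)
    w = np.empty_like(grid)
    w[0] = (grid[1] - grid[0]) / 2
    w[-1] = (grid[-1] - grid[-2]) / 2
    if grid.size > 2:
        w[1:-1] = (grid[2:] - grid[:-2]) / 2
    return w


def genotype_function(X_gene, positions):
    """Represent coded genotypes as profiles on the rescaled [0,1] grid.

    Returns ``(profiles, grid, weights)``; profiles are returned unchanged
    (the grid is what changes), so this is the discretised functional view.
    """
    X_gene = np.asarray(X_gene, dtype=float)
    if X_gene.ndim != 2 or X_gene.shape[1] != len(np.atleast_1d(positions)):
        raise SparseSemError("X_gene must be n x m with one column per position")
    grid = rescale_positions(positions)
    return X_gene, grid, trapezoid_weights(grid)


def fpc_scores(X_gene, positions, gene_id: str = "gene", var_target: float = 0.8,
               min_eigval_ratio: float = 1e-10) -> FpcBasis:
    """Discretised FPCA of a gene's coded-genotype profiles.

    Keeps the smallest number of components whose eigenvalues explain at
    least ``var_target`` of total profile variance; components below
    ``min_eigval_ratio`` times the leading eigenvalue are always dropped.
    """
    if not (0.0 < var_target <= 1.0):
        raise ValueError("var_target must lie in (0, 1]")
    profiles, grid, w = genotype_function(X_gene, positions)
    n, m = profiles.shape
    if n < 2:
        raise SparseSemError("FPCA needs at least two samples")
    mean_profile = profiles.mean(axis=0)
    Xc = profiles - mean_profile
    if np.allclose(Xc, 0.0):
        raise SparseSemError(f"gene {gene_id} is monomorphic: zero profile variance")

    # weighted SVD: eigenfunctions of the quadrature-weighted covariance
    S = Xc * np.sqrt(w)
    _, sing, vt = np.linalg.svd(S / np.sqrt(n - 1), full_matrices=False)
    evals = sing**2
    keep = evals > min_eigval_ratio * evals[0]
    evals = evals[keep]
    V = vt[keep].T  # m x r, orthonormal in the Euclidean sense

    frac = np.cumsum(evals) / evals.sum()
    L = int(np.searchsorted(frac, var_target - 1e-12) + 1)
    evals = evals[:L]
    V = V[:, :L]
    phi = V / np.sqrt(w)[:, None]       # orthonormal under the weights
    scores = (Xc * w) @ phi             # quadrature projection of profiles
    return FpcBasis(gene_id=gene_id, grid=grid, weights=w,
                    mean_profile=mean_profile, eigenfunctions=phi,
                    eigenvalues=evals, scores=scores,
                    var_explained=frac[:L])


def fpca_by_gene(X: GenotypeData, regions, var_target: float = 0.8,
                 min_eigval_ratio: float = 1e-10) -> list[FpcBasis]:
    """Run :func:`fpc_scores` for every gene region of a coded SNP matrix."""
    bases = []
    for region in regions:
        idx = list(region.snp_indices)
        pos = [X.columns[k].position for k in idx]
        order = np.argsort(pos)
        idx = [idx[o] for o in order]
        bases.append(fpc_scores(X.values[:, idx], np.sort(pos),
                                gene_id=region.gene_id, var_target=var_target,
                                min_eigval_ratio=min_eigval_ratio))
    return bases


def build_fsem_design(Y, bases: list[FpcBasis]) -> GenotypeData:
    """Concatenate per-gene score blocks into the exogenous matrix eta.

    Column descriptors record (gene_id, component) and ``gene_blocks`` maps
    each gene to its column slice, used later for gene-level tests.
    """
    if not bases:
        raise SparseSemError("no FPC bases supplied")
    n = bases[0].n
    sample_ids = Y.sample_ids if isinstance(Y, PhenotypeMatrix) else [
        f"s{i+1}" for i in range(n)]
    cols, descriptors, blocks = [], [], {}
    start = 0
    for basis in bases:
        if basis.n != n:
            raise SparseSemError(
                f"gene {basis.gene_id}: score matrix has {basis.n} samples, expected {n}")
        cols.append(basis.scores)
        descriptors.extend(FpcColumn(gene_id=basis.gene_id, component=l + 1)
                           for l in range(basis.L))
        blocks[basis.gene_id] = slice(start, start + basis.L)
        start += basis.L
    return GenotypeData(values=np.column_stack(cols), columns=descriptors,
                        sample_ids=list(sample_ids), gene_blocks=blocks)
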