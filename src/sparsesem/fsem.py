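"""Gene-based sparse functional SEM fitting and two-stage genome screening.

The functional system replaces per-SNP columns by per-gene FPC score blocks:
Y Gamma + eta B + E = 0, estimated with exactly the same penalised
two-stage least squares solver, with eta standing in for X.  The genetic
effect of gene j on phenotype i is the coefficient function

    beta_ji(t) = sum_g b_jig phi_jg(t)

on the gene's position grid, recovered from the fitted block coefficients
and the gene's eigenfunctions.

Whole-genome analyses proceed in two stages: genes are split into groups
(pathways or chromosome-order chunks), the FSEM is fitted per group and
genes with any nominally significant path coefficient are retained; the
retained genes are then pooled and refitted jointly.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .datamodel import GenotypeData, SemFit, SparseSemError
from .fpca import FpcBasis, build_fsem_design
from .solver import AdmmConfig, cross_validate_lambda, fit_s2sem, lambda_grid


@dataclass
class FsemFit:
    """A :class:`SemFit` on FPC scores plus the gene -> column-block map."""

    sem: SemFit
    gene_blocks: dict[str, slice]
    bases: dict[str, FpcBasis]

    @property
    def Gamma(self):
        return self.sem.Gamma

    @property
    def B(self):
        return self.sem.B

    def gene_support(self) -> dict[tuple[str, str], bool]:
        """(gene, phenotype) -> any nonzero coefficient in the gene block."""
        out = {}
        for gene, block in self.gene_blocks.items():
            for i, pheno in enumerate(self.sem.phenotype_names):
                out[(gene, pheno)] = bool(self.sem.support_b[block, i].any())
        return out


def fit_fsem(Y, eta: GenotypeData, lam, config: AdmmConfig | None = None,
             bases: list[FpcBasis] | None = None, ridge: float = 0.0) -> FsemFit:
    """Fit the sparse functional SEM on an FPC score design.

    ``eta`` must come from :func:`sparsesem.fpca.build_fsem_design` (or at
    least carry ``gene_blocks``); the solver path is identical to the
    SNP-based fit with X replaced by eta.
    """
    if eta.gene_blocks is None:
        raise SparseSemError("eta must carry gene_blocks (use build_fsem_design)")
    sem = fit_s2sem(Y, eta, lam, config=config, ridge=ridge)
    base_map = {b.gene_id: b for b in bases} if bases else {}
    return FsemFit(sem=sem, gene_blocks=dict(eta.gene_blocks), bases=base_map)


def effect_function(fit: FsemFit, gene: str, phenotype: str,
                    basis: FpcBasis | None = None):
    """Genetic effect function beta_ji(t) of ``gene`` on ``phenotype``.

    Returns ``(grid, values, selected)``; ``selected`` is False when the
    gene block is entirely outside the fitted support (the function is then
    identically zero).
    """
    basis = basis or fit.bases.get(gene)
    if basis is None:
        raise SparseSemError(f"no FPC basis available for gene {gene}")
    if gene not in fit.gene_blocks:
        raise SparseSemError(f"gene {gene} not in the fitted design")
    i = fit.sem.phenotype_names.index(phenotype)
    b = fit.B[fit.gene_blocks[gene], i]
    values = basis.eigenfunctions[:, : b.size] @ b
    selected = bool(np.any(b != 0))
    return basis.grid, values, selected


def screen_and_refit(Y, bases: list[FpcBasis], groups: dict[str, list[str]] | None = None,
                     alpha1: float = 0.05, config: AdmmConfig | None = None,
                     grid_points: int = 8, cv_folds: int = 5, seed: int = 0,
                     max_group_size: int = 100, ridge: float = 0.0):
    """Two-stage whole-genome network construction.

    Stage 1 fits the FSEM separately within each gene group (CV-selected
    penalty per group) and retains genes whose gene-level test has p-value
    below ``alpha1`` for any phenotype.  Stage 2 refits the FSEM on the
    union of retained genes.  Returns ``(final_fit_or_None, retained_genes,
    stage1_tests)``.
    """
    from .inference import test_gene

    base_map = {b.gene_id: b for b in bases}
    if groups is None:
        gene_ids = list(base_map)
        groups = {f"group{g+1}": gene_ids[g * max_group_size:(g + 1) * max_group_size]
                  for g in range((len(gene_ids) + max_group_size - 1) // max_group_size)}

    retained: list[str] = []
    stage1_tests = []
    for group_id, gene_ids in sorted(groups.items()):
        group_bases = [base_map[g] for g in gene_ids if g in base_map]
        if not group_bases:
            continue
        eta = build_fsem_design(Y, group_bases)
        grid = lambda_grid(Y, eta, n_points=grid_points, ridge=ridge)
        lam = cross_validate_lambda(Y, eta, grid, folds=cv_folds, seed=seed,
                                    config=config, ridge=ridge)
        fit = fit_fsem(Y, eta, lam, config=config, bases=group_bases, ridge=ridge)
        for gene in (b.gene_id for b in group_bases):
            keep = False
            for pheno in fit.sem.phenotype_names:
                t = test_gene(Y, eta, fit, gene, pheno)
                stage1_tests.append(t)
                if t.p_value < alpha1:
                    keep = True
            if keep:
                retained.append(gene)

    if not retained:
        return None, [], stage1_tests

    eta2 = build_fsem_design(Y, [base_map[g] for g in retained])
    grid2 = lambda_grid(Y, eta2, n_points=grid_points, ridge=ridge)
    lam2 = cross_validate_lambda(Y, eta2, grid2, folds=cv_folds, seed=seed,
                                 config=config, ridge=ridge)
    final = fit_fsem(Y, eta2, lam2, config=config,
                     bases=[base_map[g] for g in retained], ridge=ridge)
    return final, retained, stage1_tests
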