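"""Synthetic genotype-phenotype networks and the PD/FDR evaluation harness.

The generator reproduces the study design used to benchmark the sparse SEM
estimators: a random phenotype DAG with expected total degree 3 per node,
path coefficients drawn uniformly from (0.5, 1) or (-1, -0.5) with equal
sign probability, genotype -> phenotype coefficients from (0, 1) or (-1, 0),
Hardy-Weinberg genotypes at common (MAF ~ U(0.05, 0.5)) or rare
(MAF ~ U(0.005, 0.01)) allele frequencies, and phenotypes generated from
the structural system as

    Y = -(X B + eps) Gamma^{-1},    eps ~ N(0, 0.01 I).

Network recovery is scored by the power of detection PD = N_true / N_t
(fraction of true edges recovered) and the false discovery rate
FDR = N_false / N_detected.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .datamodel import GeneRegion, GenotypeData, PhenotypeMatrix, encode_genotypes
from .fpca import fpca_by_gene, build_fsem_design
from .fsem import fit_fsem
from .solver import AdmmConfig, cross_validate_lambda, fit_s2sem, lambda_grid


@dataclass
class SimConfig:
    """Study conditions for one simulation scenario."""

    M: int = 10                      # phenotypes
    n_snps: int | None = None        # SNP-based runs
    n_genes: int | None = None       # gene-based runs
    snps_per_gene: int = 10
    maf_regime: str = "common"       # common | rare | mixed
    common_band: tuple = (0.05, 0.5)
    rare_band: tuple = (0.005, 0.01)
    n: int = 1000                    # sample size
    expected_degree: float = 3.0     # expected total degree of phenotype nodes
    noise_sd: float = 0.1            # residual sd (variance 0.01)
    variants_per_phenotype: int = 3  # genetic units affecting each phenotype
    genotype_edges: str = "per_phenotype"  # or "one_to_one" (no pleiotropy)
    n_replicates: int = 20
    seed: int = 0

    def __post_init__(self) -> None:
        if (self.n_snps is None) == (self.n_genes is None):
            raise ValueError("set exactly one of n_snps or n_genes")
        if self.noise_sd <= 0 or self.n <= 0 or self.M <= 0:
            raise ValueError("counts and noise_sd must be positive")
        if self.expected_degree >= self.M:
            raise ValueError("expected_degree must be below the phenotype count")

    @property
    def total_snps(self) -> int:
        return self.n_snps if self.n_snps is not None else self.n_genes * self.snps_per_gene

    @property
    def n_units(self) -> int:
        """Genetic units for network edges: genes if gene-based, else SNPs."""
        return self.n_genes if self.n_genes is not None else self.n_snps


@dataclass
class EvalMetrics:
    pd: float
    fdr: float
    n_true_detected: int
    n_false_detected: int
    n_detected: int
    n_true_total: int


def random_network(config: SimConfig, rng: np.random.Generator):
    """Draw the phenotype DAG (Gamma) and genotype connections (B).

    The DAG is sampled by a random topological order with independent edge
    inclusion at probability expected_degree / (M - 1), so the expected
    total degree per node equals ``expected_degree``.  ``Gamma[j, i]`` is
    the coefficient of the phenotype edge j -> i (diagonal fixed at -1).
    For gene-based configs B carries one coefficient per member SNP of
    each selected gene.  Returns (Gamma, B, gamma_edges, b_edges) with
    edge sets as (source_index, target_index) pairs over phenotype /
    genetic-unit indices.
    """
    M = config.M
    Gamma = -np.eye(M)
    order = rng.permutation(M)
    p_edge = config.expected_degree / (M - 1) if M > 1 else 0.0
    gamma_edges = set()
    for a in range(M):
        for b_ in range(a + 1, M):
            if rng.random() < p_edge:
                src, tgt = order[a], order[b_]
                sign = 1.0 if rng.random() < 0.5 else -1.0
                Gamma[src, tgt] = sign * rng.uniform(0.5, 1.0)
                gamma_edges.add((int(src), int(tgt)))

    B = np.zeros((config.total_snps, M))
    b_edges = set()
    gene_of_snp = None
    if config.n_genes is not None:
        gene_of_snp = np.repeat(np.arange(config.n_genes), config.snps_per_gene)
    if config.genotype_edges == "one_to_one":
        for i in range(M):
            unit = i % config.n_units
            _assign_unit(B, unit, i, config, gene_of_snp, rng)
            b_edges.add((int(unit), i))
    elif config.genotype_edges == "per_phenotype":
        for i in range(M):
            units = rng.choice(config.n_units,
                               size=min(config.variants_per_phenotype, config.n_units),
                               replace=False)
            for unit in units:
                _assign_unit(B, int(unit), i, config, gene_of_snp, rng)
                b_edges.add((int(unit), i))
    else:
        raise ValueError(f"unknown genotype_edges scheme {config.genotype_edges!r}")
    return Gamma, B, gamma_edges, b_edges


def _assign_unit(B, unit, pheno, config, gene_of_snp, rng):
    sign = 1.0 if rng.random() < 0.5 else -1.0
    if gene_of_snp is None:
        B[unit, pheno] = sign * rng.uniform(0.0, 1.0)
    else:
        snps = np.where(gene_of_snp == unit)[0]
        B[snps, pheno] = sign * rng.uniform(0.0, 1.0, size=snps.size)


def simulate_genotypes(config: SimConfig, rng: np.random.Generator):
    """HWE genotypes at MAFs drawn from the configured band.

    Monomorphic draws are resampled so every column is polymorphic.
    Returns (GenotypeData, gene_regions) where the coded values use the
    frequency-weighted profile coding; gene_regions is None for SNP runs.
    """
    K, n = config.total_snps, config.n
    mafs = np.empty(K)
    for k in range(K):
        if config.maf_regime == "common":
            band = config.common_band
        elif config.maf_regime == "rare":
            band = config.rare_band
        elif config.maf_regime == "mixed":
            band = config.common_band if k % 2 == 0 else config.rare_band
        else:
            raise ValueError(f"unknown maf_regime {config.maf_regime!r}")
        mafs[k] = rng.uniform(*band)

    calls = np.empty((n, K), dtype=int)
    for k in range(K):
        col = rng.binomial(2, mafs[k], size=n)
        while np.ptp(col) == 0:  # resample monomorphic columns
            col = rng.binomial(2, mafs[k], size=n)
        calls[:, k] = col

    genes = None
    positions = np.arange(1, K + 1) * 100
    gene_ids = [None] * K
    if config.n_genes is not None:
        gene_ids = [f"G{g+1}" for g in
                    np.repeat(np.arange(config.n_genes), config.snps_per_gene)]
        genes = [GeneRegion(gene_id=f"G{g+1}",
                            start=int(positions[g * config.snps_per_gene]),
                            end=int(positions[(g + 1) * config.snps_per_gene - 1]),
                            snp_indices=list(range(g * config.snps_per_gene,
                                                   (g + 1) * config.snps_per_gene)))
                 for g in range(config.n_genes)]
    freqs = [(1.0 - m, m) for m in mafs]  # q = minor/alternate allele
    X = encode_genotypes(calls, freqs, positions=positions, genes=gene_ids)
    return X, genes


def simulate_phenotypes(Gamma, B, X, noise_sd: float,
                        rng: np.random.Generator, eps=None) -> PhenotypeMatrix:
    """Solve the structural system for Y: Y = -(X B + eps) Gamma^{-1}.

    ``eps`` overrides the drawn noise matrix (the returned Y then satisfies
    Y Gamma + X B + eps = 0 exactly, up to linear-solve roundoff).
    """
    Xv = X.values if isinstance(X, GenotypeData) else np.asarray(X, float)
    n = Xv.shape[0]
    M = Gamma.shape[0]
    if eps is None:
        eps = rng.normal(0.0, noise_sd, size=(n, M))
    try:
        Y = -np.linalg.solve(Gamma.T, (Xv @ B + eps).T).T
    except np.linalg.LinAlgError as exc:
        raise ValueError("singular Gamma: phenotype system unsolvable") from exc
    sample_ids = (X.sample_ids if isinstance(X, GenotypeData)
                  else [f"s{i+1}" for i in range(n)])
    return PhenotypeMatrix(values=Y, sample_ids=list(sample_ids),
                           phenotype_names=[f"P{i+1}" for i in range(M)])


def evaluate(true_edges: set, detected_edges: set) -> EvalMetrics:
    """PD and FDR of a detected edge set against the generating truth."""
    true_edges, detected_edges = set(true_edges), set(detected_edges)
    tp = len(true_edges & detected_edges)
    fp = len(detected_edges - true_edges)
    n_det = len(detected_edges)
    n_true = len(true_edges)
    return EvalMetrics(pd=tp / n_true if n_true else 0.0,
                       fdr=fp / n_det if n_det else 0.0,
                       n_true_detected=tp, n_false_detected=fp,
                       n_detected=n_det, n_true_total=n_true)


def _detected_edges_s2sem(fit):
    det = {("gamma", j, i) for j in range(fit.M) for i in range(fit.M)
           if j != i and fit.support_gamma[j, i]}
    det |= {("b", k, i) for k in range(fit.K) for i in range(fit.M)
            if fit.support_b[k, i]}
    return det


def _detected_edges_fsem(fit, n_genes):
    sem = fit.sem
    det = {("gamma", j, i) for j in range(sem.M) for i in range(sem.M)
           if j != i and sem.support_gamma[j, i]}
    for g in range(n_genes):
        block = fit.gene_blocks[f"G{g+1}"]
        for i in range(sem.M):
            if sem.support_b[block, i].any():
                det.add(("b", g, i))
    return det


def run_replicate(config: SimConfig, estimator: str, rng: np.random.Generator,
                  cv_folds: int = 5, grid_points: int = 8,
                  admm: AdmmConfig | None = None,
                  cv_admm: AdmmConfig | None = None, var_target: float = 0.8,
                  ridge: float = 0.0) -> EvalMetrics:
    """One draw-fit-evaluate cycle of the power experiment.

    Penalty selection runs the ADMM at screening accuracy (``cv_admm``,
    default 500 iterations at tolerances 1e-5/1e-3): the held-out GLS
    criterion is insensitive to the final digits of the path solutions,
    and the final fit at the selected penalty uses full accuracy.
    """
    cv_admm = cv_admm or AdmmConfig(max_iter=500, tol_abs=1e-5, tol_rel=1e-3)
    Gamma, B, gamma_edges, b_edges = random_network(config, rng)
    X, genes = simulate_genotypes(config, rng)
    Y = simulate_phenotypes(Gamma, B, X, config.noise_sd, rng)
    truth = {("gamma", j, i) for j, i in gamma_edges} | \
            {("b", u, i) for u, i in b_edges}
    cv_seed = int(rng.integers(0, 2**31 - 1))

    if estimator == "s2sem":
        design_X = X
        grid = lambda_grid(Y, design_X, n_points=grid_points, ridge=ridge)
        lam = cross_validate_lambda(Y, design_X, grid, folds=cv_folds,
                                    seed=cv_seed, config=cv_admm, ridge=ridge)
        fit = fit_s2sem(Y, design_X, lam, config=admm, ridge=ridge)
        detected = _detected_edges_s2sem(fit)
        if config.n_genes is not None:  # collapse SNP hits to gene level
            spg = config.snps_per_gene
            detected = {(t, k // spg if t == "b" else k, i)
                        for t, k, i in detected}
    elif estimator == "fsem":
        if genes is None:
            raise ValueError("fsem estimator needs a gene-based config")
        bases = fpca_by_gene(X, genes, var_target=var_target)
        eta = build_fsem_design(Y, bases)
        grid = lambda_grid(Y, eta, n_points=grid_points, ridge=ridge)
        lam = cross_validate_lambda(Y, eta, grid, folds=cv_folds,
                                    seed=cv_seed, config=cv_admm, ridge=ridge)
        fit = fit_fsem(Y, eta, lam, config=admm, bases=bases, ridge=ridge)
        detected = _detected_edges_fsem(fit, config.n_genes)
    else:
        raise ValueError(f"unknown estimator {estimator!r}")
    return evaluate(truth, detected)


def power_experiment(config: SimConfig, estimator: str = "s2sem",
                     rng: np.random.Generator | int | None = None,
                     **kwargs) -> dict:
    """Mean PD/FDR (with Monte-Carlo standard errors) over replicates.

    Per replicate: draw a network, genotypes and phenotypes, select the
    penalty by cross-validation, fit, and score the recovered edge set.
    Failed replicates are dropped with a warning and counted.
    """
    if not isinstance(rng, np.random.Generator):
        rng = np.random.default_rng(config.seed if rng is None else rng)
    metrics: list[EvalMetrics] = []
    failures = 0
    for _ in range(config.n_replicates):
        try:
            metrics.append(run_replicate(config, estimator, rng, **kwargs))
        except Exception as exc:  # noqa: BLE001 - replicate-level robustness
            failures += 1
            warnings.warn(f"replicate failed and was dropped: {exc}")
    pds = np.array([m.pd for m in metrics])
    fdrs = np.array([m.fdr for m in metrics])
    r = max(len(metrics), 1)
    return {"pd": float(pds.mean()) if metrics else 0.0,
            "fdr": float(fdrs.mean()) if metrics else 0.0,
            "pd_se": float(pds.std(ddof=1) / np.sqrt(r)) if r > 1 else 0.0,
            "fdr_se": float(fdrs.std(ddof=1) / np.sqrt(r)) if r > 1 else 0.0,
            "n_replicates": len(metrics), "n_failed": failures,
            "replicates": metrics}
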