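"""Decomposition of effects in a linear SEM path diagram.

In a directed coefficient graph, the direct effect of X on Y is the path
coefficient of the edge X -> Y (zero if absent); the indirect effect is the
sum over all directed paths of length >= 2 of the product of the path
coefficients; the total effect is their sum, equivalently the derivative of
E[Y | do(X = x)].  For a parentless source (a SNP or gene node) the total
effect also equals the simple-regression (marginal) slope of Y on X; for a
mediating phenotype with parent set pa_X it is the coefficient of X in the
regression of Y on (X, pa_X).  The correlation identity

    beta_{YX.Z} = beta_{YX} (1 - rho_YZ rho_ZX / rho_YX) / (1 - rho_XZ^2)

links the adjusted slope to the marginal slope for a single parent Z.
"""

from __future__ import annotations

from dataclasses import dataclass

import networkx as nx
import numpy as np

from .datamodel import SemFit, SparseSemError


class CyclicNetworkError(SparseSemError):
    """Raised when a total effect is requested along a cyclic route."""


@dataclass
class EffectRecord:
    outcome: str
    causal: str
    direct: float
    indirect: float
    total: float
    marginal: float | None = None


@dataclass
class PathSet:
    """All simple directed paths source -> target with their coefficients."""

    paths: list[list[str]]          # node sequences, lexicographic order
    coefficients: list[list[float]]  # per-edge coefficients along each path

    @property
    def products(self) -> list[float]:
        return [float(np.prod(c)) if c else 0.0 for c in self.coefficients]


def network_from_fit(fit: SemFit, gene_blocks: dict | None = None) -> nx.DiGraph:
    """Directed coefficient graph of a fitted system.

    Phenotype edges carry the Gamma coefficients.  With ``gene_blocks``
    given, exogenous edges are collapsed to one gene -> phenotype edge
    whose weight is the block's leading (largest-magnitude) coefficient;
    otherwise one edge per SNP column.
    """
    G = nx.DiGraph()
    G.add_nodes_from(fit.phenotype_names)
    for s, t, c in fit.gamma_edges():
        G.add_edge(s, t, weight=c)
    if gene_blocks:
        for gene, block in gene_blocks.items():
            for i, pheno in enumerate(fit.phenotype_names):
                coefs = fit.B[block, i]
                if np.any(coefs != 0):
                    lead = coefs[int(np.argmax(np.abs(coefs)))]
                    G.add_edge(gene, pheno, weight=float(lead))
    else:
        for s, t, c in fit.b_edges():
            G.add_edge(s, t, weight=c)
    return G


def network_from_edges(edges) -> nx.DiGraph:
    """Build a coefficient graph from (source, target, coefficient) triples."""
    G = nx.DiGraph()
    for s, t, c in edges:
        G.add_edge(s, t, weight=float(c))
    return G


def _connecting_subgraph(G: nx.DiGraph, source, target) -> nx.DiGraph:
    nodes = (nx.descendants(G, source) & nx.ancestors(G, target)) | {source, target}
    return G.subgraph(nodes)


def enumerate_paths(G: nx.DiGraph, source, target, max_len: int | None = None) -> PathSet:
    """All simple directed paths from source to target, up to ``max_len`` edges."""
    if source == target:
        raise SparseSemError("source and target must differ")
    if source not in G or target not in G:
        return PathSet(paths=[], coefficients=[])
    cutoff = max_len if max_len is not None else G.number_of_nodes() - 1
    paths = sorted(nx.all_simple_paths(G, source, target, cutoff=cutoff))
    coefs = [[G[u][v]["weight"] for u, v in zip(p[:-1], p[1:])] for p in paths]
    return PathSet(paths=[list(p) for p in paths], coefficients=coefs)


def _check_acyclic_route(G, source, target):
    sub = _connecting_subgraph(G, source, target)
    if not nx.is_directed_acyclic_graph(sub):
        cyc = next(nx.simple_cycles(sub))
        raise CyclicNetworkError(
            f"total effect of {source} on {target} is undefined: the "
            f"connecting subgraph contains the cycle {cyc}")


def total_effect_paths(G: nx.DiGraph, source, target) -> float:
    """Sum over directed paths of per-path coefficient products."""
    _check_acyclic_route(G, source, target)
    return float(sum(enumerate_paths(G, source, target).products))


def decompose(G: nx.DiGraph, source, target, data=None) -> EffectRecord:
    """Direct, indirect and total effect of ``source`` on ``target``.

    total = direct + indirect always holds on acyclic path sets.  When a
    sample table ``data`` (pandas DataFrame with columns named after the
    nodes) is supplied, the marginal (simple-regression) effect is filled
    in as well.
    """
    _check_acyclic_route(G, source, target)
    direct = float(G[source][target]["weight"]) if G.has_edge(source, target) else 0.0
    total = total_effect_paths(G, source, target)
    marginal = None
    if data is not None and source in data and target in data:
        marginal = marginal_effect(data, source, target)
    return EffectRecord(outcome=target, causal=source, direct=direct,
                        indirect=total - direct, total=total, marginal=marginal)


def total_effect_matrix(Gamma: np.ndarray) -> np.ndarray:
    """Closed-form phenotype total effects: T = (I - C)^{-1} - I, C = Gamma + I.

    ``C[j, i]`` is the edge coefficient j -> i; requires an acyclic
    coefficient matrix (spectral radius of C below 1 suffices for the
    Neumann series to converge to the path-product sums).
    """
    m = Gamma.shape[0]
    C = Gamma + np.eye(m)
    return np.linalg.inv(np.eye(m) - C) - np.eye(m)


def marginal_effect(data, source, outcome) -> float:
    """Simple-regression slope of ``outcome`` on ``source``."""
    x = np.asarray(data[source], dtype=float)
    y = np.asarray(data[outcome], dtype=float)
    x = x - x.mean()
    denom = float(x @ x)
    if denom == 0:
        raise SparseSemError(f"zero-variance source {source}")
    return float(x @ (y - y.mean())) / denom


def total_effect_intervention(data, source, outcome, parents=()) -> float:
    """Total effect via the adjustment regression of the do-calculus.

    Coefficient of ``source`` in the least-squares regression of
    ``outcome`` on ``source`` and the parents of ``source``; with no
    parents (SNP or gene nodes) this is the marginal slope.
    """
    parents = list(parents)
    if not parents:
        return marginal_effect(data, source, outcome)
    cols = [source] + parents
    Xm = np.column_stack([np.asarray(data[c], float) for c in cols])
    Xm = np.column_stack([np.ones(Xm.shape[0]), Xm])
    if np.linalg.matrix_rank(Xm) < Xm.shape[1]:
        raise SparseSemError(f"collinear adjustment set for source {source}: {parents}")
    y = np.asarray(data[outcome], dtype=float)
    beta, *_ = np.linalg.lstsq(Xm, y, rcond=None)
    return float(beta[1])


def partial_slope_from_correlations(beta_yx: float, rho_yx: float, rho_yz: float,
                                    rho_xz: float) -> float:
    """Adjusted slope beta_{YX.Z} from the marginal slope and correlations."""
    if abs(rho_xz) >= 1:
        raise SparseSemError("X and Z are perfectly correlated")
    return beta_yx * (1.0 - rho_yz * rho_xz / rho_yx) / (1.0 - rho_xz**2)


def effect_table(G: nx.DiGraph, pairs=None, data=None, ndigits: int = 4):
    """Table of direct/indirect/total/marginal effects per (causal, outcome).

    Without ``pairs``, every ordered pair with at least one connecting path
    is reported.  Pairs on cyclic routes are skipped and listed in the
    returned ``flagged`` list rather than guessed at.
    """
    import pandas as pd

    if pairs is None:
        pairs = [(s, t) for s in G.nodes for t in G.nodes
                 if s != t and nx.has_path(G, s, t)]
    rows, flagged = [], []
    for s, t in pairs:
        try:
            rec = decompose(G, s, t, data=data)
        except CyclicNetworkError:
            flagged.append((s, t))
            continue
        rows.append({"outcome": rec.outcome, "causal": rec.causal,
                     "direct": round(rec.direct, ndigits),
                     "indirect": round(rec.indirect, ndigits),
                     "total": round(rec.total, ndigits),
                     "marginal": (round(rec.marginal, ndigits)
                                  if rec.marginal is not None else np.nan)})
    return pd.DataFrame(rows, columns=["outcome", "causal", "direct",
                                       "indirect", "total", "marginal"]), flagged
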