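"""Core domain types for genotype-phenotype network models.

The linear structural equation system relating an n x M phenotype matrix Y
(endogenous) and an n x K genotype matrix X (exogenous) is

    Y @ Gamma + X @ B + E = 0,

with the normalisation gamma_ii = -1, so that each column i reads

    y_i = Y_{-i} @ gamma_{-i} + X @ B_i + e_i.

``Gamma[j, i]`` is the path coefficient of the directed phenotype edge
j -> i and ``B[k, i]`` the coefficient of the edge from exogenous column k
(a coded SNP or a functional principal-component score) to phenotype i.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


class SparseSemError(Exception):
    """Base class for errors raised by this package."""


@dataclass
class SnpRecord:
    """Metadata for a single biallelic SNP.

    Q is the reference allele, q the alternate allele; ``freq_Q`` and
    ``freq_q`` are their population (or sample-estimated) frequencies and
    must sum to one.  ``position`` is a 1-based genomic coordinate.
    """

    id: str
    position: int
    freq_Q: float
    freq_q: float
    gene: str | None = None

    def __post_init__(self) -> None:
        if abs(self.freq_Q + self.freq_q - 1.0) > 1e-9:
            raise ValueError(
                f"SNP {self.id}: allele frequencies must sum to 1 "
                f"(got {self.freq_Q} + {self.freq_q})"
            )
        if self.position < 0:
            raise ValueError(f"SNP {self.id}: negative position {self.position}")


@dataclass
class GeneRegion:
    """A gene (or genomic region) [start, end] owning a set of SNP columns."""

    gene_id: str
    start: int
    end: int
    snp_indices: list[int] = field(default_factory=list)

    def __post_init__(self) -> None:
        if not self.snp_indices:
            raise ValueError(f"gene {self.gene_id}: empty SNP index set")


@dataclass
class PhenotypeMatrix:
    """n x M matrix of endogenous phenotype observations."""

    values: np.ndarray
    sample_ids: list[str]
    phenotype_names: list[str]
    rank_normalised: bool = False

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2:
            raise ValueError("phenotype values must be a 2-D matrix")
        n, m = self.values.shape
        if len(self.sample_ids) != n or len(self.phenotype_names) != m:
            raise ValueError("sample/phenotype labels do not match matrix shape")
        if np.isnan(self.values).any():
            raise ValueError("phenotype matrix contains missing values")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def M(self) -> int:
        return self.values.shape[1]


@dataclass
class FpcColumn:
    """Descriptor of one functional principal-component score column."""

    gene_id: str
    component: int  # 1-based index of the eigenfunction

    @property
    def id(self) -> str:
        return f"{self.gene_id}:pc{self.component}"


@dataclass
class GenotypeData:
    """n x K exogenous matrix: coded genotypes or per-gene FPC scores.

    ``columns`` carries one descriptor per column (:class:`SnpRecord` for
    coded genotypes, :class:`FpcColumn` for scores); ``gene_blocks`` maps a
    gene id to the slice of columns belonging to that gene (set for FSEM
    score designs).
    """

    values: np.ndarray
    columns: list
    sample_ids: list[str]
    gene_blocks: dict[str, slice] | None = None

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=float)
        if self.values.ndim != 2 or self.values.shape[1] < 1:
            raise ValueError("genotype matrix must be 2-D with K >= 1 columns")
        if len(self.columns) != self.values.shape[1]:
            raise ValueError("column descriptors do not match matrix width")
        if len(self.sample_ids) != self.values.shape[0]:
            raise ValueError("sample ids do not match matrix height")

    @property
    def n(self) -> int:
        return self.values.shape[0]

    @property
    def K(self) -> int:
        return self.values.shape[1]

    @property
    def column_ids(self) -> list[str]:
        return [c.id for c in self.columns]


@dataclass
class SemFit:
    """Estimated structural system: Gamma (M x M, diagonal -1) and B (K x M).

    ``support_gamma`` / ``support_b`` mark the nonzero (selected) entries;
    entries outside the support are exactly zero.  ``sigma2`` holds the
    per-equation residual variances and ``lam`` the penalty used for each
    equation.
    """

    Gamma: np.ndarray
    B: np.ndarray
    sigma2: np.ndarray
    lam: np.ndarray
    support_gamma: np.ndarray
    support_b: np.ndarray
    phenotype_names: list[str]
    column_ids: list[str]
    converged: np.ndarray | None = None

    def __post_init__(self) -> None:
        m = self.Gamma.shape[0]
        if self.Gamma.shape != (m, m):
            raise ValueError("Gamma must be square")
        if not np.allclose(np.diag(self.Gamma), -1.0):
            raise ValueError("diagonal of Gamma must be -1")
        if self.B.shape[1] != m:
            raise ValueError("B must have one column per phenotype")

    @property
    def M(self) -> int:
        return self.Gamma.shape[0]

    @property
    def K(self) -> int:
        return self.B.shape[0]

    def gamma_edges(self) -> list[tuple[str, str, float]]:
        """Directed phenotype edges (source, target, coefficient)."""
        out = []
        for j in range(self.M):
            for i in range(self.M):
                if j != i and self.support_gamma[j, i]:
                    out.append(
                        (self.phenotype_names[j], self.phenotype_names[i], float(self.Gamma[j, i]))
                    )
        return out

    def b_edges(self) -> list[tuple[str, str, float]]:
        """Directed exogenous->phenotype edges (source, target, coefficient)."""
        out = []
        for k in range(self.K):
            for i in range(self.M):
                if self.support_b[k, i]:
                    out.append((self.column_ids[k], self.phenotype_names[i], float(self.B[k, i])))
        return out


# genotype call symbols accepted by encode_genotypes; integers count copies
# of the alternate allele q
_CALL_TO_Q_COUNT = {"QQ": 0, "Qq": 1, "qQ": 1, "qq": 2}


def encode_genotypes(calls, freqs, snp_ids=None, sample_ids=None, positions=None,
                     genes=None) -> GenotypeData:
    """Code genotype calls into the frequency-weighted profile values.

    For a SNP with allele frequencies (P_Q, P_q) the three genotypes are
    coded QQ -> 2*P_q, Qq -> P_q - P_Q, qq -> -2*P_Q.  Under Hardy-Weinberg
    equilibrium at those frequencies the coded value has expectation zero.

    Parameters
    ----------
    calls
        n x K array of genotype calls, either strings in {"QQ","Qq","qq"}
        or integer counts of the q allele in {0, 1, 2}.  Missing calls
        (None, "", "./.", NaN or -1) are imputed to the coded mean, which
        is 0 under HWE.
    freqs
        length-K sequence of (freq_Q, freq_q) pairs, each strictly in (0,1).
    """
    calls = np.asarray(calls)
    if calls.ndim != 2:
        raise ValueError("calls must be an n x K array")
    n, K = calls.shape
    if len(freqs) != K:
        raise ValueError("one (freq_Q, freq_q) pair required per SNP")
    snp_ids = snp_ids if snp_ids is not None else [f"snp{k+1}" for k in range(K)]
    sample_ids = sample_ids if sample_ids is not None else [f"s{i+1}" for i in range(n)]
    positions = positions if positions is not None else list(range(1, K + 1))
    genes = genes if genes is not None else [None] * K

    coded = np.zeros((n, K))
    records = []
    for k in range(K):
        p_Q, p_q = freqs[k]
        if not (0.0 < p_Q < 1.0 and 0.0 < p_q < 1.0):
            raise ValueError(f"SNP {snp_ids[k]}: frequencies must lie strictly in (0,1)")
        codes = {0: 2.0 * p_q, 1: p_q - p_Q, 2: -2.0 * p_Q}
        for i in range(n):
            c = calls[i, k]
            qc = _q_count(c, sample_ids[i], snp_ids[k])
            coded[i, k] = 0.0 if qc is None else codes[qc]
        records.append(SnpRecord(id=snp_ids[k], position=int(positions[k]),
                                 freq_Q=float(p_Q), freq_q=float(p_q), gene=genes[k]))
    return GenotypeData(values=coded, columns=records, sample_ids=list(sample_ids))


def _q_count(call, sample_id, snp_id):
    """Map one genotype call to its q-allele count; None means missing."""
    if call is None:
        return None
    if isinstance(call, (bytes, np.bytes_)):
        call = call.decode()
    if isinstance(call, str):
        if call in ("", ".", "./.", ".|.", "NA"):
            return None
        if call in _CALL_TO_Q_COUNT:
            return _CALL_TO_Q_COUNT[call]
        raise ValueError(f"unknown genotype call {call!r} for sample {sample_id}, SNP {snp_id}")
    val = float(call)
    if np.isnan(val) or val == -1:
        return None
    if val in (0.0, 1.0, 2.0):
        return int(val)
    raise ValueError(f"unknown genotype call {call!r} for sample {sample_id}, SNP {snp_id}")
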