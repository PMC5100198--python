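"""Readers and writers for the on-disk formats.

Formats: VCF (biallelic SNVs, via cyvcf2), a simple sample x SNP dosage TSV,
a sample x phenotype TSV, BED / TSV gene maps, and the TSV edge list used to
serialise inferred networks.
"""

from __future__ import annotations

import warnings

import numpy as np
import pandas as pd
from scipy import stats

from .datamodel import GeneRegion, PhenotypeMatrix, SemFit, SnpRecord, SparseSemError


def read_phenotypes(path, rank_normalise: bool = False) -> PhenotypeMatrix:
    """Read a phenotype TSV (header row; first column holds sample ids)."""
    df = pd.read_csv(path, sep="\t", index_col=0)
    if df.isna().any().any():
        bad = df.columns[df.isna().any()].tolist()
        raise SparseSemError(f"missing phenotype values in columns {bad}")
    values = df.to_numpy(dtype=float)
    if rank_normalise:
        values = np.column_stack([inverse_rank_normal(values[:, j])
                                  for j in range(values.shape[1])])
    return PhenotypeMatrix(values=values,
                           sample_ids=[str(s) for s in df.index],
                           phenotype_names=[str(c) for c in df.columns],
                           rank_normalised=rank_normalise)


def write_phenotypes(pheno: PhenotypeMatrix, path) -> None:
    pd.DataFrame(pheno.values, index=pheno.sample_ids,
                 columns=pheno.phenotype_names).to_csv(path, sep="\t",
                                                       index_label="sample_id")


def inverse_rank_normal(column, offset: float = 0.375):
    """Rank-based inverse normal transform with the Blom offset c = 3/8.

    Maps value of rank r (average ranks on ties) to
    Phi^{-1}((r - c) / (n - 2c + 1)).  Invariant under any strictly
    monotone transform of the input.
    """
    x = np.asarray(column, dtype=float)
    if x.size < 2:
        raise SparseSemError("inverse rank normal transform needs n >= 2")
    if np.ptp(x) == 0:
        raise SparseSemError("constant column: ranks undefined for the transform")
    ranks = stats.rankdata(x, method="average")
    return stats.norm.ppf((ranks - offset) / (x.size - 2 * offset + 1))


def read_genotype_calls(path, fmt: str = "vcf"):
    """Read genotype calls plus allele frequencies and SNP metadata.

    Returns ``(calls, freqs, records, sample_ids)`` where ``calls`` is an
    n x K integer matrix of alternate-allele counts (-1 = missing), and
    ``freqs`` a list of (freq_Q, freq_q) with Q the reference allele.
    Frequencies absent from the file are estimated from the sample.
    Multiallelic sites are skipped with a warning; monomorphic sites are
    excluded (their coded column would carry no information).
    """
    if fmt == "vcf":
        return _read_vcf(path)
    if fmt in ("dosage", "dosage-tsv"):
        return _read_dosage_tsv(path)
    raise SparseSemError(f"unknown genotype format {fmt!r}")


def _read_vcf(path):
    from cyvcf2 import VCF

    vcf = VCF(str(path))
    sample_ids = list(vcf.samples)
    calls_cols, freqs, records = [], [], []
    for var in vcf:
        if len(var.ALT) != 1:
            warnings.warn(f"skipping multiallelic site {var.CHROM}:{var.POS}")
            continue
        gts = np.asarray(var.gt_types)  # 0=hom ref, 1=het, 2=unknown, 3=hom alt
        col = np.where(gts == 0, 0, np.where(gts == 1, 1, np.where(gts == 3, 2, -1)))
        known = col[col >= 0]
        if known.size == 0 or np.ptp(known) == 0:
            warnings.warn(f"excluding monomorphic site {var.CHROM}:{var.POS}")
            continue
        p_q = known.sum() / (2.0 * known.size)
        snp_id = var.ID if var.ID not in (None, ".") else f"{var.CHROM}:{var.POS}"
        records.append(SnpRecord(id=snp_id, position=int(var.POS),
                                 freq_Q=1.0 - p_q, freq_q=p_q))
        calls_cols.append(col)
    if not calls_cols:
        raise SparseSemError(f"no usable biallelic polymorphic sites in {path}")
    calls = np.column_stack(calls_cols)
    freqs = [(r.freq_Q, r.freq_q) for r in records]
    return calls, freqs, records, sample_ids


def _read_dosage_tsv(path):
    df = pd.read_csv(path, sep="\t", index_col=0)
    sample_ids = [str(s) for s in df.index]
    calls_cols, records = [], []
    for k, snp_id in enumerate(df.columns):
        col = df.iloc[:, k].to_numpy(dtype=float)
        bad = ~(np.isnan(col) | np.isin(col, (0.0, 1.0, 2.0, -1.0)))
        if bad.any():
            raise SparseSemError(
                f"malformed dosage record at line {int(np.where(bad)[0][0]) + 2}, "
                f"SNP {snp_id}: value {col[bad][0]!r}")
        icol = np.where(np.isnan(col), -1, col).astype(int)
        known = icol[icol >= 0]
        if known.size == 0 or np.ptp(known) == 0:
            warnings.warn(f"excluding monomorphic SNP {snp_id}")
            continue
        p_q = known.sum() / (2.0 * known.size)
        records.append(SnpRecord(id=str(snp_id), position=k + 1,
                                 freq_Q=1.0 - p_q, freq_q=p_q))
        calls_cols.append(icol)
    if not calls_cols:
        raise SparseSemError(f"no polymorphic SNPs in {path}")
    calls = np.column_stack(calls_cols)
    freqs = [(r.freq_Q, r.freq_q) for r in records]
    return calls, freqs, records, sample_ids


def write_dosage_tsv(calls, snp_ids, sample_ids, path) -> None:
    pd.DataFrame(np.asarray(calls, dtype=int), index=sample_ids,
                 columns=snp_ids).to_csv(path, sep="\t", index_label="sample_id")


def check_sample_alignment(geno_ids, pheno_ids) -> None:
    """Raise listing offending ids when genotype/phenotype samples differ."""
    g, p = list(geno_ids), list(pheno_ids)
    if g != p:
        only_g = sorted(set(g) - set(p))
        only_p = sorted(set(p) - set(g))
        raise SparseSemError(
            "sample ids do not align between genotype and phenotype inputs; "
            f"genotype-only: {only_g[:10]}, phenotype-only: {only_p[:10]}"
            + ("" if only_g or only_p else " (same ids, different order)"))


def read_gene_map(path, records: list[SnpRecord]) -> list[GeneRegion]:
    """Read a snp_id -> gene_id TSV and group SNP columns into genes."""
    df = pd.read_csv(path, sep="\t", header=None, names=["snp_id", "gene_id"],
                     comment="#", dtype=str)
    by_snp = dict(zip(df["snp_id"], df["gene_id"]))
    groups: dict[str, list[int]] = {}
    for k, rec in enumerate(records):
        gene = by_snp.get(rec.id)
        if gene is not None:
            groups.setdefault(gene, []).append(k)
            rec.gene = gene
    return [_region(gene, idx, records) for gene, idx in groups.items()]


def read_bed_regions(path, records: list[SnpRecord]) -> list[GeneRegion]:
    """Assign SNPs to genes from a BED file (0-based half-open -> 1-based)."""
    bed = pd.read_csv(path, sep="\t", header=None, comment="#",
                      usecols=[0, 1, 2, 3], names=["chrom", "start", "end", "name"])
    regions = []
    for _, row in bed.iterrows():
        start, end = int(row["start"]) + 1, int(row["end"])  # 1-based inclusive
        idx = [k for k, r in enumerate(records) if start <= r.position <= end]
        if idx:
            for k in idx:
                records[k].gene = str(row["name"])
            regions.append(GeneRegion(gene_id=str(row["name"]), start=start,
                                      end=end, snp_indices=idx))
    return regions


def _region(gene_id, idx, records):
    pos = [records[k].position for k in idx]
    return GeneRegion(gene_id=gene_id, start=min(pos), end=max(pos), snp_indices=idx)


NETWORK_COLUMNS = ["source", "target", "edge_type", "coefficient", "p_value", "stability"]


def write_network(fit: SemFit, path, tests=None, gene_level: bool = False) -> None:
    """Serialise the fitted network support as a TSV edge list.

    ``tests`` may be a mapping (source, target) -> (p_value, stability);
    missing entries are written as NA.  ``gene_level`` labels exogenous
    edges gene->phenotype instead of snp->phenotype.
    """
    tests = tests or {}
    rows = []
    for src, tgt, coef in fit.gamma_edges():
        p, s = tests.get((src, tgt), (np.nan, np.nan))
        rows.append((src, tgt, "phenotype->phenotype", coef, p, s))
    exo_type = "gene->phenotype" if gene_level else "snp->phenotype"
    for src, tgt, coef in fit.b_edges():
        p, s = tests.get((src, tgt), (np.nan, np.nan))
        rows.append((src, tgt, exo_type, coef, p, s))
    pd.DataFrame(rows, columns=NETWORK_COLUMNS).to_csv(path, sep="\t", index=False,
                                                       na_rep="NA")


def read_network(path) -> pd.DataFrame:
    return pd.read_csv(path, sep="\t", na_values="NA")
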