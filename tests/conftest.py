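"""Shared fixtures: small simulated objects reused across test modules."""

import numpy as np
import pandas as pd
import pytest

from eqtlsim.expression import simulate_expression
from eqtlsim.genotypes import (
    GenotypeMatrix,
    TruthAssignments,
    TruthEntry,
    filter_variants,
    sample_genotypes,
    simulate_gene_annotation,
    simulate_haplotype_panel,
)
from eqtlsim.mapping import AssociationTable, map_cis


@pytest.fixture(scope="session")
def small_panel():
    return simulate_haplotype_panel(
        n_haplotypes=60, n_snps=1200, region_length=3_000_000, seed=42
    )


@pytest.fixture(scope="session")
def small_G(small_panel):
    G = sample_genotypes(small_panel, 400, seed=7)
    return filter_variants(G)


@pytest.fixture(scope="session")
def small_genes():
    return simulate_gene_annotation(n_genes=30, region_length=3_000_000, seed=3)


@pytest.fixture(scope="session")
def small_truth(small_G, small_genes):
    from eqtlsim.genotypes import select_causal_esnps

    return select_causal_esnps(
        small_G, small_genes, maf_target=0.25, n_causal=10, seed=5
    )


@pytest.fixture(scope="session")
def small_E(small_truth, small_G):
    return simulate_expression(small_truth, small_G, seed=11)


@pytest.fixture(scope="session")
def small_assoc(small_E, small_G, small_genes):
    return map_cis(small_E, small_G, small_genes)


def make_table(gene_pvals: dict, positions=None, n_samples=100) -> AssociationTable:
    """Hand-built AssociationTable: gene -> [(snp_idx, p_nominal), ...]."""
    gene_ids = list(gene_pvals)
    nsnp = 1 + max(i for recs in gene_pvals.values() for i, _ in recs)
    if positions is None:
        positions = np.arange(1, nsnp + 1) * 1000
    snp_ids = np.array([f"s{i}" for i in range(nsnp)], dtype=object)
    idx, pv = [], []
    counts = []
    for g in gene_ids:
        recs = gene_pvals[g]
        counts.append(len(recs))
        for i, p in recs:
            idx.append(i)
            pv.append(p)
    indptr = np.concatenate([[0], np.cumsum(counts)]).astype(np.int64)
    pv = np.array(pv)
    n = len(pv)
    windows = np.array(
        [[min(i for i, _ in gene_pvals[g]), max(i for i, _ in gene_pvals[g]) + 1]
         for g in gene_ids]
    )
    return AssociationTable(
        gene_ids=gene_ids,
        indptr=indptr,
        snp_idx=np.array(idx, dtype=np.int32),
        beta=np.ones(n),
        se=np.ones(n),
        t_stat=np.ones(n),
        p_nominal=pv,
        distance_to_tss=np.zeros(n, dtype=np.int64),
        snp_ids=snp_ids,
        positions=np.asarray(positions, dtype=np.int64),
        gene_windows=windows,
        n_samples=n_samples,
    )


def constructed_genotypes(columns, positions=None) -> GenotypeMatrix:
    """GenotypeMatrix from a list of dosage columns (each length n)."""
    d = np.stack([np.asarray(c, dtype=np.int8) for c in columns], axis=1)
    nsnp = d.shape[1]
    if positions is None:
        positions = np.arange(1, nsnp + 1) * 1000
    return GenotypeMatrix(
        dosages=d,
        positions=np.asarray(positions, dtype=np.int64),
        snp_ids=np.array([f"s{i}" for i in range(nsnp)], dtype=object),
    )


def single_gene_truth(gene_id, snp_id, beta=1.0, coding="additive", nulls=()):
    return TruthAssignments(
        entries=[
            TruthEntry(gene_id=gene_id, snp_ids=(snp_id,), betas=(beta,), coding=coding)
        ],
        null_gene_ids=list(nulls),
    )


def gene_frame(tss_by_gene: dict) -> pd.DataFrame:
    return pd.DataFrame(
        {
            "gene_id": list(tss_by_gene),
            "chrom": "chr22",
            "tss": list(tss_by_gene.values()),
        }
    )
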