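"""Haplotype panel, genotype sampling, QC filters, LD and causal selection."""

import numpy as np
import pytest
from scipy import stats

from eqtlsim.errors import CapacityError, DegenerateInputError, InvalidArgumentError
from eqtlsim.genotypes import (
    GenotypeMatrix,
    HaplotypePanel,
    filter_variants,
    hwe_pvalues,
    ld_r2,
    sample_genotypes,
    select_causal_esnps,
    simulate_gene_annotation,
    simulate_haplotype_panel,
)

from conftest import constructed_genotypes, gene_frame


class TestPanelSimulation:
    def test_single_snp_panel_is_polymorphic(self):
        p = simulate_haplotype_panel(
            n_haplotypes=40, n_snps=1, region_length=100_000, seed=1
        )
        assert p.alleles.shape == (40, 1)
        assert 0 < p.frequencies[0] < 1

    def test_same_seed_reproduces_panel_bit_exactly(self):
        kw = dict(n_haplotypes=30, n_snps=300, region_length=1_000_000, seed=9)
        a, b = simulate_haplotype_panel(**kw), simulate_haplotype_panel(**kw)
        assert np.array_equal(a.alleles, b.alleles)
        assert np.array_equal(a.positions, b.positions)

    def test_invalid_dimensions_rejected(self):
        with pytest.raises(InvalidArgumentError):
            simulate_haplotype_panel(n_haplotypes=1, n_snps=10)
        with pytest.raises(InvalidArgumentError):
            simulate_haplotype_panel(n_haplotypes=10, n_snps=0)

    def test_positions_strictly_increasing_and_binary(self, small_panel):
        assert np.all(np.diff(small_panel.positions) > 0)
        assert set(np.unique(small_panel.alleles)) <= {0, 1}

    def test_mean_r2_decays_with_distance(self, small_panel):
        """Binned mean pairwise r² is monotone non-increasing in distance."""
        H = small_panel.alleles.astype(float)
        sd = H.std(axis=0)
        ok = sd > 0
        Z = (H[:, ok] - H[:, ok].mean(axis=0)) / sd[ok]
        pos = small_panel.positions[ok]
        rng = np.random.default_rng(0)
        ii = rng.integers(0, Z.shape[1], 60_000)
        jj = rng.integers(0, Z.shape[1], 60_000)
        keep = ii != jj
        ii, jj = ii[keep], jj[keep]
        r2 = (np.einsum("ni,ni->i", Z[:, ii], Z[:, jj]) / Z.shape[0]) ** 2
        d = np.abs(pos[ii] - pos[jj])
        edges = [0, 5_000, 20_000, 100_000, 500_000, 3_000_000]
        means = [
            r2[(d >= lo) & (d < hi)].mean() for lo, hi in zip(edges, edges[1:])
        ]
        assert all(a >= b - 0.01 for a, b in zip(means, means[1:]))
        assert means[0] > 3 * means[-1]  # genuine decay, not flat

    def test_maf_spectrum_weights_reshape_sites(self):
        kw = dict(n_haplotypes=50, n_snps=150, region_length=4_000_000, seed=2)
        neutral = simulate_haplotype_panel(**kw)
        common = simulate_haplotype_panel(**kw, maf_spectrum=lambda p: p**2)
        maf_n = np.minimum(neutral.frequencies, 1 - neutral.frequencies)
        maf_c = np.minimum(common.frequencies, 1 - common.frequencies)
        assert maf_c.mean() > maf_n.mean() + 0.03


class TestGenotypeSampling:
    def test_all_zero_panel_gives_zero_dosages(self):
        panel = HaplotypePanel(
            alleles=np.zeros((4, 5), dtype=np.uint8),
            positions=np.arange(1, 6) * 100,
            snp_ids=[f"s{i}" for i in range(5)],
        )
        G = sample_genotypes(panel, 10, seed=0, error_rate=0.0)
        assert np.all(G.dosages == 0)

    def test_dosages_in_range_and_maf_consistent(self, small_G):
        assert set(np.unique(small_G.dosages)) <= {0, 1, 2}
        freq = small_G.dosages.mean(axis=0) / 2
        assert np.allclose(small_G.maf, np.minimum(freq, 1 - freq))

    def test_sample_frequency_matches_binomial_oracle(self, small_panel):
        """Large-sample allele frequency stays inside the binomial 99.9% CI
        around the panel frequency."""
        G = sample_genotypes(small_panel, 5000, seed=3, error_rate=0.0)
        pf = small_panel.frequencies
        j = int(np.argmin(np.abs(pf - 0.3)))  # minor-coded stays unflipped
        p = pf[j]
        n_chrom = 2 * G.n_samples
        obs = int(G.dosages[:, j].sum())
        lo, hi = stats.binom.ppf([0.0005, 0.9995], n_chrom, p)
        assert lo <= obs <= hi

    def test_empty_panel_rejected(self):
        panel = HaplotypePanel(
            alleles=np.zeros((4, 0), dtype=np.uint8),
            positions=np.array([], dtype=np.int64),
            snp_ids=[],
        )
        with pytest.raises(InvalidArgumentError):
            sample_genotypes(panel, 5, seed=0)

    def test_deterministic_given_seed(self, small_panel):
        a = sample_genotypes(small_panel, 50, seed=4)
        b = sample_genotypes(small_panel, 50, seed=4)
        assert np.array_equal(a.dosages, b.dosages)


class TestVariantFilters:
    def test_defaults_match_standard_qc(self):
        import inspect

        sig = inspect.signature(filter_variants)
        assert sig.parameters["maf_min"].default == 0.005
        assert sig.parameters["hwe_p_min"].default == 5e-6

    def test_monomorphic_snp_removed(self):
        G = constructed_genotypes([[0] * 10, [0, 1] * 5])
        out = filter_variants(G)
        assert list(out.snp_ids) == ["s1"]

    def test_hwe_outlier_removed_matches_chi_square_oracle(self):
        # SNP 1: extreme heterozygote excess (all hets); SNPs 0, 2 near HWE
        n = 100
        rng = np.random.default_rng(0)
        cols = [
            rng.binomial(2, 0.4, n),
            np.ones(n, dtype=int),
            rng.binomial(2, 0.25, n),
        ]
        G = constructed_genotypes(cols)
        out = filter_variants(G)
        # brute-force 1-df chi-square per SNP
        survivors = []
        for j, c in enumerate(cols):
            c = np.asarray(c)
            p = c.mean() / 2
            exp = n * np.array([(1 - p) ** 2, 2 * p * (1 - p), p**2])
            obs = np.array([(c == 0).sum(), (c == 1).sum(), (c == 2).sum()])
            chi2 = ((obs - exp) ** 2 / exp).sum()
            if stats.chi2.sf(chi2, 1) >= 5e-6 and min(p, 1 - p) >= 0.005:
                survivors.append(f"s{j}")
        assert list(out.snp_ids) == survivors == ["s0", "s2"]

    def test_filter_is_idempotent(self, small_G):
        again = filter_variants(small_G)
        assert np.array_equal(again.dosages, small_G.dosages)

    def test_monomorphic_hwe_pvalue_defined(self):
        G = constructed_genotypes([[0] * 8])
        assert hwe_pvalues(G)[0] == 1.0


class TestLD:
    def test_self_and_duplicate_r2_is_one(self):
        col = [0, 1, 2, 1, 0, 2]
        G = constructed_genotypes([col, col])
        assert ld_r2(G, "s0", "s0") == pytest.approx(1.0)
        assert ld_r2(G, "s0", "s1") == pytest.approx(1.0)

    def test_matches_direct_correlation_formula(self):
        a = np.array([0, 1, 2, 0, 1, 2], dtype=float)
        b = np.array([0, 1, 1, 0, 2, 2], dtype=float)
        G = constructed_genotypes([a, b])
        cov = np.mean(a * b) - a.mean() * b.mean()
        expected = cov**2 / (a.var() * b.var())
        assert ld_r2(G, "s0", "s1") == pytest.approx(expected, rel=1e-12)

    def test_symmetric_and_flip_invariant(self):
        rng = np.random.default_rng(5)
        a = rng.integers(0, 3, 30)
        b = rng.integers(0, 3, 30)
        G = constructed_genotypes([a, b, 2 - a])
        assert ld_r2(G, "s0", "s1") == pytest.approx(ld_r2(G, "s1", "s0"))
        assert ld_r2(G, "s2", "s1") == pytest.approx(ld_r2(G, "s0", "s1"))

    def test_zero_variance_errors(self):
        G = constructed_genotypes([[1] * 6, [0, 1, 2, 0, 1, 2]])
        with pytest.raises(DegenerateInputError):
            ld_r2(G, "s0", "s1")


class TestCausalSelection:
    def test_null_genes_complement_true_egenes(self, small_G, small_genes):
        truth = select_causal_esnps(
            small_G, small_genes, maf_target=0.25, n_causal=10, seed=1
        )
        assert len(truth.entries) == 10
        assert len(truth.null_gene_ids) == len(small_genes) - 10
        assert set(truth.true_gene_ids).isdisjoint(truth.null_gene_ids)

    def test_selected_pairwise_r2_pruned_and_maf_in_band(self, small_G, small_genes):
        truth = select_causal_esnps(
            small_G, small_genes, maf_target=0.25, n_causal=8, prune_r2=0.3, seed=2
        )
        snps = [e.snp_ids[0] for e in truth.entries]
        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                assert ld_r2(small_G, a, b) <= 0.3 + 1e-12
        # brute-force MAF band check
        for s in snps:
            maf = small_G.maf[small_G.snp_index(s)]
            assert 0.25 * 0.8 - 1e-12 <= maf <= 0.25 * 1.2 + 1e-12

    def test_causal_snps_are_cis_to_their_gene(self, small_G, small_genes):
        truth = select_causal_esnps(
            small_G, small_genes, maf_target=0.25, n_causal=8, seed=3
        )
        tss = dict(zip(small_genes.gene_id, small_genes.tss))
        for e in truth.entries:
            pos = small_G.positions[small_G.snp_index(e.snp_ids[0])]
            assert abs(pos - tss[e.gene_id]) <= 1_000_000

    def test_insufficient_candidates_raise_capacity_error(self, small_G, small_genes):
        with pytest.raises(CapacityError):
            select_causal_esnps(
                small_G, small_genes, maf_target=0.25, n_causal=1000, seed=0
            )
        with pytest.raises(CapacityError):
            # absurdly narrow MAF band
            select_causal_esnps(
                small_G, small_genes, maf_target=0.4999, n_causal=5,
                maf_tol=1e-6, seed=0,
            )

    def test_prune_zero_on_independent_snps(self):
        rng = np.random.default_rng(8)
        cols = [rng.binomial(2, 0.3, 3000) for _ in range(12)]
        G = constructed_genotypes(cols, positions=np.arange(1, 13) * 100_000)
        genes = gene_frame({f"g{i}": (i + 1) * 100_000 for i in range(12)})
        truth = select_causal_esnps(
            G, genes, maf_target=0.3, n_causal=6, prune_r2=0.05, seed=4
        )
        snps = [e.snp_ids[0] for e in truth.entries]
        for i, a in enumerate(snps):
            for b in snps[i + 1 :]:
                assert ld_r2(G, a, b) < 0.05

    def test_effect_draw_attached(self, small_G, small_genes):
        truth = select_causal_esnps(
            small_G, small_genes, maf_target=0.25, n_causal=5, seed=6,
            effect_draw=lambda rng, k: np.full(k, 1.5),
        )
        assert all(e.betas == (1.5,) for e in truth.entries)


def test_gene_annotation_shape_and_bounds():
    genes = simulate_gene_annotation(n_genes=50, region_length=10_000_000, seed=1)
    assert len(genes) == 50
    assert genes.gene_id.is_unique
    assert genes.tss.between(1, 10_000_000).all()
    assert genes.tss.is_monotonic_increasing
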