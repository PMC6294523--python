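"""Multiple-testing procedures: elementary adjustments, eigenMT,
permutation schemes, and the pooled/hierarchical drivers."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from scipy import stats

from eqtlsim.correction import (
    HierarchicalResult,
    adjust_bh,
    adjust_bonferroni,
    adjust_by,
    adjust_st,
    eigenmt_effective_tests,
    estimate_pi0,
    hierarchical_correct,
    permutation_local,
    pooled_correct,
)
from eqtlsim.errors import DegenerateInputError, InvalidArgumentError
from eqtlsim.expression import ExpressionMatrix, simulate_expression
from eqtlsim.genotypes import TruthAssignments

from conftest import constructed_genotypes, make_table


def brute_bh(p):
    """Independent step-up oracle for BH adjusted p-values."""
    p = np.asarray(p, float)
    m = len(p)
    order = np.argsort(p)
    adj = np.empty(m)
    running = 1.0
    for rank in range(m - 1, -1, -1):
        running = min(running, p[order[rank]] * m / (rank + 1))
        adj[order[rank]] = running
    return adj


def brute_by(p):
    c = np.sum(1.0 / np.arange(1, len(p) + 1))
    return np.minimum(1.0, brute_bh(p) * c)


class TestElementaryAdjustments:
    def test_bonferroni_formula_and_cap(self):
        assert adjust_bonferroni([0.01], 10)[0] == pytest.approx(0.1)
        assert adjust_bonferroni([0.5], 10)[0] == 1.0
        with pytest.raises(InvalidArgumentError):
            adjust_bonferroni([0.1], 0)

    @settings(max_examples=30, deadline=None)
    @given(st.integers(0, 2**31 - 1), st.integers(1, 40))
    def test_bh_by_match_brute_force_oracle(self, seed, m):
        p = np.random.default_rng(seed).uniform(1e-8, 1, m)
        assert np.allclose(adjust_bh(p), brute_bh(p))
        assert np.allclose(adjust_by(p), brute_by(p))

    def test_single_p_identities(self):
        assert adjust_bh([0.37])[0] == pytest.approx(0.37)
        assert adjust_by([0.37])[0] == pytest.approx(adjust_bh([0.37])[0])

    def test_adjusted_values_monotone_in_sorted_order(self):
        p = np.random.default_rng(0).uniform(size=200)
        for adj in (adjust_bh(p), adjust_by(p), adjust_st(p)):
            assert np.all(np.diff(adj[np.argsort(p)]) >= -1e-15)
            assert ((adj > 0) & (adj <= 1)).all()

    def test_empty_vectors(self):
        assert adjust_bh([]).size == 0
        assert adjust_by([]).size == 0


class TestStoreyTibshirani:
    def test_uniform_null_gives_pi0_near_one(self):
        p = np.random.default_rng(1).uniform(size=20000)
        pi0 = estimate_pi0(p)
        assert pi0 == pytest.approx(1.0, abs=0.05)
        assert np.allclose(adjust_st(p), pi0 * np.minimum(1, brute_bh(p)), atol=1e-9)

    def test_mixture_recovers_null_fraction(self):
        rng = np.random.default_rng(2)
        null = rng.uniform(size=14000)
        alt = stats.norm.sf(rng.normal(loc=3.0, size=6000))
        pi0 = estimate_pi0(np.concatenate([null, alt]))
        assert pi0 == pytest.approx(0.7, abs=0.08)

    def test_q_values_never_exceed_bh(self):
        p = np.random.default_rng(3).uniform(size=500) ** 2
        assert np.all(adjust_st(p) <= adjust_bh(p) + 1e-12)

    def test_all_tiny_p_floored_with_warning(self):
        pi0 = estimate_pi0(np.full(200, 1e-12))
        assert pi0 == pytest.approx(1e-3)


class TestEigenMT:
    def test_perfectly_correlated_snps_count_as_one(self):
        rng = np.random.default_rng(4)
        col = rng.integers(0, 3, 500)
        assert eigenmt_effective_tests(np.stack([col, col, col], axis=1)) == 1

    def test_independent_snps_count_near_m(self):
        rng = np.random.default_rng(5)
        X = rng.binomial(2, 0.4, size=(4000, 50))
        meff = eigenmt_effective_tests(X)
        assert 45 <= meff <= 50

    def test_meff_never_exceeds_m(self, small_G):
        for lo in (0, 100, 400):
            X = small_G.dosages[:, lo : lo + 120]
            assert 1 <= eigenmt_effective_tests(X) <= X.shape[1]

    def test_constant_matrix_rejected(self):
        with pytest.raises(DegenerateInputError):
            eigenmt_effective_tests(np.ones((50, 4)))


class TestPermutationLocal:
    def test_exact_p_floor_is_one_over_b_plus_one(self):
        rng = np.random.default_rng(6)
        g = rng.binomial(2, 0.4, 150)
        y = 2.0 * g + rng.normal(size=150)  # overwhelming signal
        res = permutation_local(y, g[:, None], scheme="exact", B=999, seed=0)
        assert res.p_value == pytest.approx(1 / 1000)

    def test_null_gene_permutation_p_roughly_uniform(self):
        rng = np.random.default_rng(7)
        X = rng.binomial(2, 0.3, size=(80, 10))
        ps = [
            permutation_local(
                np.random.default_rng(100 + i).normal(size=80),
                X,
                scheme="exact",
                B=200,
                seed=i,
            ).p_value
            for i in range(40)
        ]
        assert stats.kstest(ps, "uniform").pvalue > 1e-3

    def test_beta_scheme_tracks_exact_oracle(self, small_G):
        """Beta-approximated p ranks genes like a long exact permutation run."""
        rng = np.random.default_rng(8)
        cols = np.arange(200, 260)
        X = small_G.dosages[:, cols]
        p_exact, p_beta = [], []
        for i in range(30):
            beta_true = [0, 0.05, 0.1, 0.15, 0.2, 0.3][i % 6]
            y = beta_true * X[:, (7 * i) % X.shape[1]] + rng.normal(size=X.shape[0])
            p_exact.append(
                permutation_local(y, X, scheme="exact", B=4000, seed=i).p_value
            )
            p_beta.append(
                permutation_local(y, X, scheme="beta", B=1000, seed=1000 + i).p_value
            )
        rho = stats.spearmanr(p_exact, p_beta).statistic
        assert rho > 0.99

    def test_adaptive_scheme_stops_early_for_null_genes(self):
        rng = np.random.default_rng(9)
        X = rng.binomial(2, 0.3, size=(60, 8))
        y = rng.normal(size=60)
        res = permutation_local(y, X, scheme="adaptive", B=1000, b_max=10000, seed=2)
        assert res.n_permutations <= 1000  # null gene hits 15 exceedances fast
        assert res.beta_fit is not None

    def test_validation_errors(self):
        X = np.random.default_rng(0).binomial(2, 0.3, size=(50, 3))
        with pytest.raises(DegenerateInputError):
            permutation_local(np.ones(50), X, B=100)
        with pytest.raises(InvalidArgumentError):
            permutation_local(np.random.default_rng(1).normal(size=50), X, B=50)
        with pytest.raises(InvalidArgumentError):
            permutation_local(
                np.random.default_rng(1).normal(size=50), X, scheme="jackknife"
            )


class TestHierarchical:
    def test_single_gene_single_snp_reduces_to_nominal(self):
        table = make_table({"g": [(0, 0.013)]})
        res = hierarchical_correct(table, "bh", "bh")
        assert res.local_min_p[0] == pytest.approx(0.013)
        assert res.global_p[0] == pytest.approx(0.013)
        assert res.egenes == ["g"]

    def test_three_gene_hand_trace(self):
        """Full hand-traced Steps 1-3 with BH local and BH global."""
        table = make_table(
            {
                "A": [(0, 0.0001), (1, 0.002), (2, 0.5)],
                "B": [(3, 0.01), (4, 0.04)],
                "C": [(5, 0.2)],
            }
        )
        res = hierarchical_correct(table, "bh", "bh", alpha=0.05)
        # Step 1: BH within genes -> min adj p A:3e-4, B:0.02, C:0.2
        assert res.local_min_p == pytest.approx([3e-4, 0.02, 0.2])
        # Step 2: BH across genes -> [9e-4, 0.03, 0.2]
        assert res.global_p == pytest.approx([9e-4, 0.03, 0.2])
        assert res.egenes == ["A", "B"]
        # Step 3: threshold = max gene-min among significant = 0.02
        assert res.esnp_threshold == pytest.approx(0.02)
        assert list(res.esnps_for("A")) == ["s0", "s1"]
        assert list(res.esnps_for("B")) == ["s3"]
        assert res.esnps_for("C").size == 0

    def test_no_gene_passes_alpha(self):
        table = make_table({"a": [(0, 0.4)], "b": [(1, 0.9)]})
        res = hierarchical_correct(table, "bonferroni", "bh")
        assert res.egenes == [] and res.esnp_threshold is None

    def test_bonferroni_local_scale_recorded(self):
        table = make_table({"g": [(0, 0.001), (1, 0.02), (2, 0.9)]})
        res = hierarchical_correct(table, "bonferroni", "bh")
        assert res.scale_for("g") == 3
        assert res.local_min_p[0] == pytest.approx(0.003)

    def test_eigenmt_local_adj_never_exceeds_bonferroni(self, small_assoc, small_G):
        bonf = hierarchical_correct(small_assoc, "bonferroni", "bh", G=small_G)
        eig = hierarchical_correct(small_assoc, "eigenmt", "bh", G=small_G)
        ok = ~np.isnan(bonf.local_min_p)
        assert np.all(eig.local_min_p[ok] <= bonf.local_min_p[ok] + 1e-12)
        assert np.all(eig.local_scale[ok] <= bonf.local_scale[ok])

    def test_hierarchical_bonferroni_bh_subset_of_pooled_bh(
        self, small_assoc, small_truth, small_G
    ):
        hier = hierarchical_correct(small_assoc, "bonferroni", "bh")
        pooled = pooled_correct(small_assoc, "bh")
        assert set(hier.egenes) <= set(pooled.egenes)

    def test_unknown_methods_rejected(self, small_assoc):
        with pytest.raises(InvalidArgumentError):
            hierarchical_correct(small_assoc, "fdr", "bh")
        with pytest.raises(InvalidArgumentError):
            hierarchical_correct(small_assoc, "bh", "perm")
        with pytest.raises(InvalidArgumentError):
            hierarchical_correct(small_assoc, "eigenmt", "bh", G=None)

    def test_permutation_local_hierarchy_on_small_scan(self, small_G, small_genes):
        from eqtlsim.genotypes import select_causal_esnps
        from eqtlsim.mapping import map_cis

        truth = select_causal_esnps(
            small_G, small_genes, maf_target=0.25, n_causal=6, seed=13,
            effect_draw=lambda rng, k: np.full(k, 1.2),
        )
        E = simulate_expression(truth, small_G, seed=14)
        assoc = map_cis(E, small_G, small_genes)
        res = hierarchical_correct(
            assoc, "bperm", "bh", G=small_G, E=E, perm_B=300, seed=5
        )
        # strong signals: most true eGenes detected, and each significant
        # eGene has at least one significant eSNP (its own top SNP)
        assert len(set(res.egenes) & set(truth.true_gene_ids)) >= 4
        for g in res.egenes:
            assert res.esnps_for(g).size >= 1


class TestPooled:
    def test_single_record_reduces_to_single_test(self):
        table = make_table({"g": [(0, 0.04)]})
        res = pooled_correct(table, "bh", alpha=0.05)
        assert res.egenes == ["g"]

    def test_toy_instance_matches_brute_force(self):
        table = make_table(
            {
                "A": [(0, 0.0001), (1, 0.002), (2, 0.5)],
                "B": [(3, 0.01), (4, 0.04)],
                "C": [(5, 0.2)],
            }
        )
        res = pooled_correct(table, "bh", alpha=0.05)
        adj = brute_bh([0.0001, 0.002, 0.5, 0.01, 0.04, 0.2])
        assert set(res.egenes) == {"A", "B"}
        assert list(res.esnps_for("A")) == ["s0", "s1"]
        assert list(res.esnps_for("B")) == ["s3"]
        # spot-check adjusted values against the oracle
        assert res._esnps["A"][1] == pytest.approx(adj[[0, 1]])

    def test_bonferroni_pooled_most_conservative(self, small_assoc):
        bonf = pooled_correct(small_assoc, "bonferroni")
        bh = pooled_correct(small_assoc, "bh")
        assert set(bonf.egenes) <= set(bh.egenes)

    def test_unknown_method_rejected(self, small_assoc):
        with pytest.raises(InvalidArgumentError):
            pooled_correct(small_assoc, "eigenmt")
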