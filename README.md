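# eqtlsim

Simulation and evaluation of *cis*-eQTL study designs: statistical power,
eGene-level false discovery rate, and Winner's-Curse effect-size bias.

## What problem this addresses

Expression quantitative trait locus (eQTL) studies regress every gene's
expression on every SNP within ±1 Mb of its transcription start site,
producing hundreds of thousands of correlated tests. How the resulting
p-values are corrected — pooled across all SNP–gene pairs, or
hierarchically (first across the SNPs of each gene, then across genes) —
changes which genes are declared eGenes, and naive effect estimates at
ascertained loci are biased upward (the Winner's Curse). Because the true
causal variants in real data are unknown, these properties can only be
quantified by simulation with known ground truth. `eqtlsim` provides that
laboratory: it simulates LD-structured genotypes and matched expression,
maps cis-eQTLs, applies a family of multiple-testing corrections, runs
conditional analysis and bootstrap effect-size correction, and scores every
pipeline against the simulated truth. It is aimed at statistical
geneticists designing or reviewing eQTL analyses.

## Models

**Genotypes.** A phased reference panel (default 100 haplotypes over a
20 Mb chromosome with 16,000 SNPs) is simulated with a neutral coalescent
with recombination, giving a realistic allele-frequency spectrum (density
roughly ∝ 1/p, minor allele frequencies down to 0.5%) and pairwise r² that
decays smoothly with distance. Study individuals are produced by
Li–Stephens mosaic copying from the panel (Poisson template switching plus
a small copying-error rate), then filtered at MAF ≥ 0.5% and Hardy–Weinberg
p ≥ 5×10⁻⁶.

**Expression.** For each of 200 true eGenes (of 618 genes),

    y_i = Σ_k β_k · g_ik + ε_i,   ε_i ~ N(0, 1)

with g the minor-allele dosage of the causal eSNP(s), optionally coded
dominant (0,2,2) or recessive (0,0,2); β is constant or drawn from a gamma
distribution; noise may be log-normal, expression may be inverse
rank-normalized, co-expressed gene blocks can share a causal eSNP with
noise correlation r ~ U(0.6, 0.9), and genes may receive 2–3 causal eSNPs
whose mutual LD follows Beta(2.6, 4.5). Null genes are pure noise.

**Analysis methods implemented.** Matrix-style OLS cis mapping; pooled
Bonferroni/BH/BY/Storey–Tibshirani correction; the three-step hierarchical
correction with local ST/BH/BY/Bonferroni, eigenMT-style effective-test
Bonferroni, or exact/beta-approximated/adaptive permutation p-values;
forward/backward conditional analysis; and the bootstrap Winner's-Curse
estimators (shrinkage, out-of-sample, weighted with ω = 0.632). Scoring
uses the r² ≥ 0.8 truth-matching rule at the gene level.

## Worked example

```python
from eqtlsim import ScenarioConfig, EffectSizeDistribution, run_scenario

config = ScenarioConfig(
    n_samples=300, causal_maf=0.10,
    effect=EffectSizeDistribution(family="constant", constant_beta=1.0),
    n_snps=4000, region_length=5_000_000, n_genes=150, n_true_egenes=50,
    replicates=2, seed=42,
)
summary = run_scenario(config, ["pooled_bh", "bonferroni_bh", "eigenmt_bh"],
                       top_esnp=True)
print(summary[summary.metric.isin(["tpr", "fdr", "top_esnp_causal_rate"])]
      .pivot(index="method", columns="metric", values="value").round(3))
```

prints

```
metric           fdr  top_esnp_causal_rate   tpr
method
bonferroni_bh  0.020                 0.827  0.98
eigenmt_bh     0.057                 0.818  0.99
pooled_bh      0.231                 0.820  1.00
```

All three pipelines detect essentially every true eGene at this power
(TPR ≈ 1), but pooled BH lets the eGene-level FDR balloon to 23% while the
hierarchical procedures hold it near the nominal 5% — the central design
lesson the simulator quantifies. The top (lowest-p) eSNP of a detected
eGene is the simulated causal variant (or a perfect-LD proxy) about 82% of
the time here.

The same pipeline is scriptable from a shell:

```bash
eqtlsim simulate --config scenario.yaml --out run/
eqtlsim correct --genotypes run/genotypes.tsv --expression run/expression.tsv \
    --genes run/genes.tsv --local eigenmt --global bh --out-prefix run/hier
eqtlsim bootstrap --genotypes run/genotypes.tsv --expression run/expression.tsv \
    --genes run/genes.tsv --out run/effects.tsv
```

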