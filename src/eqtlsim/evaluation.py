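"""Scoring of eQTL pipelines against simulated truth, and scenario drivers.

Gene-level scoring follows the LD-aware truth-matching rule: a significant
eGene is a true positive when it was simulated as a true eGene *and* at
least one of its significant eSNPs is in high LD (r² >= 0.8) with one of
its causal eSNPs; every other significant eGene is a false discovery.
Sensitivity (TPR) is the fraction of simulated true eGenes recovered; FDR
pools true/false-positive counts across replicates before forming the
ratio.  Top-eSNP scoring asks, among true-positive eGenes, how often the
minimum-p SNP is the causal eSNP itself (or a perfect-LD proxy).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace as dc_replace

import numpy as np
import pandas as pd

from ._rng import child_seed
from .bootstrap import bootstrap_correct
from .correction import hierarchical_correct, pooled_correct
from .errors import ConsistencyError, InvalidArgumentError
from .expression import (
    EffectSizeDistribution,
    ExpressionMatrix,
    simulate_expression,
)
from .genotypes import (
    GenotypeMatrix,
    LDProfile,
    TruthAssignments,
    filter_variants,
    sample_genotypes,
    select_causal_esnps,
    simulate_gene_annotation,
    simulate_haplotype_panel,
    standardized_dosages,
)
from .mapping import AssociationTable, map_cis

logger = logging.getLogger(__name__)

__all__ = [
    "ScenarioConfig",
    "ReplicateData",
    "EGeneScore",
    "TopESnpScore",
    "score_egenes",
    "score_top_esnp",
    "score_estimators",
    "simulate_replicate",
    "apply_method",
    "run_scenario",
    "run_scenario_grid",
    "HIGH_LD_R2",
    "PERFECT_LD_R2",
]

HIGH_LD_R2 = 0.8
PERFECT_LD_R2 = 1.0 - 1e-9


@dataclass(frozen=True)
class ScenarioConfig:
    """One simulation scenario: genome, sample and effect parameters."""

    n_samples: int = 1000
    causal_maf: float = 0.25
    effect: EffectSizeDistribution = EffectSizeDistribution()
    coding: str = "additive"
    noise: str = "normal"
    inverse_normalize: bool = False
    n_causal_per_gene: int = 1
    correlated_blocks: bool = False
    n_genes: int = 618
    n_true_egenes: int = 200
    n_snps: int = 16000
    region_length: int = 20_000_000
    panel_haplotypes: int = 100
    ld_profile: LDProfile = LDProfile()
    cis_window: int = 1_000_000
    maf_min: float = 0.005
    hwe_p_min: float = 5e-6
    prune_r2: float = 0.3
    maf_tol: float = 0.2
    replicates: int = 10
    seed: int = 0

    def __post_init__(self):
        if self.n_true_egenes > self.n_genes:
            raise InvalidArgumentError("n_true_egenes must be <= n_genes")
        for name in ("n_samples", "n_genes", "n_snps", "replicates"):
            if getattr(self, name) < 1:
                raise InvalidArgumentError(f"{name} must be positive")

    def with_(self, **kw) -> "ScenarioConfig":
        return dc_replace(self, **kw)

    def label(self) -> str:
        eff = (
            f"beta{self.effect.constant_beta:g}"
            if self.effect.family == "constant"
            else f"gamma({self.effect.shape:g},{self.effect.scale:g})"
        )
        return f"n{self.n_samples}_maf{self.causal_maf:g}_{eff}"


@dataclass
class ReplicateData:
    """All per-replicate artifacts of the simulate→map pipeline."""

    G: GenotypeMatrix
    E: ExpressionMatrix
    truth: TruthAssignments
    genes: pd.DataFrame
    assoc: AssociationTable
    Z: np.ndarray  # standardized dosages, reused for LD lookups


@dataclass
class EGeneScore:
    tp: int
    fp: int
    n_true: int
    tp_genes: list = field(default_factory=list)

    @property
    def n_called(self) -> int:
        return self.tp + self.fp

    @property
    def tpr(self) -> float:
        return self.tp / self.n_true if self.n_true else np.nan

    @property
    def fdr(self) -> float:
        return self.fp / self.n_called if self.n_called else np.nan


@dataclass
class TopESnpScore:
    n_top: int
    n_causal_hit: int
    n_highld_of_misses: int

    @property
    def causal_rate(self) -> float:
        return self.n_causal_hit / self.n_top if self.n_top else np.nan

    @property
    def highld_rate(self) -> float:
        misses = self.n_top - self.n_causal_hit
        return self.n_highld_of_misses / misses if misses else np.nan


def _causal_r2(Z: np.ndarray, snp_cols: np.ndarray, causal_cols: np.ndarray):
    """Max r² of each column in snp_cols against any causal column."""
    n = Z.shape[0]
    R = Z[:, snp_cols].T @ Z[:, causal_cols] / n
    return (R * R).max(axis=1)


def score_egenes(
    calls, truth: TruthAssignments, G: GenotypeMatrix, Z: np.ndarray | None = None
) -> EGeneScore:
    """Gene-level true/false positives under the r² >= 0.8 matching rule."""
    if Z is None:
        Z = standardized_dosages(G)
    known = set(truth.gene_ids)
    true_set = set(truth.true_gene_ids)
    tp, fp, tp_genes = 0, 0, []
    for g in calls.egenes:
        if g not in known:
            raise ConsistencyError(f"called gene {g!r} absent from truth")
        hit = False
        if g in true_set:
            entry = truth.entry_for(g)
            causal_cols = np.array([G.snp_index(s) for s in entry.snp_ids])
            sig_cols = np.asarray(calls.esnp_idx_for(g))
            if sig_cols.size:
                hit = bool(
                    (_causal_r2(Z, sig_cols, causal_cols) >= HIGH_LD_R2).any()
                )
        if hit:
            tp += 1
            tp_genes.append(g)
        else:
            fp += 1
    return EGeneScore(tp=tp, fp=fp, n_true=len(true_set), tp_genes=tp_genes)


def score_top_esnp(
    calls,
    truth: TruthAssignments,
    G: GenotypeMatrix,
    assoc: AssociationTable,
    Z: np.ndarray | None = None,
    egene_score: EGeneScore | None = None,
) -> TopESnpScore:
    """Causal-identification rate of top eSNPs among true-positive eGenes."""
    if Z is None:
        Z = standardized_dosages(G)
    if egene_score is None:
        egene_score = score_egenes(calls, truth, G, Z=Z)
    n_top = n_hit = n_highld = 0
    for g in egene_score.tp_genes:
        entry = truth.entry_for(g)
        top_snp, _ = assoc.top_association(g)
        n_top += 1
        if top_snp in entry.snp_ids:
            n_hit += 1
            continue
        causal_cols = np.array([G.snp_index(s) for s in entry.snp_ids])
        r2 = float(_causal_r2(Z, np.array([G.snp_index(top_snp)]), causal_cols)[0])
        if r2 >= PERFECT_LD_R2:
            n_hit += 1
        elif r2 >= HIGH_LD_R2:
            n_highld += 1
    return TopESnpScore(n_top=n_top, n_causal_hit=n_hit, n_highld_of_misses=n_highld)


_ESTIMATOR_COLS = [
    ("beta_naive", "naive"),
    ("beta_shrinkage", "shrinkage"),
    ("beta_oos", "out_of_sample"),
    ("beta_weighted", "weighted"),
]


def estimator_errors(
    est: pd.DataFrame, truth: TruthAssignments, tp_genes=None
) -> pd.DataFrame:
    """Long frame of per-gene errors (estimate - true beta) per estimator.

    Computed on true-positive eGenes (single-causal truth: the gene's
    simulated effect size).  Positive error means overestimation.
    """
    genes = list(est.gene_id if tp_genes is None else tp_genes)
    sub = est[est.gene_id.isin(genes)]
    true_beta = sub.gene_id.map(
        {e.gene_id: e.betas[0] for e in truth.entries}
    ).to_numpy(dtype=float)
    frames = []
    for col, name in _ESTIMATOR_COLS:
        err = sub[col].to_numpy(dtype=float) - true_beta
        err = err[np.isfinite(err)]
        frames.append(pd.DataFrame({"estimator": name, "error": err}))
    return pd.concat(frames, ignore_index=True)


def score_estimators(
    est: pd.DataFrame, truth: TruthAssignments, tp_genes=None
) -> pd.DataFrame:
    """Median error and MSE per estimator (see :func:`estimator_errors`)."""
    errs = estimator_errors(est, truth, tp_genes=tp_genes)
    rows = []
    for _, name in _ESTIMATOR_COLS:
        e = errs.loc[errs.estimator == name, "error"].to_numpy()
        rows.append(
            (
                name,
                float(np.median(e)) if e.size else np.nan,
                float(np.mean(e**2)) if e.size else np.nan,
                int(e.size),
            )
        )
    return pd.DataFrame(rows, columns=["estimator", "median_error", "mse", "n"])


# ---------------------------------------------------------------------------
# Scenario execution
# ---------------------------------------------------------------------------

def simulate_replicate(config: ScenarioConfig, rep: int) -> ReplicateData:
    """Simulate genotypes, truth and expression and map cis associations."""
    panel = simulate_haplotype_panel(
        n_haplotypes=config.panel_haplotypes,
        n_snps=config.n_snps,
        region_length=config.region_length,
        ld_profile=config.ld_profile,
        seed=child_seed(config.seed, "rep", rep, "panel"),
    )
    G = sample_genotypes(
        panel,
        config.n_samples,
        seed=child_seed(config.seed, "rep", rep, "genotypes"),
        ld_profile=config.ld_profile,
    )
    G = filter_variants(G, maf_min=config.maf_min, hwe_p_min=config.hwe_p_min)
    genes = simulate_gene_annotation(
        n_genes=config.n_genes,
        region_length=config.region_length,
        seed=child_seed(config.seed, "rep", rep, "genes"),
    )
    if config.correlated_blocks:
        from .expression import make_block_truth, simulate_correlated_blocks

        truth = make_block_truth(
            G,
            genes,
            maf_target=config.causal_maf,
            n_true=config.n_true_egenes,
            effect_draw=config.effect.draw,
            seed=child_seed(config.seed, "rep", rep, "truth"),
            maf_tol=config.maf_tol,
        )
        E = simulate_correlated_blocks(
            truth, G, genes,
            seed=child_seed(config.seed, "rep", rep, "expression"),
        )
        if config.inverse_normalize:
            from .expression import inverse_rank_normalize

            E = inverse_rank_normalize(E)
        assoc = map_cis(E, G, genes, window=config.cis_window)
        return ReplicateData(
            G=G, E=E, truth=truth, genes=genes, assoc=assoc,
            Z=standardized_dosages(G),
        )
    truth = select_causal_esnps(
        G,
        genes,
        maf_target=config.causal_maf,
        n_causal=config.n_true_egenes,
        prune_r2=config.prune_r2,
        maf_tol=config.maf_tol,
        seed=child_seed(config.seed, "rep", rep, "truth"),
        effect_draw=config.effect.draw,
        coding=config.coding,
        cis_window=config.cis_window,
    )
    if config.n_causal_per_gene > 1:
        from .expression import add_secondary_causals

        truth = add_secondary_causals(
            truth,
            G,
            n_extra=config.n_causal_per_gene - 1,
            effect_draw=config.effect.draw,
            seed=child_seed(config.seed, "rep", rep, "secondary"),
            cis_window=config.cis_window,
        )
    E = simulate_expression(
        truth,
        G,
        noise=config.noise,
        seed=child_seed(config.seed, "rep", rep, "expression"),
        inverse_normalize=config.inverse_normalize,
    )
    assoc = map_cis(E, G, genes, window=config.cis_window)
    return ReplicateData(
        G=G, E=E, truth=truth, genes=genes, assoc=assoc, Z=standardized_dosages(G)
    )


def parse_method(method: str) -> tuple:
    """'pooled_bh' -> ('pooled', 'bh'); 'eigenmt_bh' -> ('eigenmt', 'bh')."""
    parts = method.lower().split("_")
    if len(parts) != 2:
        raise InvalidArgumentError(
            f"method {method!r}: expected 'pooled_<m>' or '<local>_<global>'"
        )
    return parts[0], parts[1]


def apply_method(
    data: ReplicateData,
    method: str,
    alpha: float = 0.05,
    seed: int = 0,
    **hier_kw,
):
    """Apply one pooled or hierarchical correction to a replicate."""
    first, second = parse_method(method)
    if first == "pooled":
        return pooled_correct(data.assoc, method=second, alpha=alpha)
    return hierarchical_correct(
        data.assoc,
        local_method=first,
        global_method=second,
        alpha=alpha,
        G=data.G,
        E=data.E,
        seed=seed,
        **hier_kw,
    )


def run_scenario(
    config: ScenarioConfig,
    methods,
    alpha: float = 0.05,
    top_esnp: bool = False,
    bootstrap_B: int | None = None,
    bootstrap_method: str = "bonferroni_bh",
    **hier_kw,
) -> pd.DataFrame:
    """Run all replicates of one scenario and score each method.

    Returns a long-format frame (scenario, method, metric, value).  FDR is
    pooled over replicates; for ``top_esnp=True`` the causal-identification
    counts of true-positive eGenes are pooled likewise.  ``bootstrap_B``
    additionally runs the Winner's-Curse bootstrap on the gate given by
    ``bootstrap_method`` and reports pooled estimator errors.
    """
    methods = list(methods)
    agg = {m: {"tp": 0, "fp": 0, "n_true": 0} for m in methods}
    top = {m: {"n_top": 0, "hit": 0, "highld": 0} for m in methods}
    est_frames = []
    for rep in range(config.replicates):
        data = simulate_replicate(config, rep)
        for m in methods:
            calls = apply_method(
                data,
                m,
                alpha=alpha,
                seed=child_seed(config.seed, "rep", rep, "method", m),
                **hier_kw,
            )
            sc = score_egenes(calls, data.truth, data.G, Z=data.Z)
            agg[m]["tp"] += sc.tp
            agg[m]["fp"] += sc.fp
            agg[m]["n_true"] += sc.n_true
            if top_esnp:
                ts = score_top_esnp(
                    calls, data.truth, data.G, data.assoc, Z=data.Z, egene_score=sc
                )
                top[m]["n_top"] += ts.n_top
                top[m]["hit"] += ts.n_causal_hit
                top[m]["highld"] += ts.n_highld_of_misses
            if bootstrap_B and m == bootstrap_method and calls.egenes:
                bdf = bootstrap_correct(
                    data.E,
                    data.G,
                    calls,
                    data.assoc,
                    B_total=bootstrap_B,
                    seed=child_seed(config.seed, "rep", rep, "bootstrap"),
                )
                est_frames.append(
                    estimator_errors(bdf, data.truth, tp_genes=sc.tp_genes)
                )
    rows = []
    label = config.label()
    for m in methods:
        a = agg[m]
        called = a["tp"] + a["fp"]
        rows.append((label, m, "tp", a["tp"]))
        rows.append((label, m, "fp", a["fp"]))
        rows.append((label, m, "n_significant_egenes", called))
        rows.append((label, m, "tpr", a["tp"] / a["n_true"] if a["n_true"] else np.nan))
        rows.append((label, m, "fdr", a["fp"] / called if called else np.nan))
        if top_esnp:
            t = top[m]
            misses = t["n_top"] - t["hit"]
            rows.append((label, m, "top_esnp_n", t["n_top"]))
            rows.append((label, m, "top_esnp_hits", t["hit"]))
            rows.append(
                (label, m, "top_esnp_causal_rate",
                 t["hit"] / t["n_top"] if t["n_top"] else np.nan)
            )
            rows.append(
                (label, m, "top_esnp_highld_rate",
                 t["highld"] / misses if misses else np.nan)
            )
    out = pd.DataFrame(rows, columns=["scenario", "method", "metric", "value"])
    if est_frames:
        est = pd.concat(est_frames, ignore_index=True)
        for name, grp in est.groupby("estimator"):
            e = grp.error.to_numpy()
            out.loc[len(out)] = (
                label, bootstrap_method, f"{name}_median_error",
                float(np.median(e)) if e.size else np.nan,
            )
            out.loc[len(out)] = (
                label, bootstrap_method, f"{name}_mse",
                float(np.mean(e**2)) if e.size else np.nan,
            )
    return out


def run_scenario_grid(configs, methods, **kw) -> pd.DataFrame:
    """Score every method on every scenario configuration."""
    frames = [run_scenario(c, methods, **kw) for c in configs]
    return pd.concat(frames, ignore_index=True)
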