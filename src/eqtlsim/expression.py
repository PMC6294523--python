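"""Gene-expression simulation under the generative eQTL models.

Expression of a true eGene is a linear function of the (coded) minor-allele
dosage of its causal eSNP(s) plus unit-variance noise:

    y_i = sum_k beta_k * g_ik + eps_i,    eps_i ~ N(0, 1)

Null genes are pure noise.  Variants implemented here:

* constant or gamma-distributed effect sizes,
* normal or log-normal noise, optionally followed by inverse rank
  normalization,
* dominant (0,2,2) and recessive (0,0,2) codings of the causal dosage,
* co-expression blocks in which adjacent true eGenes share one causal eSNP
  and correlated noise,
* two or three causal eSNPs per gene, with the extra causal variants chosen
  so their correlation with the primary eSNP follows a Beta(2.6, 4.5)
  distribution (the LD spectrum reported for secondary signals in large
  blood eQTL data).
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .errors import (
    CapacityError,
    ConsistencyError,
    DegenerateInputError,
    InvalidArgumentError,
)
from .genotypes import (
    CODING_MODES,
    GenotypeMatrix,
    TruthAssignments,
    TruthEntry,
    standardized_dosages,
)

__all__ = [
    "EffectSizeDistribution",
    "ExpressionMatrix",
    "CoexpressionBlockSpec",
    "code_genotype",
    "simulate_expression",
    "simulate_correlated_blocks",
    "make_block_truth",
    "select_secondary_causals",
    "add_secondary_causals",
    "inverse_rank_normalize",
]


@dataclass(frozen=True)
class EffectSizeDistribution:
    """True effect sizes: s.d. of expression per minor allele.

    ``gamma`` draws from Gamma(shape, scale); the defaults (1.8, 0.35) give
    mostly small effects with a long tail and are an explicit stand-in for a
    distribution fitted to real cohort eQTL effect estimates.  ``constant``
    uses ``constant_beta`` for every eGene.
    """

    family: str = "gamma"
    shape: float = 1.8
    scale: float = 0.35
    constant_beta: float = 1.0

    def __post_init__(self):
        if self.family not in ("gamma", "constant"):
            raise InvalidArgumentError(f"unknown effect family: {self.family!r}")
        if self.shape <= 0 or self.scale <= 0 or self.constant_beta <= 0:
            raise InvalidArgumentError("effect-size parameters must be positive")

    def draw(self, rng: np.random.Generator, size: int) -> np.ndarray:
        if self.family == "constant":
            return np.full(size, float(self.constant_beta))
        out = rng.gamma(self.shape, self.scale, size=size)
        # strictly positive draws (gamma can underflow to 0.0)
        return np.maximum(out, 1e-12)


@dataclass
class ExpressionMatrix:
    """Expression values (genes x samples) with unique gene ids."""

    values: np.ndarray
    gene_ids: list

    def __post_init__(self):
        self.values = np.ascontiguousarray(self.values, dtype=np.float64)
        self.gene_ids = list(self.gene_ids)
        if self.values.ndim != 2 or self.values.shape[0] != len(self.gene_ids):
            raise InvalidArgumentError("values rows must match gene_ids")
        if len(set(self.gene_ids)) != len(self.gene_ids):
            raise InvalidArgumentError("gene_ids must be unique")
        if self.values.size and not np.all(np.isfinite(self.values)):
            raise InvalidArgumentError("expression values must be finite")
        self._row = {g: i for i, g in enumerate(self.gene_ids)}

    @property
    def n_genes(self) -> int:
        return self.values.shape[0]

    @property
    def n_samples(self) -> int:
        return self.values.shape[1]

    def row(self, gene_id: str) -> np.ndarray:
        try:
            return self.values[self._row[gene_id]]
        except KeyError:
            raise InvalidArgumentError(f"unknown gene id: {gene_id!r}") from None


@dataclass(frozen=True)
class CoexpressionBlockSpec:
    """Co-expression block layout and noise-correlation bounds."""

    block_length: int = 1_000_000
    r_low: float = 0.6
    r_high: float = 0.9

    def __post_init__(self):
        if not (0 <= self.r_low <= self.r_high < 1):
            raise InvalidArgumentError("require 0 <= r_low <= r_high < 1")
        if self.block_length < 1:
            raise InvalidArgumentError("block_length must be positive")


def code_genotype(dosage, mode: str):
    """Recode additive dosages for the given genetic model.

    additive -> (0, 1, 2); dominant -> (0, 2, 2); recessive -> (0, 0, 2).
    """
    d = np.asarray(dosage)
    if d.size and (d.min() < 0 or d.max() > 2):
        raise InvalidArgumentError("dosage values must be in {0, 1, 2}")
    if mode == "additive":
        out = d.astype(np.float64)
    elif mode == "dominant":
        out = np.where(d > 0, 2.0, 0.0)
    elif mode == "recessive":
        out = np.where(d == 2, 2.0, 0.0)
    else:
        raise InvalidArgumentError(f"unknown coding mode: {mode!r}")
    return out if out.ndim else float(out)


def _noise(rng: np.random.Generator, noise: str, size) -> np.ndarray:
    if noise == "normal":
        return rng.standard_normal(size)
    if noise == "lognormal":
        return rng.lognormal(mean=0.0, sigma=1.0, size=size)
    if noise == "none":
        return np.zeros(size)
    raise InvalidArgumentError(f"unknown noise family: {noise!r}")


def simulate_expression(
    truth: TruthAssignments,
    G: GenotypeMatrix,
    noise: str = "normal",
    seed: int = 0,
    inverse_normalize: bool = False,
) -> ExpressionMatrix:
    """Simulate one expression matrix for all genes in ``truth``.

    Rows are ordered as ``truth.gene_ids`` (true eGenes first, then null
    genes).  Reproducible bit-exactly for a fixed seed.
    """
    rng = rng_for(seed, "expression")
    gene_ids = truth.gene_ids
    n = G.n_samples
    values = _noise(rng, noise, (len(gene_ids), n))
    for row, entry in enumerate(truth.entries):
        genetic = np.zeros(n)
        for snp_id, beta in zip(entry.snp_ids, entry.betas):
            try:
                j = G.snp_index(snp_id)
            except InvalidArgumentError as exc:
                raise ConsistencyError(
                    f"causal SNP {snp_id!r} for gene {entry.gene_id!r} "
                    "is missing from the genotype matrix"
                ) from exc
            genetic += beta * code_genotype(G.dosages[:, j], entry.coding)
        values[row] += genetic
    E = ExpressionMatrix(values=values, gene_ids=gene_ids)
    return inverse_rank_normalize(E) if inverse_normalize else E


# ---------------------------------------------------------------------------
# Correlated co-expression blocks
# ---------------------------------------------------------------------------

def make_block_truth(
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    maf_target: float,
    n_true: int = 200,
    spec: CoexpressionBlockSpec = CoexpressionBlockSpec(),
    effect_draw=None,
    seed: int = 0,
    maf_tol: float = 0.2,
) -> TruthAssignments:
    """Truth table in which true eGenes of a 1 Mb block share a causal eSNP.

    Genes are binned by TSS into consecutive ``spec.block_length`` intervals
    from the chromosome start; ``n_true`` random genes become true eGenes and
    each occupied block receives one causal eSNP located inside the block
    (hence cis to every gene of the block) at the target MAF.
    """
    rng = rng_for(seed, "block-truth")
    lo = maf_target * (1 - maf_tol)
    hi = min(0.5, maf_target * (1 + maf_tol))
    band = np.flatnonzero((G.maf >= lo) & (G.maf <= hi))
    if band.size == 0:
        raise CapacityError(f"no SNPs with MAF in [{lo:.4g}, {hi:.4g}]")
    chosen = rng.choice(len(genes), size=n_true, replace=False)
    true_genes = genes.iloc[np.sort(chosen)]
    blocks = (true_genes.tss.to_numpy() - 1) // spec.block_length
    entries: list[TruthEntry] = []
    for b in np.unique(blocks):
        members = true_genes[blocks == b]
        b_lo, b_hi = b * spec.block_length + 1, (b + 1) * spec.block_length
        cands = band[(G.positions[band] >= b_lo) & (G.positions[band] <= b_hi)]
        if cands.size == 0:
            raise CapacityError(
                f"block {int(b)} [{b_lo}, {b_hi}] has no SNP at MAF target "
                f"{maf_target}"
            )
        snp = G.snp_ids[rng.choice(cands)]
        beta = (
            float(effect_draw(rng, 1)[0]) if effect_draw is not None else 1.0
        )
        for g in members.gene_id:
            entries.append(
                TruthEntry(gene_id=g, snp_ids=(snp,), betas=(beta,))
            )
    null_ids = [g for g in genes.gene_id if g not in set(true_genes.gene_id)]
    return TruthAssignments(entries=entries, null_gene_ids=null_ids)


def correlated_noise(
    rng: np.random.Generator, n_genes: int, n_samples: int, r: np.ndarray
) -> np.ndarray:
    """Unit-variance noise rows with row i correlated to row 0 at r[i].

    Row 0 ignores ``r[0]``; row i is r_i*eps_1 + sqrt(1-r_i^2)*eps_i, which
    has variance r_i^2 + (1 - r_i^2) = 1 by construction.
    """
    eps = rng.standard_normal((n_genes, n_samples))
    out = eps.copy()
    for i in range(1, n_genes):
        out[i] = r[i] * eps[0] + np.sqrt(1.0 - r[i] ** 2) * eps[i]
    return out


def simulate_correlated_blocks(
    truth: TruthAssignments,
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    spec: CoexpressionBlockSpec = CoexpressionBlockSpec(),
    seed: int = 0,
) -> ExpressionMatrix:
    """Expression with correlated noise among the true eGenes of each block.

    ``truth`` should assign one shared causal eSNP per block (see
    :func:`make_block_truth`).  Null genes get independent N(0,1) noise.
    """
    rng = rng_for(seed, "block-expression")
    n = G.n_samples
    tss = dict(zip(genes.gene_id, genes.tss))
    gene_ids = truth.gene_ids
    values = np.empty((len(gene_ids), n))
    row_of = {g: i for i, g in enumerate(gene_ids)}
    blocks: dict[int, list[TruthEntry]] = {}
    for e in truth.entries:
        b = (int(tss[e.gene_id]) - 1) // spec.block_length
        blocks.setdefault(b, []).append(e)
    for b in sorted(blocks):
        members = blocks[b]
        k = len(members)
        r = np.concatenate([[0.0], rng.uniform(spec.r_low, spec.r_high, size=k - 1)])
        noise = correlated_noise(rng, k, n, r)
        for i, e in enumerate(members):
            genetic = np.zeros(n)
            for snp_id, beta in zip(e.snp_ids, e.betas):
                genetic += beta * code_genotype(
                    G.dosages[:, G.snp_index(snp_id)], e.coding
                )
            values[row_of[e.gene_id]] = genetic + noise[i]
    for g in truth.null_gene_ids:
        values[row_of[g]] = rng.standard_normal(n)
    return ExpressionMatrix(values=values, gene_ids=gene_ids)


# ---------------------------------------------------------------------------
# Multiple causal eSNPs
# ---------------------------------------------------------------------------

def select_secondary_causals(
    G: GenotypeMatrix,
    primary_snp: str,
    n_extra: int,
    ld_beta_shape: tuple = (2.6, 4.5),
    seed: int = 0,
    exclude=(),
    cis_window: int = 1_000_000,
    Z: np.ndarray | None = None,
) -> list:
    """Pick extra causal SNPs whose |r| with the primary follows a beta law.

    For each extra causal SNP a target |correlation| is drawn from
    Beta(*ld_beta_shape*) and the SNP within ``cis_window`` of the primary
    (not already causal) whose realized |r| is closest to the target is
    selected.
    """
    if n_extra < 1:
        raise InvalidArgumentError("n_extra must be >= 1")
    rng = rng_for(seed, "secondary-causals", primary_snp)
    j = G.snp_index(primary_snp)
    if Z is None:
        Z = standardized_dosages(G)
    pos = G.positions
    win = np.flatnonzero(np.abs(pos - pos[j]) <= cis_window)
    taken = {j} | {G.snp_index(s) for s in exclude}
    win = np.array([w for w in win if w not in taken and Z[:, w].std() > 0])
    if win.size == 0:
        raise CapacityError(f"no eligible neighbours for primary SNP {primary_snp!r}")
    absr = np.abs(Z[:, win].T @ Z[:, j] / G.n_samples)
    chosen: list = []
    for _ in range(n_extra):
        target = rng.beta(*ld_beta_shape)
        order = np.argsort(np.abs(absr - target), kind="stable")
        for o in order:
            if win[o] not in taken:
                taken.add(int(win[o]))
                chosen.append(G.snp_ids[win[o]])
                break
        else:
            raise CapacityError("ran out of eligible neighbour SNPs")
    return chosen


def add_secondary_causals(
    truth: TruthAssignments,
    G: GenotypeMatrix,
    n_extra: int,
    effect_draw=None,
    seed: int = 0,
    ld_beta_shape: tuple = (2.6, 4.5),
    cis_window: int = 1_000_000,
) -> TruthAssignments:
    """Extend every true eGene with ``n_extra`` additional causal eSNPs."""
    rng = rng_for(seed, "secondary-effects")
    Z = standardized_dosages(G)
    entries = []
    for e in truth.entries:
        extra = select_secondary_causals(
            G,
            e.snp_ids[0],
            n_extra,
            ld_beta_shape=ld_beta_shape,
            seed=seed,
            exclude=e.snp_ids[1:],
            cis_window=cis_window,
            Z=Z,
        )
        betas = (
            effect_draw(rng, n_extra)
            if effect_draw is not None
            else np.ones(n_extra)
        )
        entries.append(
            replace(
                e,
                snp_ids=e.snp_ids + tuple(extra),
                betas=e.betas + tuple(float(b) for b in betas),
            )
        )
    return TruthAssignments(entries=entries, null_gene_ids=truth.null_gene_ids)


# ---------------------------------------------------------------------------
# Inverse rank normalization
# ---------------------------------------------------------------------------

def inverse_rank_normalize(E: ExpressionMatrix) -> ExpressionMatrix:
    """Per-gene rank-based inverse normal transform.

    Values are replaced by standard-normal quantiles of (rank - 0.5)/n, with
    average ranks for ties; the transform is monotone per gene.
    """
    out = np.empty_like(E.values)
    n = E.n_samples
    for i in range(E.n_genes):
        v = E.values[i]
        if np.ptp(v) == 0:
            raise DegenerateInputError(
                f"gene {E.gene_ids[i]!r} is constant; rank-normal transform undefined"
            )
        ranks = stats.rankdata(v, method="average")
        out[i] = stats.norm.ppf((ranks - 0.5) / n)
    return ExpressionMatrix(values=out, gene_ids=list(E.gene_ids))
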