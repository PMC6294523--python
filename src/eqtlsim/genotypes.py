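"""LD-structured genotype simulation, variant QC and causal-eSNP selection.

The generator works in two stages, mirroring how reference-panel based
simulators produce study genotypes:

1. :func:`simulate_haplotype_panel` builds a small phased reference panel
   (default 100 haplotypes, standing in for a 1000-Genomes-sized population
   sample of one chromosome) with a standard neutral coalescent with
   recombination.  This yields a realistic allele-frequency spectrum (density
   roughly proportional to 1/p, down to panel singletons) and pairwise r²
   that decays smoothly with inter-SNP distance on the scale set by the
   population-scaled recombination rate.
2. :func:`sample_genotypes` expands the panel to an arbitrary number of
   diploid individuals by Li–Stephens-style mosaic copying: each study
   haplotype copies a random panel haplotype, switching template at a
   Poisson rate per bp, with a small per-site copying error rate.  Diploid
   dosages are the sum of two independent mosaics.

Variant QC (:func:`filter_variants`) applies the conventional MAF and
Hardy–Weinberg filters.  :func:`select_causal_esnps` picks true causal eSNPs
at a target MAF from an LD-pruned subset and assigns each to a cis gene,
producing the simulation ground truth.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import child_seed, rng_for
from .errors import (
    CapacityError,
    DegenerateInputError,
    InvalidArgumentError,
)

logger = logging.getLogger(__name__)

__all__ = [
    "LDProfile",
    "HaplotypePanel",
    "GenotypeMatrix",
    "TruthEntry",
    "TruthAssignments",
    "simulate_haplotype_panel",
    "sample_genotypes",
    "filter_variants",
    "hwe_pvalues",
    "ld_r2",
    "select_causal_esnps",
    "simulate_gene_annotation",
    "CODING_MODES",
]

CODING_MODES = ("additive", "dominant", "recessive")


@dataclass(frozen=True)
class LDProfile:
    """Parameters controlling LD decay and panel-to-sample copying.

    effective_pop_size
        Coalescent effective population size of the panel; together with
        ``recomb_rate`` it sets the LD decay length scale (~1/(4·Ne·c) bp).
    recomb_rate
        Per-bp per-generation recombination rate of the panel ancestry.
    switch_rate
        Template switch rate per bp of the mosaic copying process used when
        expanding the panel into study haplotypes.
    error_rate
        Per-site allele copying error (mutation) probability in the mosaic;
        introduces rare variation and slightly erodes perfect LD.
    """

    effective_pop_size: float = 1e4
    recomb_rate: float = 1e-8
    switch_rate: float = 1e-6
    error_rate: float = 1e-4


@dataclass
class HaplotypePanel:
    """Phased reference haplotypes: binary alleles at ordered SNP positions."""

    alleles: np.ndarray  # (n_haplotypes, n_snps) uint8 in {0, 1}
    positions: np.ndarray  # (n_snps,) int64, strictly increasing
    snp_ids: np.ndarray  # (n_snps,) str

    def __post_init__(self):
        self.alleles = np.ascontiguousarray(self.alleles, dtype=np.uint8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.alleles.ndim != 2 or self.alleles.shape[0] < 2:
            raise InvalidArgumentError("panel needs >= 2 haplotypes")
        if self.alleles.shape[1] != len(self.positions):
            raise InvalidArgumentError("positions do not match allele columns")
        if len(self.snp_ids) != len(self.positions):
            raise InvalidArgumentError("snp_ids do not match positions")
        if self.alleles.size and self.alleles.max() > 1:
            raise InvalidArgumentError("panel alleles must be 0/1")
        if len(self.positions) > 1 and not np.all(np.diff(self.positions) > 0):
            raise InvalidArgumentError("positions must be strictly increasing")

    @property
    def n_haplotypes(self) -> int:
        return self.alleles.shape[0]

    @property
    def n_snps(self) -> int:
        return self.alleles.shape[1]

    @property
    def frequencies(self) -> np.ndarray:
        """Derived-allele frequency of each SNP in the panel."""
        return self.alleles.mean(axis=0)


@dataclass
class GenotypeMatrix:
    """Diploid minor-allele dosages for a sample of individuals."""

    dosages: np.ndarray  # (n_samples, n_snps) int8 in {0, 1, 2}
    positions: np.ndarray
    snp_ids: np.ndarray
    maf: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self):
        self.dosages = np.ascontiguousarray(self.dosages, dtype=np.int8)
        self.positions = np.asarray(self.positions, dtype=np.int64)
        self.snp_ids = np.asarray(self.snp_ids, dtype=object)
        if self.dosages.ndim != 2:
            raise InvalidArgumentError("dosages must be 2-D (samples x SNPs)")
        if self.dosages.shape[1] != len(self.positions):
            raise InvalidArgumentError("positions do not match dosage columns")
        if len(self.snp_ids) != len(self.positions):
            raise InvalidArgumentError("snp_ids do not match positions")
        if self.dosages.size and (self.dosages.min() < 0 or self.dosages.max() > 2):
            raise InvalidArgumentError("dosages must be in {0, 1, 2}")
        computed = self._compute_maf()
        if self.maf is None:
            self.maf = computed
        else:
            self.maf = np.asarray(self.maf, dtype=float)
            if not np.allclose(self.maf, computed, atol=1e-12):
                raise InvalidArgumentError("stored MAF does not match dosages")
        self._index = None

    def _compute_maf(self) -> np.ndarray:
        if self.dosages.shape[0] == 0:
            return np.zeros(self.dosages.shape[1])
        freq = self.dosages.mean(axis=0) / 2.0
        return np.minimum(freq, 1.0 - freq)

    @property
    def n_samples(self) -> int:
        return self.dosages.shape[0]

    @property
    def n_snps(self) -> int:
        return self.dosages.shape[1]

    def snp_index(self, snp_id: str) -> int:
        if self._index is None:
            self._index = {s: i for i, s in enumerate(self.snp_ids)}
        try:
            return self._index[snp_id]
        except KeyError:
            raise InvalidArgumentError(f"unknown SNP id: {snp_id!r}") from None

    def subset(self, keep: np.ndarray) -> "GenotypeMatrix":
        keep = np.asarray(keep)
        return GenotypeMatrix(
            dosages=self.dosages[:, keep],
            positions=self.positions[keep],
            snp_ids=self.snp_ids[keep],
        )


@dataclass(frozen=True)
class TruthEntry:
    """Ground truth for one simulated eGene."""

    gene_id: str
    snp_ids: tuple
    betas: tuple
    coding: str = "additive"

    def __post_init__(self):
        if self.coding not in CODING_MODES:
            raise InvalidArgumentError(f"unknown coding mode: {self.coding!r}")
        if len(self.snp_ids) != len(self.betas):
            raise InvalidArgumentError("snp_ids and betas length mismatch")
        if any(b <= 0 for b in self.betas):
            raise InvalidArgumentError("true eGene effect sizes must be > 0")


@dataclass
class TruthAssignments:
    """Per-gene causal eSNPs and effect sizes; the simulation ground truth."""

    entries: list
    null_gene_ids: list

    def __post_init__(self):
        seen = set()
        for e in self.entries:
            if e.gene_id in seen:
                raise InvalidArgumentError(f"gene {e.gene_id} appears twice in truth")
            seen.add(e.gene_id)
        if seen & set(self.null_gene_ids):
            raise InvalidArgumentError("a gene cannot be both true eGene and null")

    @property
    def true_gene_ids(self) -> list:
        return [e.gene_id for e in self.entries]

    @property
    def gene_ids(self) -> list:
        """All simulated genes: true eGenes first, then null genes."""
        return self.true_gene_ids + list(self.null_gene_ids)

    def entry_for(self, gene_id: str) -> TruthEntry:
        for e in self.entries:
            if e.gene_id == gene_id:
                return e
        raise InvalidArgumentError(f"gene {gene_id!r} is not a true eGene")

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for e in self.entries:
            for s, b in zip(e.snp_ids, e.betas):
                rows.append((e.gene_id, s, b, e.coding))
        return pd.DataFrame(rows, columns=["gene_id", "snp_id", "beta", "coding_mode"])


# ---------------------------------------------------------------------------
# Panel simulation
# ---------------------------------------------------------------------------

def simulate_haplotype_panel(
    n_haplotypes: int = 100,
    n_snps: int = 16000,
    region_length: int = 20_000_000,
    ld_profile: LDProfile = LDProfile(),
    maf_spectrum=None,
    seed: int = 0,
) -> HaplotypePanel:
    """Simulate a phased haplotype panel with realistic LD decay.

    The panel ancestry is a standard neutral coalescent with recombination
    (haploid samples), with binary mutations dropped on the genealogy at a
    rate calibrated so the expected number of segregating sites comfortably
    exceeds ``n_snps``; sites are then thinned to exactly ``n_snps``.

    Parameters
    ----------
    maf_spectrum
        ``None`` keeps the neutral site-frequency spectrum (density roughly
        proportional to 1/p).  Otherwise a callable ``w(p)`` giving a relative
        sampling weight per panel minor-allele frequency, used when thinning
        sites; this reshapes, but cannot create frequencies absent from the
        panel.
    """
    import msprime

    if n_haplotypes < 2:
        raise InvalidArgumentError("n_haplotypes must be >= 2")
    if n_snps < 1:
        raise InvalidArgumentError("n_snps must be >= 1")
    if region_length < 1:
        raise InvalidArgumentError("region_length must be >= 1")

    anc_seed = child_seed(seed, "panel-ancestry") or 1
    mut_seed = child_seed(seed, "panel-mutations") or 1
    ts = msprime.sim_ancestry(
        samples=n_haplotypes,
        ploidy=1,
        sequence_length=region_length,
        recombination_rate=ld_profile.recomb_rate,
        population_size=ld_profile.effective_pop_size,
        random_seed=anc_seed,
    )
    # Haploid coalescent: E[total tree length] = 2*Ne*sum_{i<n} 1/i, so the
    # expected number of segregating sites is mu*L times that.  Overshoot by
    # 60% so thinning to n_snps almost surely succeeds.
    harmonic = float(np.sum(1.0 / np.arange(1, n_haplotypes)))
    mu = 1.6 * n_snps / (
        2.0 * ld_profile.effective_pop_size * region_length * harmonic
    )
    ts = msprime.sim_mutations(
        ts, rate=mu, random_seed=mut_seed, model=msprime.BinaryMutationModel()
    )
    alleles = ts.genotype_matrix().T.astype(np.uint8)  # (haplotypes, sites)
    positions = np.array([int(s.position) for s in ts.sites()], dtype=np.int64)

    # keep polymorphic biallelic sites at unique integer positions
    freq = alleles.mean(axis=0)
    keep = (freq > 0) & (freq < 1)
    keep &= np.concatenate([[True], np.diff(positions) > 0])
    alleles, positions = alleles[:, keep], positions[keep]

    if alleles.shape[1] < n_snps:
        raise CapacityError(
            f"coalescent yielded {alleles.shape[1]} usable sites "
            f"(< requested {n_snps}); increase region_length or Ne"
        )
    rng = rng_for(seed, "panel-thin")
    if maf_spectrum is None:
        chosen = rng.choice(alleles.shape[1], size=n_snps, replace=False)
    else:
        p = alleles.mean(axis=0)
        w = np.asarray(maf_spectrum(np.minimum(p, 1 - p)), dtype=float)
        w = np.clip(w, 0, np.inf)
        if (w > 0).sum() < n_snps:
            raise CapacityError(
                f"maf_spectrum leaves {(w > 0).sum()} candidate sites "
                f"(< requested {n_snps}); relax the spectrum or enlarge the region"
            )
        chosen = rng.choice(
            alleles.shape[1], size=n_snps, replace=False, p=w / w.sum()
        )
    chosen.sort()
    alleles, positions = alleles[:, chosen], positions[chosen]
    positions = positions + 1  # 1-based inclusive coordinates
    snp_ids = np.array([f"snp{p}" for p in positions], dtype=object)
    return HaplotypePanel(alleles=alleles, positions=positions, snp_ids=snp_ids)


# ---------------------------------------------------------------------------
# Genotype sampling (Li–Stephens mosaic)
# ---------------------------------------------------------------------------

def _mosaic_haplotypes(
    panel: HaplotypePanel,
    n_haplotypes: int,
    switch_rate: float,
    error_rate: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Sample haplotypes by mosaic copying from the panel."""
    H, S = panel.n_haplotypes, panel.n_snps
    L = int(panel.positions[-1]) + 1 if S else 1
    out = np.empty((n_haplotypes, S), dtype=np.uint8)
    pos = panel.positions
    for h in range(n_haplotypes):
        n_switch = rng.poisson(switch_rate * L)
        if n_switch == 0:
            template = np.full(S, rng.integers(H))
        else:
            breaks = np.sort(rng.integers(1, L, size=n_switch))
            templates = rng.integers(H, size=n_switch + 1)
            template = templates[np.searchsorted(breaks, pos, side="right")]
        hap = panel.alleles[template, np.arange(S)]
        if error_rate > 0 and S:
            n_err = rng.binomial(S, error_rate)
            if n_err:
                idx = rng.choice(S, size=n_err, replace=False)
                hap = hap.copy()
                hap[idx] ^= 1
        out[h] = hap
    return out


def sample_genotypes(
    panel: HaplotypePanel,
    n_samples: int,
    seed: int = 0,
    switch_rate: float | None = None,
    error_rate: float | None = None,
    ld_profile: LDProfile = LDProfile(),
) -> GenotypeMatrix:
    """Sample diploid individuals by mosaic resampling of the panel.

    Each individual is the sum of two independently sampled mosaic
    haplotypes.  Dosages are recoded to count the minor allele in the sample
    (columns with sample frequency > 0.5 are flipped).
    """
    if n_samples < 1:
        raise InvalidArgumentError("n_samples must be >= 1")
    if panel.n_snps == 0:
        raise InvalidArgumentError("panel has no SNPs")
    sw = ld_profile.switch_rate if switch_rate is None else switch_rate
    er = ld_profile.error_rate if error_rate is None else error_rate
    rng = rng_for(seed, "genotype-sampling")
    haps = _mosaic_haplotypes(panel, 2 * n_samples, sw, er, rng)
    dosages = (haps[0::2].astype(np.int8) + haps[1::2].astype(np.int8))
    freq = dosages.mean(axis=0) / 2.0
    flip = freq > 0.5
    if np.any(flip):
        dosages[:, flip] = 2 - dosages[:, flip]
    return GenotypeMatrix(
        dosages=dosages, positions=panel.positions, snp_ids=panel.snp_ids
    )


# ---------------------------------------------------------------------------
# Variant QC
# ---------------------------------------------------------------------------

def hwe_pvalues(G: GenotypeMatrix) -> np.ndarray:
    """Chi-square (1 df) Hardy–Weinberg goodness-of-fit p-value per SNP."""
    d = G.dosages
    n = d.shape[0]
    n2 = (d == 2).sum(axis=0)
    n1 = (d == 1).sum(axis=0)
    n0 = n - n1 - n2
    p = (n1 + 2 * n2) / (2.0 * n)
    q = 1.0 - p
    exp = np.stack([n * q * q, 2 * n * p * q, n * p * p])
    obs = np.stack([n0, n1, n2])
    with np.errstate(divide="ignore", invalid="ignore"):
        chi2 = np.where(exp > 0, (obs - exp) ** 2 / exp, 0.0).sum(axis=0)
    pvals = stats.chi2.sf(chi2, df=1)
    # monomorphic SNPs: no test, define p = 1
    mono = (p == 0) | (p == 1)
    pvals[mono] = 1.0
    return pvals


def filter_variants(
    G: GenotypeMatrix, maf_min: float = 0.005, hwe_p_min: float = 5e-6
) -> GenotypeMatrix:
    """Drop SNPs with MAF < ``maf_min`` or HWE p-value < ``hwe_p_min``."""
    if G.n_snps == 0:
        return G
    keep = (G.maf >= maf_min) & (hwe_pvalues(G) >= hwe_p_min)
    dropped = int((~keep).sum())
    if dropped:
        logger.info("filter_variants: removed %d of %d SNPs", dropped, G.n_snps)
    return G.subset(np.flatnonzero(keep))


# ---------------------------------------------------------------------------
# LD
# ---------------------------------------------------------------------------

def ld_r2(G: GenotypeMatrix, snp_a: str, snp_b: str) -> float:
    """Squared Pearson correlation between two SNPs' dosage vectors."""
    a = G.dosages[:, G.snp_index(snp_a)].astype(float)
    b = G.dosages[:, G.snp_index(snp_b)].astype(float)
    va, vb = a.var(), b.var()
    if va == 0 or vb == 0:
        raise DegenerateInputError("LD undefined for zero-variance SNP")
    r = np.corrcoef(a, b)[0, 1]
    return float(r * r)


def _r2_to_selected(zc: np.ndarray, Zsel: np.ndarray) -> np.ndarray:
    """r² of a standardized candidate column against standardized columns."""
    if Zsel.shape[1] == 0:
        return np.zeros(0)
    n = zc.shape[0]
    r = Zsel.T @ zc / n
    return r * r


def standardized_dosages(G: GenotypeMatrix) -> np.ndarray:
    """Column-standardized dosage matrix (zero-variance columns left at 0)."""
    X = G.dosages.astype(np.float64)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = np.inf
    return (X - mu) / sd


# ---------------------------------------------------------------------------
# Causal eSNP selection
# ---------------------------------------------------------------------------

def simulate_gene_annotation(
    n_genes: int = 618,
    region_length: int = 20_000_000,
    seed: int = 0,
    chrom: str = "chr22",
) -> pd.DataFrame:
    """Random gene annotation: uniform TSS positions on one chromosome."""
    if n_genes < 1:
        raise InvalidArgumentError("n_genes must be >= 1")
    rng = rng_for(seed, "gene-annotation")
    tss = np.sort(rng.choice(np.arange(1, region_length + 1), size=n_genes, replace=False))
    gene_ids = [f"gene{i + 1:04d}" for i in range(n_genes)]
    return pd.DataFrame({"gene_id": gene_ids, "chrom": chrom, "tss": tss})


def select_causal_esnps(
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    maf_target: float,
    n_causal: int = 200,
    prune_r2: float = 0.3,
    seed: int = 0,
    maf_tol: float = 0.2,
    effect_draw=None,
    coding: str = "additive",
    cis_window: int = 1_000_000,
) -> TruthAssignments:
    """Designate true eGenes and pick their causal eSNPs at a target MAF.

    ``n_causal`` genes are chosen at random; for each, a causal SNP is drawn
    from the SNPs within ±``cis_window`` of its TSS whose sample MAF is
    within ``maf_tol`` (relative) of ``maf_target``, subject to pairwise
    r² <= ``prune_r2`` with all previously selected causal SNPs.  Effect
    sizes come from ``effect_draw(rng, k)`` (positive draws), or 1.0 each.
    """
    if not (0 < maf_target <= 0.5):
        raise InvalidArgumentError("maf_target must be in (0, 0.5]")
    if n_causal < 1:
        raise InvalidArgumentError("n_causal must be >= 1")
    if n_causal > len(genes):
        raise CapacityError(
            f"requested {n_causal} true eGenes but only {len(genes)} genes"
        )
    lo = maf_target * (1 - maf_tol)
    hi = min(0.5, maf_target * (1 + maf_tol))
    band = np.flatnonzero((G.maf >= lo) & (G.maf <= hi))
    if band.size == 0:
        raise CapacityError(
            f"no SNPs with MAF in [{lo:.4g}, {hi:.4g}] (target {maf_target})"
        )
    rng = rng_for(seed, "causal-selection")
    Z = standardized_dosages(G)
    gene_order = rng.permutation(len(genes))
    sel_idx: list[int] = []
    entries: list[TruthEntry] = []
    used_genes: list[str] = []
    band_set = band
    for gi in gene_order:
        if len(entries) == n_causal:
            break
        row = genes.iloc[gi]
        lo_pos, hi_pos = row.tss - cis_window, row.tss + cis_window
        in_win = band_set[
            (G.positions[band_set] >= lo_pos) & (G.positions[band_set] <= hi_pos)
        ]
        cands = in_win[~np.isin(in_win, sel_idx)] if sel_idx else in_win
        if cands.size == 0:
            continue
        Zsel = Z[:, sel_idx] if sel_idx else np.empty((G.n_samples, 0))
        for c in rng.permutation(cands):
            if np.all(_r2_to_selected(Z[:, c], Zsel) <= prune_r2):
                sel_idx.append(int(c))
                used_genes.append(row.gene_id)
                entries.append(
                    TruthEntry(
                        gene_id=row.gene_id,
                        snp_ids=(G.snp_ids[c],),
                        betas=(1.0,),
                        coding=coding,
                    )
                )
                break
    if len(entries) < n_causal:
        raise CapacityError(
            f"could only place {len(entries)} of {n_causal} causal eSNPs at "
            f"MAF target {maf_target} (band [{lo:.4g}, {hi:.4g}], "
            f"prune r2 <= {prune_r2}); deficit {n_causal - len(entries)}"
        )
    if effect_draw is not None:
        betas = np.asarray(effect_draw(rng, n_causal), dtype=float)
        if np.any(betas <= 0):
            raise InvalidArgumentError("effect_draw must return positive betas")
        entries = [replace(e, betas=(float(b),)) for e, b in zip(entries, betas)]
    null_ids = [g for g in genes.gene_id if g not in set(used_genes)]
    return TruthAssignments(entries=entries, null_gene_ids=null_ids)
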