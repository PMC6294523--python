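"""Pooled and hierarchical multiple-testing correction for cis-eQTL scans.

Pooled correction applies one procedure (Bonferroni, BH, BY or the
Storey–Tibshirani q-value) across all SNP–gene tests at once.  Hierarchical
correction is the three-step procedure now standard for eGene detection:

* Step 1 (local): within each gene, nominal p-values of its cis SNPs are
  adjusted for the number of SNPs tested — with an FDR procedure, plain
  Bonferroni, an eigenMT-style Bonferroni on the effective number of
  independent tests, or a permutation scheme (exact, beta-approximated tail,
  or adaptive).
* Step 2 (global): the per-gene minimum locally adjusted p-value is adjusted
  across genes; genes at or below ``alpha`` are the significant eGenes.
* Step 3: significant eSNPs of each significant eGene are those whose
  locally adjusted p-value is at or below the largest per-gene minimum
  locally adjusted p-value among significant eGenes (the local threshold
  implied by the global 0.05 cut-off).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.stats import multitest

from ._rng import child_seed, rng_for
from .errors import DegenerateInputError, InvalidArgumentError
from .mapping import AssociationTable

logger = logging.getLogger(__name__)

__all__ = [
    "adjust_bonferroni",
    "adjust_bh",
    "adjust_by",
    "estimate_pi0",
    "adjust_st",
    "eigenmt_effective_tests",
    "permutation_local",
    "PermutationResult",
    "hierarchical_correct",
    "pooled_correct",
    "HierarchicalResult",
    "PooledResult",
    "LOCAL_METHODS",
    "GLOBAL_METHODS",
    "POOLED_METHODS",
]

LOCAL_METHODS = ("st", "bh", "by", "bonferroni", "eigenmt", "perm", "bperm", "aperm")
GLOBAL_METHODS = ("st", "bh", "by", "bonferroni")
POOLED_METHODS = ("st", "bh", "by", "bonferroni")


# ---------------------------------------------------------------------------
# Elementary procedures
# ---------------------------------------------------------------------------

def adjust_bonferroni(p, m: int | None = None) -> np.ndarray:
    """min(1, p*m); ``m`` defaults to len(p)."""
    p = np.asarray(p, dtype=float)
    if m is None:
        m = p.size
    if m <= 0:
        raise InvalidArgumentError("m must be positive")
    return np.minimum(1.0, p * m)


def adjust_bh(p) -> np.ndarray:
    """Benjamini–Hochberg step-up adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multitest.multipletests(p, method="fdr_bh")[1]


def adjust_by(p) -> np.ndarray:
    """Benjamini–Yekutieli adjusted p-values (harmonic-sum penalty)."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    return multitest.multipletests(p, method="fdr_by")[1]


def estimate_pi0(
    p,
    lambda_grid=None,
    floor: float = 1e-3,
    warn: bool = True,
) -> float:
    """Storey–Tibshirani estimate of the proportion of true nulls.

    pi0(lambda) = #{p > lambda} / (m (1 - lambda)) is computed over the grid
    (default 0.05, 0.10, ..., 0.90), smoothed with a cubic polynomial and
    evaluated at the largest lambda, then clipped to [floor, 1].
    """
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        raise InvalidArgumentError("cannot estimate pi0 from an empty vector")
    if lambda_grid is None:
        lambda_grid = np.arange(0.05, 0.9001, 0.05)
    lam = np.asarray(lambda_grid, dtype=float)
    if warn and p.size < 100:
        logger.warning("estimate_pi0: only %d p-values; estimate is unstable", p.size)
    pi0_lam = np.array([(p > l).mean() / (1.0 - l) for l in lam])
    if np.all(pi0_lam == 0):
        logger.warning("estimate_pi0: all p-values tiny; pi0 floored at %g", floor)
        return floor
    if lam.size >= 4:
        coef = np.polyfit(lam, pi0_lam, 3)
        pi0 = float(np.polyval(coef, lam.max()))
    else:
        pi0 = float(pi0_lam[-1])
    return float(np.clip(pi0, floor, 1.0))


def adjust_st(p, lambda_grid=None, warn: bool = True) -> np.ndarray:
    """Storey–Tibshirani q-values: pi0 times the BH adjusted p-values."""
    p = np.asarray(p, dtype=float)
    if p.size == 0:
        return p.copy()
    pi0 = estimate_pi0(p, lambda_grid=lambda_grid, warn=warn)
    return np.minimum(1.0, pi0 * adjust_bh(p))


_POOLED = {
    "bonferroni": lambda p: adjust_bonferroni(p),
    "bh": adjust_bh,
    "by": adjust_by,
    "st": adjust_st,
}


# ---------------------------------------------------------------------------
# eigenMT-style effective number of tests
# ---------------------------------------------------------------------------

def _meff_segment(Zseg: np.ndarray, var_explained: float) -> int:
    """Effective tests of one window of standardized dosage columns."""
    n, m = Zseg.shape
    C = Zseg.T @ Zseg / n
    ev = np.linalg.eigvalsh(C)[::-1]
    ev = np.maximum(ev, 0.0)
    total = ev.sum()
    if total <= 0:
        return 1
    k = int(np.searchsorted(np.cumsum(ev), var_explained * total) + 1)
    return min(k, m)


def eigenmt_effective_tests(
    G_cis, window_size: int = 200, var_explained: float = 0.99
) -> int:
    """Effective number of independent tests among a gene's cis SNPs.

    SNP columns are partitioned into consecutive windows of at most
    ``window_size``; within each window the dosage correlation matrix is
    eigendecomposed and the number of leading eigenvalues needed to reach
    ``var_explained`` of the total variance is counted.  The sum over
    windows, clipped to [1, m], is the effective test count.
    """
    X = np.asarray(getattr(G_cis, "dosages", G_cis), dtype=np.float64)
    if X.ndim != 2 or X.shape[1] == 0:
        raise InvalidArgumentError("G_cis must be a non-empty 2-D matrix")
    if not (0 < var_explained <= 1):
        raise InvalidArgumentError("var_explained must be in (0, 1]")
    sd = X.std(axis=0)
    ok = sd > 0
    if not np.any(ok):
        raise DegenerateInputError("all SNPs constant; effective tests undefined")
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    m = Z.shape[1]
    meff = 0
    for start in range(0, m, window_size):
        meff += _meff_segment(Z[:, start : start + window_size], var_explained)
    return int(np.clip(meff, 1, X.shape[1]))


class _MeffCache:
    """Grid-aligned cache of per-window effective test counts.

    Genes' cis windows overlap heavily, so full ``window_size`` blocks on a
    fixed genome-wide grid are eigendecomposed once and reused; only the two
    partial blocks at a gene's window edges are computed per gene.
    """

    def __init__(self, Z: np.ndarray, window_size: int, var_explained: float):
        self.Z = Z
        self.w = window_size
        self.ve = var_explained
        self._full: dict[int, int] = {}

    def _segment(self, a: int, b: int) -> int:
        if b <= a:
            return 0
        return _meff_segment(self.Z[:, a:b], self.ve)

    def meff(self, a: int, b: int) -> int:
        """Effective tests for standardized columns [a, b)."""
        if b <= a:
            return 1
        first_full = -(-a // self.w)  # ceil division
        last_full = b // self.w
        if first_full >= last_full:  # no full grid block inside
            return max(1, self._segment(a, b))
        total = self._segment(a, first_full * self.w)
        for blk in range(first_full, last_full):
            if blk not in self._full:
                self._full[blk] = self._segment(blk * self.w, (blk + 1) * self.w)
            total += self._full[blk]
        total += self._segment(last_full * self.w, b)
        return int(np.clip(total, 1, b - a))


# ---------------------------------------------------------------------------
# Permutation-based local correction
# ---------------------------------------------------------------------------

@dataclass
class PermutationResult:
    """Per-gene permutation p-value and, for beta schemes, the tail fit."""

    p_value: float
    scheme: str
    n_permutations: int
    beta_fit: tuple | None = None
    perm_min_p: np.ndarray | None = None
    obs_min_p: float = np.nan

    def nominal_threshold(self, local_p: float) -> float:
        """Nominal p-value whose permutation p equals ``local_p``."""
        if self.scheme == "exact":
            q = np.quantile(self.perm_min_p, min(local_p, 1.0))
            return float(q)
        a, b = self.beta_fit
        return float(stats.beta.ppf(min(local_p, 1.0), a, b))


def _min_p_of_perms(Y: np.ndarray, Z: np.ndarray, df: int) -> np.ndarray:
    """Minimum nominal p over SNPs for each row of standardized Y."""
    n = Z.shape[0]
    R = np.abs(Y @ Z) / n
    rmax = np.clip(R.max(axis=1), 0, 1 - 1e-15)
    t = rmax * np.sqrt(df) / np.sqrt(1 - rmax**2)
    return 2.0 * stats.t.sf(t, df)


def _fit_beta_mle(x: np.ndarray, floor: float = 1e-6) -> tuple:
    """Two-parameter beta MLE on (0,1) data (location 0, scale 1)."""
    x = np.clip(x, 1e-300, 1 - 1e-16)
    a, b, _, _ = stats.beta.fit(x, floc=0, fscale=1)
    return max(float(a), floor), max(float(b), floor)


def permutation_local(
    E_gene,
    G_cis,
    scheme: str = "beta",
    B: int = 1000,
    seed: int = 0,
    batch_size: int = 100,
    target_hits: int = 15,
    b_max: int = 10000,
) -> PermutationResult:
    """Permutation p-value for a gene's strongest cis association.

    Sample labels of the expression vector are shuffled; the minimum nominal
    p-value across cis SNPs at each permutation forms the empirical null.

    * ``exact``: p = (r + 1) / (B + 1) with r the number of permuted minima
      at or below the observed minimum.
    * ``beta``: a Beta(k, n) distribution is fitted by maximum likelihood to
      the permuted minima; p is its CDF at the observed minimum.
    * ``adaptive``: permutes in batches of ``batch_size`` until
      ``target_hits`` permuted minima beat the observed one (or ``b_max`` is
      reached), then beta-fits.
    """
    if scheme not in ("exact", "beta", "adaptive"):
        raise InvalidArgumentError(f"unknown permutation scheme: {scheme!r}")
    if B < 100:
        raise InvalidArgumentError("B must be >= 100")
    y = np.asarray(E_gene, dtype=float)
    if np.ptp(y) == 0:
        raise DegenerateInputError("constant expression; permutation undefined")
    X = np.asarray(getattr(G_cis, "dosages", G_cis), dtype=np.float64)
    sd = X.std(axis=0)
    ok = sd > 0
    if not np.any(ok):
        raise DegenerateInputError("all cis SNPs constant")
    Z = (X[:, ok] - X[:, ok].mean(axis=0)) / sd[ok]
    n = len(y)
    df = n - 2
    yz = (y - y.mean()) / y.std()
    obs = float(_min_p_of_perms(yz[None, :], Z, df)[0])
    rng = rng_for(seed, "permutation")

    def perm_block(k: int) -> np.ndarray:
        P = np.stack([yz[rng.permutation(n)] for _ in range(k)])
        return _min_p_of_perms(P, Z, df)

    if scheme in ("exact", "beta"):
        minima = perm_block(B)
    else:
        pieces, hits, total = [], 0, 0
        while total < b_max:
            k = min(batch_size, b_max - total)
            blk = perm_block(k)
            pieces.append(blk)
            total += k
            hits += int((blk <= obs).sum())
            if hits >= target_hits and total >= 100:
                break
        minima = np.concatenate(pieces)

    if scheme == "exact":
        r = int((minima <= obs).sum())
        return PermutationResult(
            p_value=(r + 1) / (len(minima) + 1),
            scheme="exact",
            n_permutations=len(minima),
            perm_min_p=minima,
            obs_min_p=obs,
        )
    a, b = _fit_beta_mle(minima)
    return PermutationResult(
        p_value=float(np.clip(stats.beta.cdf(obs, a, b), 1e-300, 1.0)),
        scheme=scheme,
        n_permutations=len(minima),
        beta_fit=(a, b),
        perm_min_p=minima,
        obs_min_p=obs,
    )


# ---------------------------------------------------------------------------
# Hierarchical and pooled drivers
# ---------------------------------------------------------------------------

@dataclass
class HierarchicalResult:
    """Output of the three-step hierarchical correction."""

    gene_ids: list
    local_min_p: np.ndarray  # per-gene minimum locally adjusted p (Step 1-2 input)
    global_p: np.ndarray  # per-gene globally adjusted p
    local_method: str
    global_method: str
    alpha: float
    esnp_threshold: float | None  # Step-3 local threshold (None if no eGene)
    egenes: list = field(default_factory=list)
    _esnps: dict = field(default_factory=dict)  # gene_id -> (snp_idx, local_adj_p)
    local_scale: np.ndarray | None = None  # per-gene Bonferroni/eigenMT multiplier
    snp_ids: np.ndarray | None = None

    def esnp_idx_for(self, gene_id: str) -> np.ndarray:
        return self._esnps.get(gene_id, (np.zeros(0, dtype=np.int64),) * 2)[0]

    def esnps_for(self, gene_id: str) -> np.ndarray:
        return self.snp_ids[self.esnp_idx_for(gene_id)]

    def scale_for(self, gene_id: str) -> float:
        k = self.gene_ids.index(gene_id)
        return float(self.local_scale[k])

    def to_frame(self) -> pd.DataFrame:
        sig = set(self.egenes)
        return pd.DataFrame(
            {
                "gene_id": self.gene_ids,
                "local_min_p_adj": self.local_min_p,
                "global_p_adj": self.global_p,
                "significant": [g in sig for g in self.gene_ids],
            }
        )

    def esnp_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.egenes:
            idx, padj = self._esnps[g]
            for i, pa in zip(idx, padj):
                rows.append((g, self.snp_ids[i], pa))
        return pd.DataFrame(rows, columns=["gene_id", "snp_id", "local_p_adj"])


@dataclass
class PooledResult:
    """Significant (gene, SNP) pairs from a pooled correction."""

    gene_ids: list
    method: str
    alpha: float
    egenes: list
    _esnps: dict  # gene_id -> (snp_idx, adjusted p)
    snp_ids: np.ndarray

    def esnp_idx_for(self, gene_id: str) -> np.ndarray:
        return self._esnps.get(gene_id, (np.zeros(0, dtype=np.int64),) * 2)[0]

    def esnps_for(self, gene_id: str) -> np.ndarray:
        return self.snp_ids[self.esnp_idx_for(gene_id)]

    def pair_frame(self) -> pd.DataFrame:
        rows = []
        for g in self.egenes:
            idx, padj = self._esnps[g]
            for i, pa in zip(idx, padj):
                rows.append((g, self.snp_ids[i], pa))
        return pd.DataFrame(rows, columns=["gene_id", "snp_id", "p_adj"])


_LOCAL_VECTOR = {"st": adjust_st, "bh": adjust_bh, "by": adjust_by}
_PERM_SCHEME = {"perm": "exact", "bperm": "beta", "aperm": "adaptive"}


def hierarchical_correct(
    assoc: AssociationTable,
    local_method: str = "eigenmt",
    global_method: str = "bh",
    alpha: float = 0.05,
    G=None,
    E=None,
    eigenmt_window: int = 200,
    eigenmt_var_explained: float = 0.99,
    perm_B: int = 1000,
    perm_b_max: int = 10000,
    seed: int = 0,
) -> HierarchicalResult:
    """Run the three-step hierarchical multiple-testing correction.

    ``G`` (a GenotypeMatrix) is required for eigenMT and permutation local
    methods; ``E`` (an ExpressionMatrix) for permutation methods.
    """
    if local_method not in LOCAL_METHODS:
        raise InvalidArgumentError(f"unknown local method: {local_method!r}")
    if global_method not in GLOBAL_METHODS:
        raise InvalidArgumentError(f"unknown global method: {global_method!r}")
    if assoc.n_genes == 0 or assoc.n_records == 0:
        raise InvalidArgumentError("association table is empty")

    nG = assoc.n_genes
    local_min = np.full(nG, np.nan)
    local_scale = np.full(nG, np.nan)
    local_adj_chunks: dict[int, np.ndarray] = {}
    perm_results: dict[int, PermutationResult] = {}

    cache = None
    valid_cols = None
    if local_method == "eigenmt":
        if G is None:
            raise InvalidArgumentError("eigenmt local correction needs G")
        X = G.dosages.astype(np.float64)
        sd = X.std(axis=0)
        valid = sd > 0
        valid_cols = np.flatnonzero(valid)
        Z = (X[:, valid] - X[:, valid].mean(axis=0)) / sd[valid]
        cache = _MeffCache(Z, eigenmt_window, eigenmt_var_explained)
    if local_method in _PERM_SCHEME and (G is None or E is None):
        raise InvalidArgumentError("permutation local correction needs G and E")

    for k in range(nG):
        sl = assoc.gene_slice(k)
        if sl.stop == sl.start:
            continue
        p = assoc.p_nominal[sl]
        if local_method in _LOCAL_VECTOR:
            adj = _LOCAL_VECTOR[local_method](p) if local_method != "st" else adjust_st(
                p, warn=False
            )
            local_adj_chunks[k] = adj
            local_min[k] = adj.min()
        elif local_method == "bonferroni":
            m = sl.stop - sl.start
            adj = np.minimum(1.0, p * m)
            local_adj_chunks[k] = adj
            local_min[k] = adj.min()
            local_scale[k] = m
        elif local_method == "eigenmt":
            lo, hi = assoc.gene_windows[k]
            a = int(np.searchsorted(valid_cols, lo, side="left"))
            b = int(np.searchsorted(valid_cols, hi, side="left"))
            meff = cache.meff(a, b)
            adj = np.minimum(1.0, p * meff)
            local_adj_chunks[k] = adj
            local_min[k] = adj.min()
            local_scale[k] = meff
        else:  # permutation
            scheme = _PERM_SCHEME[local_method]
            cols = assoc.snp_idx[sl]
            res = permutation_local(
                E.row(assoc.gene_ids[k]),
                G.dosages[:, cols],
                scheme=scheme,
                B=perm_B,
                b_max=perm_b_max,
                seed=child_seed(seed, "perm-gene", k),
            )
            perm_results[k] = res
            local_min[k] = res.p_value

    tested = np.flatnonzero(~np.isnan(local_min))
    if tested.size == 0:
        raise InvalidArgumentError("no gene has testable cis SNPs")
    if global_method == "bonferroni":
        global_tested = adjust_bonferroni(local_min[tested])
    else:
        global_tested = _POOLED[global_method](local_min[tested])
    global_p = np.full(nG, np.nan)
    global_p[tested] = global_tested

    sig_rows = tested[global_tested <= alpha]
    egenes = [assoc.gene_ids[k] for k in sig_rows]
    threshold = float(local_min[sig_rows].max()) if sig_rows.size else None

    esnps: dict = {}
    slack = 1.0 + 1e-9  # float rounding of the threshold-defining gene
    for k in sig_rows:
        sl = assoc.gene_slice(k)
        cols = assoc.snp_idx[sl]
        p_gene = assoc.p_nominal[sl]
        if k in perm_results:
            p_thr = perm_results[k].nominal_threshold(threshold)
            # the top SNP made the gene significant; keep it regardless of
            # beta CDF/PPF round-trip rounding
            mask = (p_gene <= p_thr * slack) | (p_gene == p_gene.min())
            padj = p_gene[mask]  # nominal scale for perm methods
        else:
            adj = local_adj_chunks[k]
            mask = adj <= threshold * slack
            padj = adj[mask]
        esnps[assoc.gene_ids[k]] = (cols[mask].astype(np.int64), padj)

    return HierarchicalResult(
        gene_ids=list(assoc.gene_ids),
        local_min_p=local_min,
        global_p=global_p,
        local_method=local_method,
        global_method=global_method,
        alpha=alpha,
        esnp_threshold=threshold,
        egenes=egenes,
        _esnps=esnps,
        local_scale=local_scale,
        snp_ids=assoc.snp_ids,
    )


def pooled_correct(
    assoc: AssociationTable, method: str = "bh", alpha: float = 0.05
) -> PooledResult:
    """Apply one correction across all SNP–gene tests at once."""
    if method not in POOLED_METHODS:
        raise InvalidArgumentError(f"unknown pooled method: {method!r}")
    adj = _POOLED[method](assoc.p_nominal)
    sig = adj <= alpha
    esnps: dict = {}
    egenes: list = []
    for k in range(assoc.n_genes):
        sl = assoc.gene_slice(k)
        mask = sig[sl]
        if mask.any():
            g = assoc.gene_ids[k]
            egenes.append(g)
            esnps[g] = (assoc.snp_idx[sl][mask].astype(np.int64), adj[sl][mask])
    return PooledResult(
        gene_ids=list(assoc.gene_ids),
        method=method,
        alpha=alpha,
        egenes=egenes,
        _esnps=esnps,
        snp_ids=assoc.snp_ids,
    )
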