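"""Matrix-style cis-eQTL mapping.

Every gene is regressed on the minor-allele dosage of every SNP within
±1 Mb (inclusive) of its TSS with a simple linear model (intercept + dosage,
df = n - 2).  The engine standardizes expression and dosage once and obtains
all slopes, standard errors, t statistics and two-sided p-values from the
gene-SNP correlations, which is algebraically identical to per-pair OLS.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import stats

from .errors import AlignmentError, InvalidArgumentError
from .expression import ExpressionMatrix
from .genotypes import GenotypeMatrix

logger = logging.getLogger(__name__)

__all__ = ["AssociationTable", "map_cis"]


@dataclass
class AssociationTable:
    """Per (gene, SNP) cis association statistics in compressed row layout.

    Records of gene ``k`` occupy ``slice(indptr[k], indptr[k+1])`` of the
    flat arrays.  ``snp_idx`` indexes into the genotype matrix the table was
    computed from; ``gene_windows`` stores the [start, stop) SNP-column range
    of each gene's cis window (before zero-variance exclusion).
    """

    gene_ids: list
    indptr: np.ndarray
    snp_idx: np.ndarray
    beta: np.ndarray
    se: np.ndarray
    t_stat: np.ndarray
    p_nominal: np.ndarray
    distance_to_tss: np.ndarray
    snp_ids: np.ndarray
    positions: np.ndarray
    gene_windows: np.ndarray
    n_samples: int

    @property
    def n_genes(self) -> int:
        return len(self.gene_ids)

    @property
    def n_records(self) -> int:
        return len(self.snp_idx)

    def gene_slice(self, k: int) -> slice:
        return slice(int(self.indptr[k]), int(self.indptr[k + 1]))

    def gene_row(self, gene_id: str) -> int:
        try:
            return self._row[gene_id]
        except AttributeError:
            self._row = {g: i for i, g in enumerate(self.gene_ids)}
            return self.gene_row(gene_id)
        except KeyError:
            raise InvalidArgumentError(f"gene {gene_id!r} not in table") from None

    def top_association(self, gene_id: str):
        """(snp_id, record dict) with minimum nominal p; ties resolved by
        lowest base-pair position."""
        k = self.gene_row(gene_id)
        sl = self.gene_slice(k)
        if sl.stop == sl.start:
            raise InvalidArgumentError(f"gene {gene_id!r} has no cis records")
        p = self.p_nominal[sl]
        pos = self.positions[self.snp_idx[sl]]
        cand = np.flatnonzero(p == p.min())
        best = sl.start + cand[np.argmin(pos[cand])]
        snp = self.snp_ids[self.snp_idx[best]]
        rec = {
            "gene_id": gene_id,
            "snp_id": snp,
            "beta": float(self.beta[best]),
            "se": float(self.se[best]),
            "t_stat": float(self.t_stat[best]),
            "p_nominal": float(self.p_nominal[best]),
            "distance_to_tss": int(self.distance_to_tss[best]),
        }
        return snp, rec

    def to_frame(self) -> pd.DataFrame:
        reps = np.diff(self.indptr)
        return pd.DataFrame(
            {
                "gene_id": np.repeat(np.asarray(self.gene_ids, dtype=object), reps),
                "snp_id": self.snp_ids[self.snp_idx],
                "beta": self.beta,
                "se": self.se,
                "t_stat": self.t_stat,
                "p_nominal": self.p_nominal,
                "distance_to_tss": self.distance_to_tss,
            }
        )


def map_cis(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    genes: pd.DataFrame,
    window: int = 1_000_000,
    covariates: np.ndarray | None = None,
    min_p: float = 1e-300,
) -> AssociationTable:
    """Regress each gene on every SNP within ``window`` bp of its TSS.

    ``covariates`` (samples x k) are projected out of both expression and
    dosages before the scan (equivalent to including them in the model);
    the residual degrees of freedom become n - 2 - k.  Zero-variance SNPs
    are skipped (the test is undefined), genes without in-window SNPs yield
    zero records; both are logged.  SNPs exactly at the window edge are
    included (inclusive convention).
    """
    if window <= 0:
        raise InvalidArgumentError("window must be positive")
    if E.n_samples != G.n_samples:
        raise AlignmentError(
            f"expression has {E.n_samples} samples, genotypes {G.n_samples}"
        )
    missing = [g for g in genes.gene_id if g not in E._row]
    if missing:
        raise AlignmentError(f"genes missing from expression matrix: {missing[:5]}")
    n = G.n_samples
    n_cov = 0
    X = G.dosages.astype(np.float64)
    Ymat = np.stack([E.row(g) for g in genes.gene_id])
    if covariates is not None:
        C = np.atleast_2d(np.asarray(covariates, dtype=float))
        if C.shape[0] != n:
            raise AlignmentError("covariate rows must match the sample count")
        n_cov = C.shape[1]
        D = np.column_stack([np.ones(n), C])
        coef_x, *_ = np.linalg.lstsq(D, X, rcond=None)
        X = X - D @ coef_x
        coef_y, *_ = np.linalg.lstsq(D, Ymat.T, rcond=None)
        Ymat = (Ymat.T - D @ coef_y).T
    if n - 2 - n_cov < 1:
        raise InvalidArgumentError("need n - 2 - k >= 1 residual df")

    sx = X.std(axis=0)
    ok = sx > 1e-12
    n_bad = int((~ok).sum())
    if n_bad:
        logger.warning("map_cis: skipping %d zero-variance SNPs", n_bad)
    Xz = np.where(ok, (X - X.mean(axis=0)) / np.where(ok, sx, 1.0), 0.0)

    sy = Ymat.std(axis=1)
    Yz = (Ymat - Ymat.mean(axis=1, keepdims=True)) / np.where(sy > 0, sy, 1.0)[:, None]

    df = n - 2 - n_cov
    gene_ids = list(genes.gene_id)
    tss = genes.tss.to_numpy()
    lo = np.searchsorted(G.positions, tss - window, side="left")
    hi = np.searchsorted(G.positions, tss + window, side="right")

    chunks_idx, chunks_r, chunks_dist = [], [], []
    counts = np.zeros(len(gene_ids), dtype=np.int64)
    for k in range(len(gene_ids)):
        cols = np.arange(lo[k], hi[k])
        cols = cols[ok[cols]]
        if cols.size == 0:
            logger.warning("map_cis: gene %s has no testable cis SNPs", gene_ids[k])
            continue
        r = Xz[:, cols].T @ Yz[k] / n
        chunks_idx.append(cols.astype(np.int32))
        chunks_r.append(r)
        chunks_dist.append(G.positions[cols] - tss[k])
        counts[k] = cols.size

    if chunks_idx:
        snp_idx = np.concatenate(chunks_idx)
        r = np.concatenate(chunks_r)
        dist = np.concatenate(chunks_dist)
    else:
        snp_idx = np.zeros(0, dtype=np.int32)
        r = np.zeros(0)
        dist = np.zeros(0, dtype=np.int64)
    r = np.clip(r, -1.0, 1.0)
    with np.errstate(divide="ignore"):
        denom = np.sqrt(np.maximum(1.0 - r * r, 1e-300))
        t = r * np.sqrt(df) / denom
    p = np.maximum(2.0 * stats.t.sf(np.abs(t), df), min_p)

    gene_rows = np.repeat(np.arange(len(gene_ids)), counts)
    ratio = np.repeat(sy, counts) / sx[snp_idx]
    beta = r * ratio
    with np.errstate(divide="ignore", invalid="ignore"):
        se = np.where(t != 0, beta / t, ratio * denom / np.sqrt(df))
    se = np.abs(se)

    indptr = np.zeros(len(gene_ids) + 1, dtype=np.int64)
    np.cumsum(counts, out=indptr[1:])
    assert len(gene_rows) == indptr[-1]
    return AssociationTable(
        gene_ids=gene_ids,
        indptr=indptr,
        snp_idx=snp_idx,
        beta=beta,
        se=se,
        t_stat=t,
        p_nominal=p,
        distance_to_tss=dist,
        snp_ids=G.snp_ids,
        positions=G.positions,
        gene_windows=np.stack([lo, hi], axis=1),
        n_samples=n,
    )
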