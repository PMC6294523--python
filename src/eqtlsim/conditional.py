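"""Two-stage (forward/backward) conditional analysis of significant eGenes.

For each significant eGene the forward stage iteratively re-maps its cis
SNPs while conditioning on the accumulated sentinel SNPs (starting from the
top SNP of the initial scan) and adds the new top SNP while any conditional
p-value stays below the gene's nominal significance threshold.  The backward
stage re-tests every sentinel in a leave-one-out model conditioning on all
the others; sentinels that stay significant form the final set of
independent eQTL signals.

The nominal threshold is the one implied by the hierarchical correction of
the initial scan: the Step-3 locally adjusted threshold divided by the
gene's local multiplier (number of cis SNPs for Bonferroni, effective test
count for eigenMT).

Conditioning is implemented by residualizing both expression and candidate
dosages on the sentinel dosages (plus intercept), which is equivalent to
including the sentinels as covariates in the regression; degrees of freedom
are reduced accordingly.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .correction import HierarchicalResult
from .errors import InvalidArgumentError
from .expression import ExpressionMatrix
from .genotypes import GenotypeMatrix
from .mapping import AssociationTable

logger = logging.getLogger(__name__)

__all__ = ["Signal", "IndependentSignalSet", "run_conditional"]


@dataclass(frozen=True)
class Signal:
    snp_id: str
    beta: float
    p_value: float
    rank: int
    stage_survived: str = "backward"


@dataclass
class IndependentSignalSet:
    """Per-eGene ordered sentinel SNPs with conditional statistics."""

    signals: dict = field(default_factory=dict)  # gene_id -> list[Signal]
    nominal_thresholds: dict = field(default_factory=dict)

    def sentinels_for(self, gene_id: str) -> list:
        return [s.snp_id for s in self.signals.get(gene_id, [])]

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for g, sigs in self.signals.items():
            for s in sigs:
                rows.append(
                    (g, s.rank, s.snp_id, s.beta, s.p_value, s.stage_survived)
                )
        return pd.DataFrame(
            rows,
            columns=[
                "gene_id",
                "rank",
                "snp_id",
                "conditional_beta",
                "conditional_p",
                "stage_survived",
            ],
        )


def _residualize(M: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of the columns of M on [1, C] via least squares."""
    n = M.shape[0]
    D = np.column_stack([np.ones(n), C])
    coef, *_ = np.linalg.lstsq(D, M, rcond=None)
    return M - D @ coef


def _conditional_scan(
    y: np.ndarray, Xc: np.ndarray, C: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Slopes and p-values of y ~ x + C for each column x of Xc."""
    n = len(y)
    k = C.shape[1]
    df = n - 2 - k
    if df < 1:
        raise InvalidArgumentError("not enough samples for conditional model")
    yr = _residualize(y[:, None], C)[:, 0]
    Xr = _residualize(Xc, C)
    sx = Xr.std(axis=0)
    sy = yr.std()
    good = (sx > 1e-12) & (sy > 0)
    r = np.zeros(Xc.shape[1])
    if sy > 0:
        r[good] = (Xr[:, good].T @ yr) / (n * sx[good] * sy)
    r = np.clip(r, -1, 1)
    with np.errstate(divide="ignore", invalid="ignore"):
        t = r * np.sqrt(df) / np.sqrt(np.maximum(1 - r * r, 1e-300))
        beta = np.where(sx > 1e-12, r * sy / np.where(sx > 1e-12, sx, 1.0), 0.0)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~good] = 1.0
    return beta, p


def run_conditional(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    hier: HierarchicalResult,
    assoc: AssociationTable,
    max_iterations: int = 10,
) -> IndependentSignalSet:
    """Identify independent eQTL signals for every significant eGene."""
    if not hier.egenes:
        raise InvalidArgumentError("hierarchical result has no significant eGenes")
    if hier.esnp_threshold is None or hier.local_scale is None or np.all(
        np.isnan(hier.local_scale)
    ):
        raise InvalidArgumentError(
            "conditional analysis needs a Bonferroni or eigenMT local correction"
        )
    out = IndependentSignalSet()
    for gene in hier.egenes:
        k = assoc.gene_row(gene)
        sl = assoc.gene_slice(k)
        cols = assoc.snp_idx[sl]
        scale = hier.scale_for(gene)
        if np.isnan(scale):
            raise InvalidArgumentError(
                f"gene {gene!r} lacks a local multiplier for the nominal threshold"
            )
        thr = min(1.0, hier.esnp_threshold / scale)
        out.nominal_thresholds[gene] = thr
        # tiny relative slack so the threshold-defining gene's own top SNP
        # (whose p equals the threshold up to rounding) is retained
        thr_eff = thr * (1.0 + 1e-9)
        y = E.row(gene).astype(float)
        Xc = G.dosages[:, cols].astype(float)

        top_snp, _ = assoc.top_association(gene)
        sentinels = [int(np.flatnonzero(assoc.snp_ids[cols] == top_snp)[0])]
        # forward stage
        for _ in range(max_iterations - 1):
            C = Xc[:, sentinels]
            _, p = _conditional_scan(y, Xc, C)
            p[sentinels] = 1.0
            j = int(np.argmin(p))
            if p[j] > thr_eff:
                break
            sentinels.append(j)
        # drop collinear sentinels (later-added first)
        keep: list[int] = []
        for s in sentinels:
            if keep:
                Xr = _residualize(Xc[:, [s]], Xc[:, keep])
                if Xr.std() < 1e-8:
                    logger.warning(
                        "dropping collinear sentinel %s for gene %s",
                        assoc.snp_ids[cols[s]],
                        gene,
                    )
                    continue
            keep.append(s)
        sentinels = keep
        # backward stage: leave-one-out re-test
        survivors = []
        for rank, s in enumerate(sentinels):
            others = [o for o in sentinels if o != s]
            if others:
                beta, p = _conditional_scan(y, Xc[:, [s]], Xc[:, others])
                b, pv = float(beta[0]), float(p[0])
            else:
                beta, p = _conditional_scan(
                    y, Xc[:, [s]], np.empty((len(y), 0))
                )
                b, pv = float(beta[0]), float(p[0])
            if pv <= thr_eff:
                survivors.append(
                    Signal(
                        snp_id=str(assoc.snp_ids[cols[s]]),
                        beta=b,
                        p_value=pv,
                        rank=rank + 1,
                    )
                )
        out.signals[gene] = survivors
    return out
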