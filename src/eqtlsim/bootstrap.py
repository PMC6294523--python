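"""Winner's-Curse correction of eQTL effect sizes by bootstrap resampling.

Effect sizes of significant eGenes, estimated at their top eSNP in the
discovery data (the naive estimator), are biased away from zero because the
same data were used for detection and estimation.  The bootstrap correction
re-partitions the study repeatedly into a *detection group* (n samples drawn
with replacement — on average 63.2% unique samples) and an *estimation
group* (the out-of-bag remainder).  A bootstrap counts toward gene ``e``'s
total ``B_e`` when the gene-top-eSNP association is significant in the
detection group at the original analysis' locally adjusted threshold.  Over
the counted bootstraps three estimators are formed from the detection-group
slope ``beta_D`` and estimation-group slope ``beta_E``:

* shrinkage:     beta_naive - mean(beta_D - beta_E)
* out-of-sample: mean(beta_E)
* weighted:      (1 - w) * beta_naive + w * mean(beta_E),  w = 0.632

The top eSNP is fixed from the original full-sample analysis and only
re-estimated (never re-discovered) inside bootstraps.
"""

from __future__ import annotations

import logging

import numpy as np
import pandas as pd
from scipy import stats

from ._rng import rng_for
from .correction import HierarchicalResult
from .errors import InvalidArgumentError
from .expression import ExpressionMatrix
from .genotypes import GenotypeMatrix
from .mapping import AssociationTable

logger = logging.getLogger(__name__)

__all__ = [
    "expected_unique_fraction",
    "combine_bootstrap_estimates",
    "bootstrap_correct",
    "DEFAULT_OMEGA",
]

DEFAULT_OMEGA = 0.632


def expected_unique_fraction(n: int, B: int = 1000, seed: int = 0) -> float:
    """Mean fraction of unique samples in an n-out-of-n bootstrap resample.

    Converges to 1 - (1 - 1/n)^n (about 0.632 for large n).
    """
    if n < 1:
        raise InvalidArgumentError("n must be >= 1")
    if n == 1:
        return 1.0
    rng = rng_for(seed, "unique-fraction")
    fracs = np.empty(B)
    for b in range(B):
        fracs[b] = np.unique(rng.integers(0, n, size=n)).size / n
    return float(fracs.mean())


def combine_bootstrap_estimates(
    beta_naive: float,
    beta_det: np.ndarray,
    beta_est: np.ndarray,
    omega: float = DEFAULT_OMEGA,
) -> dict:
    """The three Winner's-Curse estimators from counted-bootstrap slopes."""
    beta_det = np.asarray(beta_det, dtype=float)
    beta_est = np.asarray(beta_est, dtype=float)
    if beta_det.shape != beta_est.shape:
        raise InvalidArgumentError("beta_det and beta_est must align")
    B_e = beta_det.size
    if B_e == 0:
        return {
            "beta_shrinkage": np.nan,
            "beta_oos": np.nan,
            "beta_weighted": np.nan,
            "B_e": 0,
            "correction_defined": False,
        }
    oos = float(beta_est.mean())
    return {
        "beta_shrinkage": float(beta_naive - (beta_det - beta_est).mean()),
        "beta_oos": oos,
        "beta_weighted": float((1 - omega) * beta_naive + omega * oos),
        "B_e": int(B_e),
        "correction_defined": True,
    }


def _slopes_and_p(Y: np.ndarray, X: np.ndarray, with_p: bool):
    """Row-wise slope (and p) of Y[g] ~ X[g] with intercept."""
    n = Y.shape[1]
    Xc = X - X.mean(axis=1, keepdims=True)
    Yc = Y - Y.mean(axis=1, keepdims=True)
    sxx = (Xc * Xc).sum(axis=1)
    sxy = (Xc * Yc).sum(axis=1)
    good = sxx > 0
    beta = np.where(good, sxy / np.where(good, sxx, 1.0), np.nan)
    if not with_p:
        return beta, None
    df = n - 2
    syy = (Yc * Yc).sum(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        rss = syy - beta * sxy
        se = np.sqrt(np.maximum(rss, 0) / (df * np.where(good, sxx, 1.0)))
        t = np.where(se > 0, beta / se, np.inf)
    p = 2.0 * stats.t.sf(np.abs(t), df)
    p[~good] = 1.0
    return beta, p


def bootstrap_correct(
    E: ExpressionMatrix,
    G: GenotypeMatrix,
    hier: HierarchicalResult,
    assoc: AssociationTable,
    B_total: int = 200,
    omega: float = DEFAULT_OMEGA,
    seed: int = 0,
) -> pd.DataFrame:
    """Winner's-Curse-corrected effect sizes for all significant eGenes.

    Requires a hierarchical result whose local correction provides a
    per-gene multiplier (Bonferroni by default; eigenMT also works): in each
    bootstrap the detection-group nominal p of the fixed top eSNP times the
    gene's multiplier is compared with the original Step-3 locally adjusted
    threshold.
    """
    if not hier.egenes:
        raise InvalidArgumentError("no significant eGenes to correct")
    if hier.esnp_threshold is None or hier.local_scale is None or np.all(
        np.isnan(hier.local_scale)
    ):
        raise InvalidArgumentError(
            "bootstrap gate needs a Bonferroni or eigenMT local correction"
        )
    genes = list(hier.egenes)
    n = G.n_samples
    top_idx = np.empty(len(genes), dtype=np.int64)
    naive = np.empty(len(genes))
    scales = np.empty(len(genes))
    Yfull = np.empty((len(genes), n))
    for i, g in enumerate(genes):
        snp, rec = assoc.top_association(g)
        top_idx[i] = G.snp_index(snp)
        naive[i] = rec["beta"]
        scales[i] = hier.scale_for(g)
        Yfull[i] = E.row(g)
    Xfull = G.dosages[:, top_idx].astype(float).T  # (genes, samples)
    thr = hier.esnp_threshold

    sum_det = np.zeros(len(genes))
    sum_est = np.zeros(len(genes))
    counts = np.zeros(len(genes), dtype=np.int64)
    skipped = 0
    for b in range(B_total):
        rng = rng_for(seed, "bootstrap", b)  # per-bootstrap substream
        det = rng.integers(0, n, size=n)
        in_det = np.zeros(n, dtype=bool)
        in_det[det] = True
        est = np.flatnonzero(~in_det)
        if est.size < 3:
            skipped += 1
            logger.warning("bootstrap %d: estimation group too small; skipped", b)
            continue
        beta_d, p_d = _slopes_and_p(Yfull[:, det], Xfull[:, det], with_p=True)
        beta_e, _ = _slopes_and_p(Yfull[:, est], Xfull[:, est], with_p=False)
        counted = (
            (np.minimum(1.0, p_d * scales) < thr)
            & np.isfinite(beta_d)
            & np.isfinite(beta_e)
        )
        sum_det[counted] += beta_d[counted]
        sum_est[counted] += beta_e[counted]
        counts[counted] += 1
    if skipped:
        logger.warning("bootstrap_correct: skipped %d degenerate bootstraps", skipped)

    rows = []
    for i, g in enumerate(genes):
        if counts[i] > 0:
            mean_d = sum_det[i] / counts[i]
            mean_e = sum_est[i] / counts[i]
            shrink = naive[i] - (mean_d - mean_e)
            weighted = (1 - omega) * naive[i] + omega * mean_e
            defined = True
        else:
            mean_e = shrink = weighted = np.nan
            defined = False
        rows.append(
            (
                g,
                str(G.snp_ids[top_idx[i]]),
                naive[i],
                shrink,
                mean_e,
                weighted,
                int(counts[i]),
                defined,
            )
        )
    return pd.DataFrame(
        rows,
        columns=[
            "gene_id",
            "top_snp_id",
            "beta_naive",
            "beta_shrinkage",
            "beta_oos",
            "beta_weighted",
            "B_e",
            "correction_defined",
        ],
    )
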