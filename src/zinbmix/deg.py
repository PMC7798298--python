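"""Soft-weighted differential expression between two clusters.

Each cell contributes to a cluster's gene-level moments in proportion to
its cluster posterior ``w_{c,k} = p(k | x_c)``; an observed zero further
contributes in proportion to the probability ``v_{c,g,k}`` that it came
from an expressed (negative binomial) component rather than dropout:

    m_{g,k} = sum_{x>0} w x / (sum_{x>0} w + sum_{x==0} w v)

The second moment uses the same weights and denominator, the variance is
E(x^2) - E(x)^2, and cluster means are compared by a Wald z statistic
with standard error sqrt(var_A / n_A + var_B / n_B) where n is the moment
denominator (effective sample size).  P-values are Benjamini-Hochberg
adjusted.  With one-hot posteriors the pipeline reduces to ordinary
per-cluster weighted statistics.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm

from .em_fit import FitResult, e_step
from .model_core import CellScalers, CountMatrix, compute_cell_scalers

logger = logging.getLogger(__name__)

DEG_COLUMNS = [
    "gene_id", "m_k1", "m_k2", "var_k1", "var_k2",
    "n_eff_k1", "n_eff_k2", "wald_z", "p_value", "p_adjusted",
]


@dataclass
class ClusterMoments:
    """Per-gene conditional moments of expressed counts in one cluster."""

    m: np.ndarray
    second_moment: np.ndarray
    var: np.ndarray
    n_eff: np.ndarray
    defined: np.ndarray  # False where the denominator vanished

    def __post_init__(self):
        for name in ("m", "second_moment", "var", "n_eff"):
            setattr(self, name, np.asarray(getattr(self, name), dtype=float))
        self.defined = np.asarray(self.defined, dtype=bool)


def expression_moments(
    counts: CountMatrix,
    gamma: np.ndarray,
    comp_post: np.ndarray,
    k: int,
) -> ClusterMoments:
    """Weighted conditional mean/variance of expressed counts in cluster k.

    ``comp_post`` is the (C, G, K, L) component posterior from the E-step;
    its dropout slice defines ``v = 1 - p(l=0 | k, x)``.  ``comp_post``
    may be None for a model without a dropout component (v = 1).
    """
    x = counts.counts.astype(float)
    C, G = x.shape
    gamma = np.asarray(gamma)
    if gamma.shape[0] != C:
        raise ValueError("gamma does not match counts")
    if not (0 <= k < gamma.shape[1]):
        raise ValueError(f"cluster index {k} out of range")
    w = gamma[:, k][:, None]  # (C, 1)
    if comp_post is not None and comp_post.shape[-1] >= 2:
        v = 1.0 - comp_post[:, :, k, 0]  # (C, G)
    else:
        v = np.ones_like(x)
    pos = x > 0
    denom = (w * pos).sum(axis=0) + (w * v * ~pos).sum(axis=0)
    num1 = (w * x * pos).sum(axis=0)
    num2 = (w * x * x * pos).sum(axis=0)
    defined = denom > 0
    safe = np.where(defined, denom, 1.0)
    m = np.where(defined, num1 / safe, np.nan)
    e2 = np.where(defined, num2 / safe, np.nan)
    var = e2 - m**2
    # clip tiny negative variances produced by float cancellation
    var = np.where((var < 0) & (var > -1e-8), 0.0, var)
    return ClusterMoments(m, e2, var, denom, defined)


def wald_deg_test(mA: ClusterMoments, mB: ClusterMoments):
    """Per-gene Wald z and two-sided normal p for the difference of the
    cluster means."""
    se2 = mA.var / mA.n_eff + mB.var / mB.n_eff
    diff = mA.m - mB.m
    with np.errstate(divide="ignore", invalid="ignore"):
        z = diff / np.sqrt(se2)
    zero_se = se2 <= 0
    if np.any(zero_se & (diff != 0)):
        logger.warning(
            "%d genes with zero pooled variance but unequal means (p set to 0)",
            int(np.sum(zero_se & (diff != 0))),
        )
    z = np.where(zero_se & (diff == 0), 0.0, z)
    z = np.where(zero_se & (diff > 0), np.inf, z)
    z = np.where(zero_se & (diff < 0), -np.inf, z)
    p = 2.0 * norm.sf(np.abs(z))
    return z, p


def benjamini_hochberg(p) -> np.ndarray:
    """Step-up Benjamini-Hochberg adjusted p-values, clipped to 1."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1:
        raise ValueError("p must be a 1-D vector")
    if np.any((p < 0) | (p > 1) | ~np.isfinite(p)):
        raise ValueError("p-values must lie in [0, 1]")
    m = p.size
    order = np.argsort(p, kind="stable")
    ranked = p[order] * m / np.arange(1, m + 1)
    adj = np.minimum.accumulate(ranked[::-1])[::-1]
    adj = np.clip(adj, 0.0, 1.0)
    out = np.empty(m)
    out[order] = adj
    return out


def deg_between_clusters(
    counts: CountMatrix,
    fit: FitResult,
    k1: int,
    k2: int,
    scalers: CellScalers | None = None,
) -> pd.DataFrame:
    """DEG table between two fitted clusters, sorted by adjusted p-value.

    Columns follow ``DEG_COLUMNS``.  Genes whose moments are undefined in
    either cluster (no effective weight) are dropped with a logged count.
    """
    if k1 == k2:
        raise ValueError("k1 and k2 must differ")
    K = fit.params.K
    if not (0 <= k1 < K and 0 <= k2 < K):
        raise ValueError("cluster index out of range")
    if scalers is None:
        scalers = compute_cell_scalers(counts)
    resp = e_step(counts, fit.params, scalers)
    mA = expression_moments(counts, resp.gamma, resp.comp_post, k1)
    mB = expression_moments(counts, resp.gamma, resp.comp_post, k2)
    testable = mA.defined & mB.defined
    # all-zero genes have a flat likelihood and are excluded
    testable &= counts.counts.sum(axis=0) > 0
    n_drop = int((~testable).sum())
    if n_drop:
        logger.info("%d untestable genes dropped from the DEG table", n_drop)
    idx = np.flatnonzero(testable)
    zA = ClusterMoments(mA.m[idx], mA.second_moment[idx], mA.var[idx],
                        mA.n_eff[idx], mA.defined[idx])
    zB = ClusterMoments(mB.m[idx], mB.second_moment[idx], mB.var[idx],
                        mB.n_eff[idx], mB.defined[idx])
    z, p = wald_deg_test(zA, zB)
    p_adj = benjamini_hochberg(p)
    table = pd.DataFrame({
        "gene_id": [counts.gene_ids[i] for i in idx],
        "m_k1": zA.m, "m_k2": zB.m,
        "var_k1": zA.var, "var_k2": zB.var,
        "n_eff_k1": zA.n_eff, "n_eff_k2": zB.n_eff,
        "wald_z": z, "p_value": p, "p_adjusted": p_adj,
    })
    return table.sort_values("p_adjusted", kind="stable").reset_index(drop=True)
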