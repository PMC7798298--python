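"""Clustering evaluation: hard assignment from posteriors, adjusted Rand
index, and averaged per-cell / per-gene Pearson correlation."""

from __future__ import annotations

import logging
from dataclasses import dataclass

import numpy as np
from sklearn.metrics import adjusted_rand_score

from .model_core import CountMatrix

logger = logging.getLogger(__name__)


@dataclass
class HardLabels:
    labels: np.ndarray

    def __post_init__(self):
        self.labels = np.asarray(self.labels, dtype=np.int64)


def hard_assign(gamma: np.ndarray) -> HardLabels:
    """Assign each cell to the cluster with the highest posterior; ties go
    to the smallest cluster index."""
    gamma = np.asarray(gamma)
    if gamma.size == 0:
        raise ValueError("empty posterior matrix")
    return HardLabels(np.argmax(gamma, axis=1))


def adjusted_rand_index(labels_a, labels_b) -> float:
    labels_a = np.asarray(labels_a)
    labels_b = np.asarray(labels_b)
    if labels_a.shape != labels_b.shape:
        raise ValueError("label vectors have different lengths")
    return float(adjusted_rand_score(labels_a, labels_b))


def _mean_rowwise_pearson(a: np.ndarray, b: np.ndarray, axis_name: str) -> float:
    """Average Pearson correlation across rows; constant rows contribute 0."""
    rhos = np.empty(a.shape[0])
    n_const = 0
    for i in range(a.shape[0]):
        x, y = a[i], b[i]
        if np.std(x) == 0 or np.std(y) == 0:
            rhos[i] = 0.0
            n_const += 1
        else:
            rhos[i] = np.corrcoef(x, y)[0, 1]
    if n_const:
        logger.warning(
            "%d constant %s vectors contributed 0 to the mean correlation",
            n_const, axis_name,
        )
    return float(rhos.mean())


def cell_gene_correlation(truth, imputed) -> tuple[float, float]:
    """Mean per-cell and mean per-gene Pearson correlation between a
    reference matrix (e.g. counts without dropout) and an imputed one."""
    x = truth.counts if isinstance(truth, CountMatrix) else np.asarray(truth)
    y = np.asarray(imputed, dtype=float)
    if x.shape != y.shape:
        raise ValueError(f"shape mismatch: {x.shape} vs {y.shape}")
    x = x.astype(float)
    rho_cell = _mean_rowwise_pearson(x, y, "cell")
    rho_gene = _mean_rowwise_pearson(x.T, y.T, "gene")
    return rho_cell, rho_gene
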