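"""Likelihood/AIC/BIC scoring of fitted models and automatic selection of
the number of clusters."""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .em_fit import InitStrategy, multi_restart_fit
from .model_core import CellScalers, CountMatrix


def count_free_params(K: int, G: int, L: int) -> int:
    """Number of independently optimized parameters.

    (K - 1) free mixing weights plus, per gene and cluster, L - 1 free
    component weights and an (alpha, beta) pair for each NB component
    (L - 1 of them when a dropout component is present, 1 when L = 1).
    """
    if K < 1 or G < 1 or L < 1:
        raise ValueError("K, G and L must be >= 1")
    n_nb = L - 1 if L >= 2 else 1
    return (K - 1) + K * G * ((L - 1) + 2 * n_nb)


def information_criteria(loglik: float, P: int, C: int) -> tuple[float, float]:
    """AIC = 2P - 2 loglik; BIC = P ln(C) - 2 loglik."""
    if C < 1:
        raise ValueError("C must be >= 1")
    aic = 2.0 * P - 2.0 * loglik
    bic = P * math.log(C) - 2.0 * loglik
    return aic, bic


@dataclass
class SelectionTable:
    """Per-K best log likelihood, parameter count and criteria."""

    frame: pd.DataFrame  # columns: K, loglik, P, AIC, BIC, init

    def to_tsv(self, path):
        self.frame.to_csv(path, sep="\t", index=False)


def select_num_clusters(
    counts: CountMatrix,
    K_range,
    L: int = 2,
    restarts_per_K: int = 10,
    criterion: str = "AIC",
    seed: int = 0,
    scalers: CellScalers | None = None,
    strategies: list[InitStrategy] | None = None,
    **fit_kwargs,
) -> tuple[int, SelectionTable]:
    """Fit each K with multi-restart EM and return the criterion argmin.

    Ties are broken toward the smaller K.
    """
    K_range = sorted(set(int(k) for k in K_range))
    if not K_range:
        raise ValueError("K_range must be nonempty")
    if criterion not in ("AIC", "BIC"):
        raise ValueError("criterion must be 'AIC' or 'BIC'")
    rows = []
    for i, K in enumerate(K_range):
        fr = multi_restart_fit(
            counts, K, L,
            strategies=strategies,
            n_random_restarts=restarts_per_K if strategies is None else 0,
            seed=seed + 1000 * i,
            scalers=scalers,
            **fit_kwargs,
        )
        P = count_free_params(K, counts.n_genes, L)
        aic, bic = information_criteria(fr.loglik, P, counts.n_cells)
        rows.append({"K": K, "loglik": fr.loglik, "P": P, "AIC": aic,
                     "BIC": bic, "init": fr.init_condition})
    frame = pd.DataFrame(rows)
    # idxmin on the sorted-K frame breaks ties toward smaller K
    K_best = int(frame.loc[frame[criterion].idxmin(), "K"])
    return K_best, SelectionTable(frame)
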