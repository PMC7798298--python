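"""Posterior-mean imputation of observed zeros for visualization.

Non-zero counts are passed through untouched.  An observed zero is
replaced by

    s_c * sum_k p(k | x_c) * p(0 | k, x=0) * sum_{l>0} p(l | k, x=0,
        expressed) * alpha_{g,k,l} / beta_{g,k,l}

i.e. the dropout posterior times the mean of the expressed components
under the expressed-conditional posterior.  Zeros judged to come from an
expressed component stay at zero with the complementary probability.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np

from .em_fit import e_step
from .model_core import (
    CellScalers,
    CountMatrix,
    ModelParams,
    compute_cell_scalers,
)


@dataclass
class ImputedMatrix:
    values: np.ndarray
    mask: np.ndarray  # True where a zero was replaced

    def __post_init__(self):
        self.values = np.asarray(self.values, dtype=float)
        self.mask = np.asarray(self.mask, dtype=bool)


def impute_zeros(
    counts: CountMatrix,
    params: ModelParams,
    scalers: CellScalers | None = None,
) -> ImputedMatrix:
    """Replace observed zeros by their posterior-mean expression."""
    params.validate()
    if scalers is None:
        scalers = compute_cell_scalers(counts)
    x = counts.counts
    C, G = x.shape
    values = x.astype(float).copy()
    mask = np.zeros((C, G), dtype=bool)
    if not params.has_dropout:
        # no dropout component: a zero is never imputed
        return ImputedMatrix(values, mask)
    resp = e_step(counts, params, scalers)
    means = params.alpha / params.beta  # (G, K, n_nb)
    # dropout and expressed-conditional posteriors at x = 0, computed from
    # the raw (unfloored) weights so q0 = 0 yields exactly no imputation;
    # the ratio form stays stable as the dropout posterior approaches 1.
    s = scalers.s[:, None, None, None]
    b = params.beta[None, :, :, :]
    a = params.alpha[None, :, :, :]
    qnb = params.q[None, :, :, 1:] * (b / (b + s)) ** a  # (C, G, K, n_nb)
    qnb_tot = qnb.sum(axis=-1)
    p0 = params.q[None, :, :, 0] / np.clip(
        params.q[None, :, :, 0] + qnb_tot, 1e-300, None)
    pexp = qnb / np.clip(qnb_tot[..., None], 1e-300, None)
    cond_mean = (pexp * means[None]).sum(axis=-1)  # (C, G, K)
    imputed = scalers.s[:, None] * (resp.gamma[:, None, :] * p0 * cond_mean).sum(axis=-1)
    zeros = x == 0
    values[zeros] = imputed[zeros]
    mask[zeros] = True
    return ImputedMatrix(values, mask)
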