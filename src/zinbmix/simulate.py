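"""Synthetic count generation following the model's generative hierarchy,
plus the packaged two-gene and three-cluster benchmarks.

Generation draws, per cell, a cluster from pi; per gene, a mixture
component from q (component 0 is dropout and yields a zero); for an
expressed component, a Gamma(alpha, beta) intensity and finally a Poisson
count with rate s_c * lambda.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .metrics import HardLabels
from .model_core import CellScalers, CountMatrix, ModelParams


@dataclass
class DEGSpec:
    """Differential-expression spike: n_genes get their NB mean multiplied
    by ``fold`` in ``target_cluster`` (implemented by scaling alpha)."""

    n_genes: int
    fold: float
    target_cluster: int = 0

    def __post_init__(self):
        if self.fold <= 0:
            raise ValueError("fold must be positive")


@dataclass
class SimulationSpec:
    params: ModelParams
    n_cells: int
    scalers: float | np.ndarray = 1.0
    dropout_override: np.ndarray | None = None  # per-cluster q0 values
    deg_spec: DEGSpec | None = None
    seed: int = 0

    def cell_scalers(self) -> CellScalers:
        s = np.asarray(self.scalers, dtype=float)
        if s.ndim == 0:
            s = np.full(self.n_cells, float(s))
        return CellScalers(s)


@dataclass
class SimulatedDataset:
    counts: CountMatrix
    true_labels: HardLabels
    true_components: np.ndarray  # (C, G); 0 = dropout, 1.. = NB component
    spec: SimulationSpec
    deg_genes: np.ndarray = field(default_factory=lambda: np.array([], dtype=int))
    gen_params: ModelParams | None = None  # realized params after spiking/override

    @property
    def scalers(self) -> CellScalers:
        return self.spec.cell_scalers()


def spike_deg(
    params: ModelParams, deg_spec: DEGSpec, seed: int = 0,
    genes: np.ndarray | None = None,
) -> tuple[ModelParams, np.ndarray]:
    """Scale the NB means of sampled genes in the target cluster by the
    fold (alpha is scaled so dispersion behaviour changes minimally).

    Returns the new parameters and the spiked gene indices.
    """
    G = params.G
    if deg_spec.n_genes > G:
        raise ValueError(f"cannot spike {deg_spec.n_genes} of {G} genes")
    if not (0 <= deg_spec.target_cluster < params.K):
        raise ValueError("target cluster out of range")
    if genes is None:
        rng = np.random.default_rng(seed)
        genes = rng.choice(G, size=deg_spec.n_genes, replace=False)
    genes = np.sort(np.asarray(genes))
    out = params.copy()
    out.alpha[genes, deg_spec.target_cluster, :] *= deg_spec.fold
    return out, genes


def _override_dropout(params: ModelParams, q0: np.ndarray) -> ModelParams:
    """Set per-cluster dropout weight, rescaling the expressed weights."""
    if not params.has_dropout:
        raise ValueError("model has no dropout component to override")
    q0 = np.broadcast_to(np.asarray(q0, dtype=float), (params.K,))
    if np.any((q0 < 0) | (q0 > 1)):
        raise ValueError("dropout probabilities must lie in [0, 1]")
    out = params.copy()
    for k in range(params.K):
        rest = out.q[:, k, 1:]
        tot = np.clip(rest.sum(axis=-1, keepdims=True), 1e-300, None)
        out.q[:, k, 1:] = (1.0 - q0[k]) * rest / tot
        out.q[:, k, 0] = q0[k]
    return out


def simulate_counts(spec: SimulationSpec) -> SimulatedDataset:
    """Draw a dataset from the four-stage hierarchy, reproducibly."""
    rng = np.random.default_rng(spec.seed)
    params = spec.params.copy()
    params.validate()
    deg_genes = np.array([], dtype=int)
    if spec.deg_spec is not None:
        params, deg_genes = spike_deg(
            params, spec.deg_spec,
            seed=rng.integers(2**31),
        )
    if spec.dropout_override is not None:
        params = _override_dropout(params, spec.dropout_override)
    C = spec.n_cells
    G = params.G
    K, L = params.K, params.L
    offset = 1 if params.has_dropout else 0
    s = spec.cell_scalers().s
    labels = rng.choice(K, size=C, p=params.pi)
    comps = np.empty((C, G), dtype=np.int64)
    x = np.zeros((C, G), dtype=np.int64)
    for k in range(K):
        cells = np.flatnonzero(labels == k)
        if cells.size == 0:
            continue
        for g in range(G):
            u = rng.random(cells.size)
            cum = np.cumsum(params.q[g, k])
            l_draw = np.searchsorted(cum, u, side="right")
            l_draw = np.clip(l_draw, 0, L - 1)
            # store 1-based NB component codes so 0 always means dropout
            comps[cells, g] = l_draw + (0 if params.has_dropout else 1)
            for j in range(params.n_nb):
                sel = cells[l_draw == offset + j]
                if sel.size == 0:
                    continue
                lam = rng.gamma(params.alpha[g, k, j],
                                1.0 / params.beta[g, k, j], size=sel.size)
                x[sel, g] = rng.poisson(s[sel] * lam)
    counts = CountMatrix(x)
    return SimulatedDataset(counts, HardLabels(labels), comps, spec, deg_genes,
                            gen_params=params)


def apply_dropout(
    counts: CountMatrix,
    q0,
    labels: HardLabels | np.ndarray | None = None,
    seed: int = 0,
) -> CountMatrix:
    """Independently zero each entry with its cell's cluster-specific
    dropout probability (post-hoc dropout injection)."""
    q0 = np.asarray(q0, dtype=float)
    if np.any((q0 < 0) | (q0 > 1)):
        raise ValueError("dropout probabilities must lie in [0, 1]")
    C, G = counts.counts.shape
    if q0.ndim == 0:
        per_cell = np.full(C, float(q0))
    else:
        if labels is None:
            raise ValueError("per-cluster dropout requires cell labels")
        lab = labels.labels if isinstance(labels, HardLabels) else np.asarray(labels)
        per_cell = q0[lab]
    rng = np.random.default_rng(seed)
    drop = rng.random((C, G)) < per_cell[:, None]
    x = counts.counts.copy()
    x[drop] = 0
    return CountMatrix(x, cell_ids=counts.cell_ids, gene_ids=counts.gene_ids)


def two_gene_benchmark_spec(
    n_cells: int = 10_000,
    q0: float = 0.2,
    seed: int = 0,
    scalers: float = 1.0,
) -> SimulationSpec:
    """The canonical two-gene, two-cluster benchmark: pi = (0.4, 0.6),
    dropout weight 0.2 (overridable), beta = 1, cluster-1 alphas (10, 5)
    and cluster-2 alphas (30, 20)."""
    alpha = np.array([[[10.0], [30.0]],
                      [[5.0], [20.0]]])  # (G=2, K=2, 1)
    beta = np.ones((2, 2, 1))
    q = np.empty((2, 2, 2))
    q[..., 0] = q0
    q[..., 1] = 1.0 - q0
    params = ModelParams(2, 2, np.array([0.4, 0.6]), q, alpha, beta).validate()
    return SimulationSpec(params, n_cells, scalers=scalers, seed=seed)


def two_gene_methods_init() -> ModelParams:
    """The stated EM starting point for the two-gene benchmark: pi =
    (0.5, 0.5), dropout 0.1, beta = 1, cluster-1 alphas (8, 8), cluster-2
    alphas (25, 25)."""
    alpha = np.array([[[8.0], [25.0]],
                      [[8.0], [25.0]]])
    beta = np.ones((2, 2, 1))
    q = np.empty((2, 2, 2))
    q[..., 0] = 0.1
    q[..., 1] = 0.9
    return ModelParams(2, 2, np.array([0.5, 0.5]), q, alpha, beta).validate()


def three_cluster_benchmark_spec(
    n_genes: int = 1000,
    n_cells: int = 1200,
    n_deg: int = 150,
    fold: float = 1.5,
    q0=0.1,
    vary_dropout_by: float = 0.0,
    seed: int = 0,
) -> SimulationSpec:
    """Three equally sized clusters sharing per-gene NB parameters except
    for ``n_deg`` genes whose mean is ``fold`` times higher in cluster 0.

    Per-gene (alpha, beta) are drawn from log-normal ranges shaped like
    fitted single-cell gene parameters (alpha median ~3 with an order of
    magnitude of spread, beta centred at 1).  ``vary_dropout_by`` offsets
    the per-cluster dropout probability by +/- that step around ``q0``.
    """
    rng = np.random.default_rng(seed)
    base_alpha = np.clip(rng.lognormal(np.log(3.0), 0.8, size=n_genes), 0.05, 200.0)
    base_beta = np.clip(rng.lognormal(0.0, 0.3, size=n_genes), 0.1, 10.0)
    alpha = np.repeat(base_alpha[:, None, None], 3, axis=1)
    beta = np.repeat(base_beta[:, None, None], 3, axis=1)
    q0 = np.asarray(q0, dtype=float)
    if q0.ndim == 0:
        q0k = np.full(3, float(q0))
        if vary_dropout_by:
            q0k = q0k + vary_dropout_by * np.array([-1.0, 0.0, 1.0])
    else:
        q0k = np.broadcast_to(q0, (3,)).astype(float)
    q0k = np.clip(q0k, 0.0, 1.0)
    q = np.empty((n_genes, 3, 2))
    q[:, :, 0] = q0k[None, :]
    q[:, :, 1] = 1.0 - q0k[None, :]
    params = ModelParams(3, 2, np.full(3, 1.0 / 3.0), q, alpha, beta).validate()
    deg = DEGSpec(n_deg, fold, target_cluster=0) if n_deg else None
    return SimulationSpec(params, n_cells, deg_spec=deg, seed=seed)
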