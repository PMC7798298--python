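"""EM fitting of the ZINB mixture: E-step posteriors, M-step updates,
initialization strategies and multi-restart driver.

The M-step updates for the mixing weights and component weights are in
closed form; the Gamma shape/rate pair of each negative-binomial
component is refreshed by a bounded quasi-Newton maximization of the
responsibility-weighted NB log likelihood in log-parameter space,
warm-started from the previous values.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.optimize import minimize
from scipy.special import digamma, gammaln

from .model_core import (
    AB_MAX,
    AB_MIN,
    Q_FLOOR,
    CellScalers,
    CountMatrix,
    ModelParams,
    cell_log_likelihoods,
    component_log_terms,
    compute_cell_scalers,
)

logger = logging.getLogger(__name__)

GAMMA_FLOOR = 1e-12

INIT_METHODS = ("random", "kmeans", "spectral")
INIT_TRANSFORMS = ("log1p", "pca2", "pca_25pct", "pca_40pct", "none")


@dataclass
class Responsibilities:
    """E-step posteriors.

    ``gamma[c, k] = p(k | x_c)`` and ``comp_post[c, g, k, l] =
    p(l | k, x_{c,g})``; the dropout slice is exactly zero at positive
    counts.
    """

    gamma: np.ndarray
    comp_post: np.ndarray
    log_joint: np.ndarray
    cell_loglik: np.ndarray

    @property
    def loglik(self) -> float:
        return float(self.cell_loglik.sum())


@dataclass
class FitResult:
    params: ModelParams
    loglik_trace: np.ndarray
    n_iter: int
    converged: bool
    seed: int | None = None
    init_condition: str = ""
    n_cells: int = 0
    candidate_logliks: list = field(default_factory=list)

    @property
    def loglik(self) -> float:
        return float(self.loglik_trace[-1])

    def information_criteria(self):
        from .model_selection import count_free_params, information_criteria

        P = count_free_params(self.params.K, self.params.G, self.params.L)
        return information_criteria(self.loglik, P, self.n_cells)

    @property
    def aic(self) -> float:
        return self.information_criteria()[0]

    @property
    def bic(self) -> float:
        return self.information_criteria()[1]


@dataclass(frozen=True)
class InitStrategy:
    """Initialization condition: a clustering method applied to a
    transformation of the counts (8 method x transform combinations plus
    fully random labels)."""

    method: str = "random"
    transform: str = "none"
    seed: int = 0

    def __post_init__(self):
        if self.method not in INIT_METHODS:
            raise ValueError(f"unknown init method {self.method!r}")
        if self.transform not in INIT_TRANSFORMS:
            raise ValueError(f"unknown init transform {self.transform!r}")

    @property
    def label(self) -> str:
        return f"{self.method}/{self.transform}/seed={self.seed}"


def paper_init_conditions(seed: int = 0) -> list[InitStrategy]:
    """The 8 clustering initialization conditions: {kmeans, spectral} x
    {log1p, pca2, pca_25pct, pca_40pct}."""
    return [
        InitStrategy(m, t, seed)
        for m in ("kmeans", "spectral")
        for t in ("log1p", "pca2", "pca_25pct", "pca_40pct")
    ]


# ---------------------------------------------------------------------------
# E-step


def e_step(
    counts: CountMatrix, params: ModelParams, scalers: CellScalers
) -> Responsibilities:
    """Posteriors over clusters (softmax of log joints) and over mixture
    components within each (cell, gene, cluster)."""
    terms = component_log_terms(counts, params, scalers)  # (C,G,K,L)
    from scipy.special import logsumexp

    per_gene = logsumexp(terms, axis=-1)  # (C,G,K)
    if not np.all(np.isfinite(per_gene)):
        c, g, k = np.argwhere(~np.isfinite(per_gene))[0]
        raise FloatingPointError(
            f"non-finite log-likelihood for cell {counts.cell_ids[c]!r}, "
            f"gene {counts.gene_ids[g]!r}, cluster {k}"
        )
    logpi = np.log(np.clip(params.pi, 1e-300, None))
    log_joint = logpi[None, :] + per_gene.sum(axis=1)
    cell_loglik = logsumexp(log_joint, axis=1)
    gamma = np.exp(log_joint - cell_loglik[:, None])
    # p(l | k, x): softmax over the component axis; -inf logits give exact 0.
    comp_post = np.exp(terms - per_gene[..., None])
    return Responsibilities(gamma, comp_post, log_joint, cell_loglik)


# ---------------------------------------------------------------------------
# Weighted NB maximum likelihood (inner M-step problem)


def _weighted_nb_negll_and_grad(theta, x, w, s):
    """Negative weighted NB log likelihood and gradient in (log a, log b)."""
    a = np.exp(theta[0])
    b = np.exp(theta[1])
    lb = np.log(b) - np.log(b + s)
    ls = np.log(s) - np.log(b + s)
    ll = w * (gammaln(x + a) - gammaln(a) + a * lb + x * ls)
    # d/da and d/db of the weighted log likelihood
    da = np.sum(w * (digamma(x + a) - digamma(a) + lb))
    db = np.sum(w * (a / b - (a + x) / (b + s)))
    return -float(ll.sum()), -np.array([a * da, b * db])


_LOG_AB_MIN = np.log(AB_MIN)
_LOG_AB_MAX = np.log(AB_MAX)


def fit_weighted_nb(
    x: np.ndarray,
    w: np.ndarray,
    s: np.ndarray,
    alpha0: float,
    beta0: float,
    max_inner: int = 25,
):
    """Maximize ``sum_c w_c nb_log_pmf(x_c, a, b, s_c)`` over (a, b).

    Works in log-parameter space (positivity by construction) with an
    L-BFGS-B inner loop warm-started at (alpha0, beta0).  Never returns a
    point worse than the warm start.
    """
    x = np.asarray(x, dtype=float)
    w = np.asarray(w, dtype=float)
    s = np.broadcast_to(np.asarray(s, dtype=float), x.shape)
    keep = w > 0
    if not np.any(keep):
        return float(alpha0), float(beta0)
    x, w, s = x[keep], w[keep], s[keep]
    # Aggregate identical (x, s) observations; with a common scaler the
    # problem collapses to the handful of distinct count values.
    if s.size and np.all(s == s[0]):
        ux, inv = np.unique(x, return_inverse=True)
        uw = np.bincount(inv, weights=w)
        x, w, s = ux, uw, np.full(ux.shape, s[0])
    theta0 = np.array([
        np.clip(np.log(alpha0), _LOG_AB_MIN, _LOG_AB_MAX),
        np.clip(np.log(beta0), _LOG_AB_MIN, _LOG_AB_MAX),
    ])
    f0, _ = _weighted_nb_negll_and_grad(theta0, x, w, s)
    try:
        res = minimize(
            _weighted_nb_negll_and_grad,
            theta0,
            args=(x, w, s),
            jac=True,
            method="L-BFGS-B",
            bounds=[(_LOG_AB_MIN, _LOG_AB_MAX)] * 2,
            options={"maxiter": max_inner},
        )
    except Exception as exc:  # pragma: no cover - optimizer failure path
        logger.warning("weighted NB optimizer failed (%s); keeping previous", exc)
        return float(alpha0), float(beta0)
    if not np.all(np.isfinite(res.x)) or res.fun > f0:
        return float(alpha0), float(beta0)
    return float(np.exp(res.x[0])), float(np.exp(res.x[1]))


# ---------------------------------------------------------------------------
# M-step


def m_step(
    counts: CountMatrix,
    resp: Responsibilities,
    params: ModelParams,
    scalers: CellScalers,
    max_inner: int = 25,
    frozen_genes: np.ndarray | None = None,
) -> ModelParams:
    """Closed-form updates for pi and q; weighted NB MLE for (alpha, beta).

    ``frozen_genes`` marks degenerate (all-zero) genes whose dropout
    weight is pinned near one and whose NB parameters stay at the floors.
    """
    x = counts.counts
    C, G = x.shape
    K, L, n_nb = params.K, params.L, params.n_nb
    offset = 1 if params.has_dropout else 0
    gamma = np.clip(resp.gamma, GAMMA_FLOOR, None)
    denom = gamma.sum(axis=0)  # (K,)

    pi = resp.gamma.sum(axis=0) / C
    r = gamma[:, None, :, None] * resp.comp_post  # (C,G,K,L)
    q = r.sum(axis=0) / denom[None, :, None]  # (G,K,L)

    alpha = params.alpha.copy()
    beta = params.beta.copy()
    sc = scalers.s
    for g in range(G):
        if frozen_genes is not None and frozen_genes[g]:
            continue
        xg = x[:, g]
        for k in range(K):
            for j in range(n_nb):
                w = r[:, g, k, offset + j]
                if w.sum() <= 1e-8:
                    continue  # no responsibility mass: keep previous values
                alpha[g, k, j], beta[g, k, j] = fit_weighted_nb(
                    xg, w, sc, alpha[g, k, j], beta[g, k, j], max_inner
                )
    new = ModelParams(K, L, pi, q, alpha, beta).clipped()
    if frozen_genes is not None and frozen_genes.any() and params.has_dropout:
        new.q[frozen_genes, :, 0] = 1.0 - Q_FLOOR * (L - 1)
        new.q[frozen_genes, :, 1:] = Q_FLOOR
        new.alpha[frozen_genes] = AB_MIN
        new.beta[frozen_genes] = AB_MAX
    return new


# ---------------------------------------------------------------------------
# Initialization


def _transform_counts(x: np.ndarray, transform: str) -> np.ndarray:
    from sklearn.decomposition import PCA

    x = np.asarray(x, dtype=float)
    if transform == "none":
        return x
    lx = np.log1p(x)
    if transform == "log1p":
        return lx
    if transform == "pca2":
        n = min(2, min(lx.shape))
        return PCA(n_components=n).fit_transform(lx)
    frac = 0.25 if transform == "pca_25pct" else 0.40
    full = PCA().fit(lx)
    csum = np.cumsum(full.explained_variance_ratio_)
    n = int(np.searchsorted(csum, frac) + 1)
    return PCA(n_components=n).fit_transform(lx)


def _cluster_labels(xt: np.ndarray, K: int, method: str, seed: int) -> np.ndarray:
    from sklearn.cluster import KMeans, SpectralClustering

    if method == "kmeans":
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        return km.fit_predict(xt)
    # spectral, with kmeans fallback on tiny/degenerate inputs
    try:
        sc = SpectralClustering(
            n_clusters=K, random_state=seed, assign_labels="kmeans",
            n_neighbors=min(10, max(2, xt.shape[0] - 1)),
            affinity="nearest_neighbors",
        )
        return sc.fit_predict(xt)
    except Exception as exc:
        logger.warning("spectral clustering failed (%s); falling back to kmeans", exc)
        km = KMeans(n_clusters=K, n_init=10, random_state=seed)
        return km.fit_predict(xt)


def params_from_labels(
    counts: CountMatrix,
    labels: np.ndarray,
    K: int,
    L: int,
    q0: float = 0.1,
    refine: bool = True,
    scalers: CellScalers | None = None,
    max_inner: int = 25,
) -> ModelParams:
    """Moment-seeded parameters from hard labels, optionally refined by one
    M-step with one-hot cluster responsibilities.

    Within each label group, each NB component's alpha starts at the group
    mean count with beta = 1; the dropout weight starts at ``q0``.  With
    more than one NB component the extra components are seeded at
    alpha = 0.1 (a near-Poisson low-rate component) like the per-gene
    validation defaults.
    """
    x = counts.counts
    C, G = x.shape
    labels = np.asarray(labels)
    has_dropout = L >= 2
    n_nb = L - 1 if has_dropout else 1
    pi = np.array([(labels == k).sum() for k in range(K)], dtype=float)
    pi = np.clip(pi, 1.0, None)
    pi /= pi.sum()
    alpha = np.empty((G, K, n_nb))
    beta = np.ones((G, K, n_nb))
    global_mean = np.clip(x.mean(axis=0), 0.1, None)
    for k in range(K):
        mask = labels == k
        mu = x[mask].mean(axis=0) if mask.any() else global_mean
        mu = np.clip(mu, 0.1, None)
        if n_nb == 1:
            alpha[:, k, 0] = mu
        else:
            alpha[:, k, :-1] = 0.1
            alpha[:, k, -1] = mu
    q = np.empty((G, K, L))
    if has_dropout:
        q[..., 0] = q0
        if n_nb == 2:
            # validation defaults: 0.5 / 0.4 split of the expressed mass
            frac = np.array([0.5, 0.4]) / 0.9
        else:
            frac = np.full(n_nb, 1.0 / n_nb)
        q[..., 1:] = (1.0 - q0) * frac[None, None, :]
    else:
        q[..., 0] = 1.0
    params = ModelParams(K, L, pi, q, alpha, beta).clipped().validate()
    if refine:
        if scalers is None:
            scalers = compute_cell_scalers(counts)
        resp = e_step(counts, params, scalers)
        onehot = np.zeros((C, K))
        onehot[np.arange(C), labels] = 1.0
        resp = Responsibilities(onehot, resp.comp_post, resp.log_joint,
                               resp.cell_loglik)
        params = m_step(counts, resp, params, scalers, max_inner=max_inner)
    return params


def initialize_params(
    counts: CountMatrix,
    K: int,
    L: int,
    strategy: InitStrategy,
    scalers: CellScalers | None = None,
) -> ModelParams:
    """Cluster the (transformed) counts, convert the labels to one-hot
    responsibilities, and derive initial parameters from them."""
    C = counts.n_cells
    n_distinct = len({tuple(row) for row in counts.counts})
    if K > n_distinct:
        raise ValueError(f"K={K} exceeds the {n_distinct} distinct cells")
    if strategy.method == "random":
        rng = np.random.default_rng(strategy.seed)
        labels = rng.integers(0, K, size=C)
        # ensure every cluster is represented
        labels[rng.permutation(C)[:K]] = np.arange(K)
    else:
        xt = _transform_counts(counts.counts, strategy.transform)
        labels = _cluster_labels(xt, K, strategy.method, strategy.seed)
    return params_from_labels(counts, labels, K, L, scalers=scalers)


# ---------------------------------------------------------------------------
# Outer EM loop


def _max_rel_param_change(old: ModelParams, new: ModelParams) -> float:
    def rel(a, b):
        return np.max(np.abs(b - a) / np.maximum(np.abs(a), 1e-3))

    return max(
        rel(old.pi, new.pi),
        rel(old.q, new.q),
        rel(old.alpha, new.alpha),
        rel(old.beta, new.beta),
    )


def fit_em(
    counts: CountMatrix,
    K: int,
    L: int = 2,
    init: "InitStrategy | ModelParams | None" = None,
    tol: float = 1e-6,
    param_tol: float = 1e-2,
    max_iter: int = 200,
    seed: int = 0,
    scalers: CellScalers | None = None,
    max_inner: int = 25,
) -> FitResult:
    """Fit the mixture by EM until the dual convergence criterion holds.

    Convergence requires both the relative change of the dataset log
    likelihood to fall below ``tol`` and the maximum relative parameter
    change to fall below ``param_tol`` (default 1%).
    """
    if K < 1 or L < 1 or max_iter < 1:
        raise ValueError("K, L and max_iter must be >= 1")
    if scalers is None:
        scalers = compute_cell_scalers(counts)
    if init is None:
        init = InitStrategy("random", "none", seed)
    if isinstance(init, InitStrategy):
        label = init.label
        params = initialize_params(counts, K, L, init, scalers=scalers)
    else:
        label = "params"
        params = init.copy().clipped().validate()
    frozen = counts.counts.sum(axis=0) == 0
    if frozen.any():
        logger.info("%d all-zero genes pinned to the dropout component",
                    int(frozen.sum()))
    if not frozen.any():
        frozen = None

    trace = []
    converged = False
    prev_ll = -np.inf
    for _ in range(max_iter):
        resp = e_step(counts, params, scalers)
        ll = resp.loglik
        trace.append(ll)
        new_params = m_step(counts, resp, params, scalers,
                            max_inner=max_inner, frozen_genes=frozen)
        dparam = _max_rel_param_change(params, new_params)
        params = new_params
        if len(trace) > 1:
            dll = abs(ll - prev_ll) / max(abs(prev_ll), 1.0)
            if dll < tol and dparam < param_tol:
                converged = True
                prev_ll = ll
                break
        prev_ll = ll
    return FitResult(
        params=params,
        loglik_trace=np.asarray(trace),
        n_iter=len(trace),
        converged=converged,
        seed=seed,
        init_condition=label,
        n_cells=counts.n_cells,
    )


def multi_restart_fit(
    counts: CountMatrix,
    K: int,
    L: int = 2,
    strategies: list[InitStrategy] | None = None,
    n_random_restarts: int = 0,
    tol: float = 1e-6,
    param_tol: float = 1e-2,
    max_iter: int = 200,
    seed: int = 0,
    scalers: CellScalers | None = None,
    max_inner: int = 25,
) -> FitResult:
    """Run EM from several initializations and keep the highest-likelihood
    fit; the final log likelihood of every candidate is recorded on the
    winner."""
    strategies = list(strategies or [])
    strategies += [
        InitStrategy("random", "none", seed + i) for i in range(n_random_restarts)
    ]
    if not strategies:
        raise ValueError("at least one strategy or restart is required")
    best = None
    finals = []
    errors = []
    for strat in strategies:
        try:
            fr = fit_em(counts, K, L, init=strat, tol=tol, param_tol=param_tol,
                        max_iter=max_iter, seed=strat.seed, scalers=scalers,
                        max_inner=max_inner)
        except Exception as exc:
            logger.warning("restart %s failed: %s", strat.label, exc)
            errors.append(exc)
            continue
        finals.append((strat.label, fr.loglik))
        if best is None or fr.loglik > best.loglik:
            best = fr
    if best is None:
        raise RuntimeError(f"all restarts failed; first error: {errors[0]}")
    best.candidate_logliks = finals
    return best
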