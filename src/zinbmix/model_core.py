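"""Core mixture distribution: data containers, NB likelihood, zero probability.

The observation model for gene ``g`` in cluster ``k`` is a mixture of a
point mass at zero (the dropout component, index ``l = 0`` when ``L >= 2``)
and ``L - 1`` negative-binomial components obtained by integrating a
Gamma(alpha, beta) intensity against a Poisson with per-cell exposure
``s_c``.  With ``L = 1`` there is a single NB component and no dropout
term.  All likelihood arithmetic is carried out in log space.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field

import numpy as np
from scipy.special import gammaln, logsumexp

# Numerical floors keeping every log finite.
Q_FLOOR = 1e-10
AB_MIN = 1e-6
AB_MAX = 1e6
PI_FLOOR = 1e-12

DEFAULT_TARGET_SIZE = 10_000.0


@dataclass
class CountMatrix:
    """Cells x genes matrix of nonnegative integer counts."""

    counts: np.ndarray
    cell_ids: list[str] = field(default=None)
    gene_ids: list[str] = field(default=None)

    def __post_init__(self):
        counts = np.asarray(self.counts)
        if counts.ndim != 2:
            raise ValueError("counts must be a 2-D cells x genes matrix")
        if np.issubdtype(counts.dtype, np.floating):
            if not np.all(counts == np.floor(counts)):
                bad = np.argwhere(counts != np.floor(counts))[0]
                raise ValueError(
                    f"non-integer count at cell {bad[0]}, gene {bad[1]}"
                )
            counts = counts.astype(np.int64)
        if not np.issubdtype(counts.dtype, np.integer):
            raise ValueError("counts must be integer-valued")
        if np.any(counts < 0):
            bad = np.argwhere(counts < 0)[0]
            raise ValueError(f"negative count at cell {bad[0]}, gene {bad[1]}")
        self.counts = counts.astype(np.int64)
        C, G = self.counts.shape
        if self.cell_ids is None:
            self.cell_ids = [f"cell{c}" for c in range(C)]
        if self.gene_ids is None:
            self.gene_ids = [f"gene{g}" for g in range(G)]
        self.cell_ids = list(map(str, self.cell_ids))
        self.gene_ids = list(map(str, self.gene_ids))
        if len(self.cell_ids) != C:
            raise ValueError("cell_ids length does not match counts")
        if len(self.gene_ids) != G:
            raise ValueError("gene_ids length does not match counts")
        if len(set(self.cell_ids)) != C:
            raise ValueError("cell_ids are not unique")
        if len(set(self.gene_ids)) != G:
            raise ValueError("gene_ids are not unique")

    @property
    def n_cells(self) -> int:
        return self.counts.shape[0]

    @property
    def n_genes(self) -> int:
        return self.counts.shape[1]

    @property
    def library_sizes(self) -> np.ndarray:
        return self.counts.sum(axis=1)

    def subset_genes(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[:, idx],
            cell_ids=self.cell_ids,
            gene_ids=[self.gene_ids[i] for i in idx],
        )

    def subset_cells(self, idx) -> "CountMatrix":
        idx = np.asarray(idx)
        return CountMatrix(
            self.counts[idx, :],
            cell_ids=[self.cell_ids[i] for i in idx],
            gene_ids=self.gene_ids,
        )


@dataclass
class CellScalers:
    """Per-cell exposure scalers, library size / target size."""

    s: np.ndarray

    def __post_init__(self):
        self.s = np.asarray(self.s, dtype=float)
        if np.any(self.s <= 0):
            bad = int(np.argwhere(self.s <= 0)[0][0])
            raise ValueError(f"non-positive scaler for cell index {bad}")


def compute_cell_scalers(
    counts: CountMatrix, target_size: float = DEFAULT_TARGET_SIZE
) -> CellScalers:
    """Library-size scalers ``s_c = library_size_c / target_size``.

    Raises if any cell has zero library size (such cells must be filtered
    before modelling).
    """
    lib = counts.library_sizes
    if np.any(lib == 0):
        bad = int(np.argwhere(lib == 0)[0][0])
        raise ValueError(
            f"cell {counts.cell_ids[bad]!r} (index {bad}) has zero library size"
        )
    return CellScalers(lib / float(target_size))


def unit_scalers(n_cells: int) -> CellScalers:
    """Scalers fixed to 1 (used by the simulation benchmarks)."""
    return CellScalers(np.ones(n_cells))


@dataclass
class ModelParams:
    """Parameters of the ZINB mixture for K clusters, G genes, L components.

    ``q`` has shape (G, K, L) and is a simplex over the last axis; when
    ``L >= 2`` index 0 is the dropout weight.  ``alpha``/``beta`` have shape
    (G, K, n_nb) where ``n_nb = L - 1`` for ``L >= 2`` and 1 for ``L = 1``
    (a plain NB model with no dropout term).
    """

    K: int
    L: int
    pi: np.ndarray
    q: np.ndarray
    alpha: np.ndarray
    beta: np.ndarray

    def __post_init__(self):
        self.pi = np.asarray(self.pi, dtype=float)
        self.q = np.asarray(self.q, dtype=float)
        self.alpha = np.asarray(self.alpha, dtype=float)
        self.beta = np.asarray(self.beta, dtype=float)

    @property
    def has_dropout(self) -> bool:
        return self.L >= 2

    @property
    def n_nb(self) -> int:
        return self.L - 1 if self.L >= 2 else 1

    @property
    def G(self) -> int:
        return self.q.shape[0]

    def validate(self, atol: float = 1e-10):
        if self.K < 1 or self.L < 1:
            raise ValueError("K and L must be >= 1")
        if self.pi.shape != (self.K,):
            raise ValueError("pi has wrong shape")
        if np.any(self.pi < 0) or abs(self.pi.sum() - 1.0) > 1e-8:
            raise ValueError("pi must be a probability vector")
        G = self.G
        if self.q.shape != (G, self.K, self.L):
            raise ValueError("q has wrong shape")
        if np.any(self.q < 0) or np.any(np.abs(self.q.sum(-1) - 1.0) > 1e-8):
            raise ValueError("q rows must be simplexes")
        if self.alpha.shape != (G, self.K, self.n_nb):
            raise ValueError("alpha has wrong shape")
        if self.beta.shape != (G, self.K, self.n_nb):
            raise ValueError("beta has wrong shape")
        if np.any(self.alpha <= 0) or np.any(self.beta <= 0):
            raise ValueError("alpha and beta must be positive")
        return self

    def copy(self) -> "ModelParams":
        return ModelParams(
            self.K, self.L, self.pi.copy(), self.q.copy(),
            self.alpha.copy(), self.beta.copy(),
        )

    def clipped(self) -> "ModelParams":
        """Return a copy with floors applied and simplexes renormalized."""
        pi = np.clip(self.pi, PI_FLOOR, None)
        pi = pi / pi.sum()
        q = np.clip(self.q, Q_FLOOR, 1.0)
        q = q / q.sum(axis=-1, keepdims=True)
        alpha = np.clip(self.alpha, AB_MIN, AB_MAX)
        beta = np.clip(self.beta, AB_MIN, AB_MAX)
        return ModelParams(self.K, self.L, pi, q, alpha, beta)

    def permute_clusters(self, perm) -> "ModelParams":
        perm = np.asarray(perm)
        return ModelParams(
            self.K, self.L, self.pi[perm], self.q[:, perm, :],
            self.alpha[:, perm, :], self.beta[:, perm, :],
        )

    def to_dict(self) -> dict:
        return {
            "K": int(self.K),
            "L": int(self.L),
            "pi": self.pi.tolist(),
            "q": self.q.tolist(),
            "alpha": self.alpha.tolist(),
            "beta": self.beta.tolist(),
        }

    @classmethod
    def from_dict(cls, d: dict) -> "ModelParams":
        return cls(
            int(d["K"]), int(d["L"]), np.array(d["pi"]), np.array(d["q"]),
            np.array(d["alpha"]), np.array(d["beta"]),
        ).validate()


@dataclass(frozen=True)
class ModelVariant:
    """Named per-gene model variants used by the zero-count validation."""

    name: str

    _TABLE = {"NB": (False, 1), "ZINB": (True, 1), "ZINB2": (True, 2)}

    def __post_init__(self):
        if self.name not in self._TABLE:
            raise ValueError(f"unknown variant {self.name!r}")

    @property
    def dropout_component(self) -> bool:
        return self._TABLE[self.name][0]

    @property
    def n_nb_components(self) -> int:
        return self._TABLE[self.name][1]

    @property
    def L(self) -> int:
        d, n = self._TABLE[self.name]
        return n + 1 if d else n


def nb_log_pmf(x, alpha, beta, s):
    """Log pmf of the Gamma-Poisson (negative binomial) count distribution.

    ``log G(x+a) - log G(a) - log x! + a log(b/(b+s)) + x log(s/(b+s))``,
    the closed form of integrating a Gamma(a, b) intensity against a
    Poisson with exposure ``s``.  Broadcasts over array arguments.
    """
    x = np.asarray(x)
    if np.issubdtype(x.dtype, np.floating):
        if not np.all(x == np.floor(x)):
            raise ValueError("x must be integer-valued")
    x = x.astype(np.int64)
    if np.any(x < 0):
        raise ValueError("x must be nonnegative")
    alpha = np.asarray(alpha, dtype=float)
    beta = np.asarray(beta, dtype=float)
    s = np.asarray(s, dtype=float)
    if np.any(alpha <= 0) or np.any(beta <= 0) or np.any(s <= 0):
        raise ValueError("alpha, beta and s must be positive")
    out = (
        gammaln(x + alpha)
        - gammaln(alpha)
        - gammaln(x + 1.0)
        + alpha * (np.log(beta) - np.log(beta + s))
        + x * (np.log(s) - np.log(beta + s))
    )
    if out.ndim == 0:
        return float(out)
    return out


def component_log_terms(
    counts: CountMatrix, params: ModelParams, scalers: CellScalers
) -> np.ndarray:
    """(C, G, K, L) array of ``log q_{g,k,l} + log h_l(x_{c,g})``.

    ``h_0`` is the zero indicator (dropout), so entries for ``l = 0`` are
    ``-inf`` at positive counts.  The log-sum-exp over the last axis gives
    the per-gene mixture log probability.
    """
    x = counts.counts  # (C, G)
    C, G = x.shape
    K, L, n_nb = params.K, params.L, params.n_nb
    s = scalers.s[:, None, None, None]  # broadcast over g, k, l
    out = np.empty((C, G, K, L))
    logq = np.log(np.clip(params.q, Q_FLOOR, None))  # (G, K, L)
    offset = 1 if params.has_dropout else 0
    # NB components
    a = params.alpha[None, :, :, :]  # (1, G, K, n_nb)
    b = params.beta[None, :, :, :]
    xb = x[:, :, None, None].astype(float)
    nb = (
        gammaln(xb + a)
        - gammaln(a)
        - gammaln(xb + 1.0)
        + a * (np.log(b) - np.log(b + s))
        + xb * (np.log(s) - np.log(b + s))
    )
    out[..., offset:] = logq[None, :, :, offset:] + nb
    if params.has_dropout:
        zero = x[:, :, None] == 0  # (C, G, 1)
        out[..., 0] = np.where(zero, logq[None, :, :, 0], -np.inf)
    return out


def gene_cluster_log_prob(
    x_g: int, g: int, k: int, params: ModelParams, s: float
) -> float:
    """Log of ``q_{g,k,0} 1{x=0} + sum_l q_{g,k,l} NB(x; a, b, s)``."""
    terms = []
    offset = 1 if params.has_dropout else 0
    if params.has_dropout and x_g == 0:
        terms.append(math.log(max(params.q[g, k, 0], Q_FLOOR)))
    for j in range(params.n_nb):
        lq = math.log(max(params.q[g, k, offset + j], Q_FLOOR))
        terms.append(lq + nb_log_pmf(x_g, params.alpha[g, k, j],
                                     params.beta[g, k, j], s))
    return float(logsumexp(terms))


def cell_log_likelihoods(
    counts: CountMatrix, params: ModelParams, scalers: CellScalers
):
    """Per-cell per-cluster log joints and per-cell total log likelihoods.

    Returns ``(log_joint, total)`` where ``log_joint[c, k] = log pi_k +
    sum_g log p(x_{c,g} | g, k)`` and ``total[c]`` is the log-sum-exp over
    clusters.
    """
    if np.all(params.pi <= 0):
        raise ValueError("pi has no positive entry")
    terms = component_log_terms(counts, params, scalers)  # (C,G,K,L)
    per_gene = logsumexp(terms, axis=-1)  # (C, G, K)
    logpi = np.log(np.clip(params.pi, PI_FLOOR, None))
    log_joint = logpi[None, :] + per_gene.sum(axis=1)  # (C, K)
    total = logsumexp(log_joint, axis=1)
    return log_joint, total


def dataset_log_likelihood(
    counts: CountMatrix, params: ModelParams, scalers: CellScalers
) -> float:
    """Sum of per-cell total log likelihoods."""
    _, total = cell_log_likelihoods(counts, params, scalers)
    return float(total.sum())


def zero_probability(g: int, k: int, params: ModelParams, s: float) -> float:
    """Closed-form probability of a zero count for gene g in cluster k:
    ``q_{g,k,0} + sum_{l>0} q_{g,k,l} (beta / (beta + s)) ** alpha``.
    """
    offset = 1 if params.has_dropout else 0
    p = params.q[g, k, 0] if params.has_dropout else 0.0
    for j in range(params.n_nb):
        b = params.beta[g, k, j]
        p += params.q[g, k, offset + j] * (b / (b + s)) ** params.alpha[g, k, j]
    return float(min(max(p, 0.0), 1.0))
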