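"""Pairwise similarity metrics and affinity-matrix construction.

The spectral pipeline partitions a weighted graph whose vertices are patch
tokens and whose edge weights are pairwise similarities.  Deep spectral
baselines use the raw dot product; it is dominated by isolated extreme
channel values ("irregular values"), so a single spiked channel can split
one instance into several.  The Bray-Curtis similarity compares feature
*distributions* (relative L1 discrepancy), the Chebyshev similarity
penalises the single worst coordinate, and their ratio

    BoC(u, t) = BC_sim / CH_sim = (1 + CH_diss) / (1 + BC_diss)

keeps distribution sensitivity while re-weighting by the maximum
deviation.  Classical distances (L1, L2, cosine, correlation,
Mahalanobis) are exposed as similarities through the same
``1 / (1 + dissimilarity)`` reversal.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.spatial import distance as _dist

__all__ = [
    "METRICS",
    "AffinityMatrix",
    "braycurtis_diss",
    "braycurtis_sim",
    "chebyshev_diss",
    "chebyshev_sim",
    "boc",
    "reversed_distance_sim",
    "pairwise_similarity",
    "build_affinity",
]

#: Names of the supported similarity metrics.
METRICS = (
    "dot",
    "braycurtis",
    "chebyshev",
    "boc",
    "cosine",
    "correlation",
    "l1",
    "l2",
    "mahalanobis",
)


def _pair(u, t) -> tuple[np.ndarray, np.ndarray]:
    u = np.asarray(u, dtype=np.float64).ravel()
    t = np.asarray(t, dtype=np.float64).ravel()
    if u.shape != t.shape:
        raise ValueError(f"vector lengths differ: {u.size} vs {t.size}")
    return u, t


def braycurtis_diss(u, t) -> float:
    """Bray-Curtis dissimilarity ``sum|u-t| / sum|u+t|``.

    Two zero vectors give 0 (identical); a zero denominator with a
    nonzero numerator gives +inf (maximal dissimilarity).
    """
    u, t = _pair(u, t)
    num = float(np.sum(np.abs(u - t)))
    den = float(np.sum(np.abs(u + t)))
    if den == 0.0:
        return 0.0 if num == 0.0 else float("inf")
    return num / den


def braycurtis_sim(u, t) -> float:
    """``1 / (1 + BC_diss)``; lies in (0, 1] (0 at infinite dissimilarity)."""
    d = braycurtis_diss(u, t)
    return 0.0 if np.isinf(d) else 1.0 / (1.0 + d)


def chebyshev_diss(u, t) -> float:
    """Chebyshev (max-coordinate) distance ``max_i |u_i - t_i|``."""
    u, t = _pair(u, t)
    return float(np.max(np.abs(u - t)))


def chebyshev_sim(u, t) -> float:
    """``1 / (1 + CH_diss)``; lies in (0, 1]."""
    return 1.0 / (1.0 + chebyshev_diss(u, t))


def boc(u, t) -> float:
    """Bray-Curtis over Chebyshev similarity ``BC_sim / CH_sim``.

    Equivalently ``(1 + CH_diss) / (1 + BC_diss)``; equals 1 for identical
    vectors and is strictly positive.
    """
    u, t = _pair(u, t)
    bc = braycurtis_diss(u, t)
    if np.isinf(bc):
        return 0.0
    return (1.0 + chebyshev_diss(u, t)) / (1.0 + bc)


def reversed_distance_sim(
    u, t, base: str, covariance: np.ndarray | None = None
) -> float:
    """Similarity obtained by reversing a classical distance.

    ``l1``, ``l2`` and ``mahalanobis`` use ``1/(1 + distance)``; ``cosine``
    and ``correlation`` use ``1/(1 + (1 - cos))`` resp. ``1/(1 + (1 - corr))``
    so that identical vectors score 1.  Mahalanobis requires a
    positive-definite ``covariance``.
    """
    u, t = _pair(u, t)
    if base == "l1":
        d = float(np.sum(np.abs(u - t)))
    elif base == "l2":
        d = float(np.linalg.norm(u - t))
    elif base == "cosine":
        nu, nt = np.linalg.norm(u), np.linalg.norm(t)
        if nu == 0.0 or nt == 0.0:
            raise ValueError("cosine similarity undefined for zero vectors")
        d = 1.0 - float(u @ t) / (nu * nt)
    elif base == "correlation":
        uc, tc = u - u.mean(), t - t.mean()
        nu, nt = np.linalg.norm(uc), np.linalg.norm(tc)
        if nu == 0.0 or nt == 0.0:
            raise ValueError("correlation undefined for constant vectors")
        d = 1.0 - float(uc @ tc) / (nu * nt)
    elif base == "mahalanobis":
        if covariance is None:
            raise ValueError("mahalanobis requires a covariance matrix")
        vi = np.linalg.inv(covariance)
        diff = u - t
        q = float(diff @ vi @ diff)
        if q < 0:
            q = 0.0
        d = float(np.sqrt(q))
    else:
        raise ValueError(f"unknown base distance {base!r}")
    return 1.0 / (1.0 + d)


def _ridge_covariance(tokens: np.ndarray) -> np.ndarray:
    """Token covariance with a small ridge so inversion never fails."""
    c = np.cov(tokens, rowvar=False)
    c = np.atleast_2d(c)
    ridge = 1e-6 * (np.trace(c) / c.shape[0] if np.trace(c) > 0 else 1.0)
    return c + ridge * np.eye(c.shape[0])


def _pairwise_bc_diss(tokens: np.ndarray) -> np.ndarray:
    # sum|u - t| and sum|u + t| as cityblock distances to X and -X
    num = _dist.cdist(tokens, tokens, "cityblock")
    den = _dist.cdist(tokens, -tokens, "cityblock")
    with np.errstate(divide="ignore", invalid="ignore"):
        d = np.where(den > 0, num / np.maximum(den, 1e-300), np.where(num > 0, np.inf, 0.0))
    return d


def pairwise_similarity(
    tokens: np.ndarray, metric: str, covariance: np.ndarray | None = None
) -> np.ndarray:
    """P x P similarity matrix over the rows of ``tokens``.

    Vectorized equivalent of calling the scalar metric on every pair;
    the ``dot`` metric clamps negative inner products to 0 so the result
    can serve as graph edge weights.
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    if tokens.ndim != 2:
        raise ValueError("tokens must be a P x C matrix")
    if metric == "dot":
        return np.maximum(tokens @ tokens.T, 0.0)
    if metric == "braycurtis":
        d = _pairwise_bc_diss(tokens)
        return np.where(np.isinf(d), 0.0, 1.0 / (1.0 + np.where(np.isinf(d), 0.0, d)))
    if metric == "chebyshev":
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "chebyshev"))
    if metric == "boc":
        bc = _pairwise_bc_diss(tokens)
        ch = _dist.cdist(tokens, tokens, "chebyshev")
        out = np.where(np.isinf(bc), 0.0, (1.0 + ch) / (1.0 + np.where(np.isinf(bc), 0.0, bc)))
        return out
    if metric == "l1":
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "cityblock"))
    if metric == "l2":
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "euclidean"))
    if metric == "cosine":
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "cosine"))
    if metric == "correlation":
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "correlation"))
    if metric == "mahalanobis":
        cov = covariance if covariance is not None else _ridge_covariance(tokens)
        vi = np.linalg.inv(cov)
        return 1.0 / (1.0 + _dist.cdist(tokens, tokens, "mahalanobis", VI=vi))
    raise ValueError(f"unknown metric {metric!r}")


@dataclasses.dataclass(frozen=True)
class AffinityMatrix:
    """Symmetric nonnegative pairwise-similarity matrix over graph vertices.

    ``vertex_index`` maps the matrix row/column position to the token index
    in the original row-major grid (identity when no mask was applied).
    """

    weights: np.ndarray
    metric: str
    vertex_index: np.ndarray

    def __post_init__(self) -> None:
        w = np.asarray(self.weights, dtype=np.float64)
        if w.ndim != 2 or w.shape[0] != w.shape[1]:
            raise ValueError("weights must be square")
        if not np.allclose(w, w.T, atol=1e-9):
            raise ValueError("affinity matrix must be symmetric")
        if w.min() < -1e-12:
            raise ValueError("affinity matrix must be nonnegative")
        object.__setattr__(self, "weights", np.maximum(w, 0.0))
        object.__setattr__(
            self, "vertex_index", np.asarray(self.vertex_index, dtype=np.int64)
        )

    @property
    def n_vertices(self) -> int:
        return self.weights.shape[0]


def build_affinity(
    tokens: np.ndarray,
    metric: str = "boc",
    mask: np.ndarray | None = None,
) -> AffinityMatrix:
    """Build the affinity matrix over (optionally masked) patch tokens.

    Parameters
    ----------
    tokens : P x C token matrix (row-major grid order).
    metric : one of :data:`METRICS`.
    mask : optional boolean vector of length P or integer index vector
        selecting the vertices to retain (e.g. foreground tokens).
    """
    tokens = np.asarray(tokens, dtype=np.float64)
    if tokens.ndim != 2:
        raise ValueError("tokens must be a P x C matrix")
    if mask is None:
        idx = np.arange(tokens.shape[0])
    else:
        mask = np.asarray(mask)
        idx = np.flatnonzero(mask) if mask.dtype == bool else mask.astype(np.int64)
    if idx.size < 2:
        raise ValueError(f"need at least 2 retained vertices, got {idx.size}")
    sub = tokens[idx]
    w = pairwise_similarity(sub, metric)
    w = 0.5 * (w + w.T)  # enforce exact symmetry against fp round-off
    return AffinityMatrix(weights=w, metric=metric, vertex_index=idx)
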