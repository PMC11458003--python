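"""Spectral graph partitioning of patch-affinity graphs.

The patch grid is a weighted graph G = (V, E) whose adjacency is an
affinity matrix W.  With D = diag(row sums of W), the unnormalized
Laplacian is L = D - W and the symmetric normalized Laplacian is
I - D^{-1/2} W D^{-1/2}.  Eigenvectors of L ("eigensegments") reshaped
onto the grid decompose the image into soft segments:

* foreground/background: the sign pattern of the Fiedler eigenvector y_1
  bipartitions the graph, approximating the normalized cut;
* instances: foreground tokens are embedded in (y_1, ..., y_4) and
  clustered with k-means.

Post-processing for the binary task: a border-majority heuristic flips
masks whose "foreground" covers most of the image border, and a 5x5
median (majority) filter removes small spurious regions.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy import linalg as sla
from scipy import ndimage
from sklearn.cluster import KMeans

from specseg.affinity import AffinityMatrix, build_affinity
from specseg.feature_model import FeatureMap, LabelMap, flatten_tokens, require_same_grid

__all__ = [
    "GraphSpectrum",
    "DegenerateSpectrumError",
    "laplacian",
    "eigensegments",
    "fgbg_segment",
    "orientation_fix",
    "median_post",
    "instance_segment",
]

_ZERO_DEGREE_EPS = 1e-12


class DegenerateSpectrumError(ValueError):
    """The affinity graph admits no meaningful cut (e.g. constant features)."""


@dataclasses.dataclass(frozen=True)
class GraphSpectrum:
    """The smallest eigenpairs of a graph Laplacian, ascending.

    ``eigenvectors[:, i]`` is y_i.  Signs are fixed deterministically:
    each eigenvector is negated if its largest-magnitude entry is
    negative, so repeated runs are bit-identical.
    """

    laplacian_kind: str
    eigenvalues: np.ndarray
    eigenvectors: np.ndarray

    @property
    def n_vectors(self) -> int:
        return self.eigenvalues.size

    def fiedler(self) -> np.ndarray:
        if self.n_vectors < 2:
            raise ValueError("spectrum holds fewer than 2 eigenpairs")
        return self.eigenvectors[:, 1]


def laplacian(w: AffinityMatrix | np.ndarray, kind: str = "normalized_sym") -> np.ndarray:
    """Graph Laplacian of an affinity matrix.

    ``kind="unnormalized"`` gives L = D - W with D the diagonal of row
    sums (self-loops included in the degree); ``kind="normalized_sym"``
    gives I - D^{-1/2} W D^{-1/2}, guarding zero-degree vertices with a
    tiny epsilon degree.
    """
    mat = w.weights if isinstance(w, AffinityMatrix) else np.asarray(w, dtype=np.float64)
    if mat.ndim != 2 or mat.shape[0] != mat.shape[1]:
        raise ValueError("affinity must be square")
    if not np.allclose(mat, mat.T, atol=1e-9):
        raise ValueError("affinity must be symmetric")
    if mat.min() < -1e-12:
        raise ValueError("affinity must be nonnegative")
    deg = mat.sum(axis=1)
    if kind == "unnormalized":
        return np.diag(deg) - mat
    if kind == "normalized_sym":
        d = np.maximum(deg, _ZERO_DEGREE_EPS)
        inv_sqrt = 1.0 / np.sqrt(d)
        lap = np.eye(mat.shape[0]) - (inv_sqrt[:, None] * mat * inv_sqrt[None, :])
        return 0.5 * (lap + lap.T)
    raise ValueError(f"unknown laplacian kind {kind!r}")


def _fix_signs(vecs: np.ndarray) -> np.ndarray:
    out = vecs.copy()
    for i in range(out.shape[1]):
        v = out[:, i]
        j = int(np.argmax(np.abs(v)))
        if v[j] < 0:
            out[:, i] = -v
    return out


def eigensegments(
    lap: np.ndarray, n_vec: int, kind: str = "normalized_sym"
) -> GraphSpectrum:
    """Smallest ``n_vec`` eigenpairs of a symmetric Laplacian, ascending.

    Dense symmetric eigendecomposition; deterministic sign fixing.
    """
    lap = np.asarray(lap, dtype=np.float64)
    p = lap.shape[0]
    if lap.ndim != 2 or lap.shape[1] != p:
        raise ValueError("laplacian must be square")
    if not 1 <= n_vec <= p:
        raise ValueError(f"n_vec={n_vec} out of range [1, {p}]")
    vals, vecs = sla.eigh(lap, subset_by_index=(0, n_vec - 1))
    return GraphSpectrum(
        laplacian_kind=kind, eigenvalues=vals, eigenvectors=_fix_signs(vecs)
    )


def fgbg_segment(
    fmap: FeatureMap,
    laplacian_kind: str = "normalized_sym",
    postprocess: bool = True,
    median_kernel: int = 5,
) -> LabelMap:
    """Binary foreground/background segmentation via the Fiedler eigenvector.

    Builds the dot-product affinity over the map's tokens, takes the
    eigenvector of the second-smallest Laplacian eigenvalue, thresholds it
    at 0 (falling back to the median if one side would be empty), applies
    the border-orientation fix and, optionally, the median filter.
    """
    tokens = flatten_tokens(fmap)
    if np.allclose(tokens, tokens[0]):
        raise DegenerateSpectrumError("constant feature map admits no cut")
    aff = build_affinity(tokens, metric="dot")
    spec = eigensegments(laplacian(aff, laplacian_kind), n_vec=2, kind=laplacian_kind)
    y1 = spec.fiedler()
    if np.ptp(y1) < 1e-10:
        raise DegenerateSpectrumError("Fiedler eigenvector is constant; no cut exists")
    fg = y1 > 0.0
    if fg.all() or not fg.any():
        fg = y1 > np.median(y1)
    if fg.all() or not fg.any():
        raise DegenerateSpectrumError("Fiedler thresholding produced a single side")
    mask = LabelMap(fg.reshape(fmap.height, fmap.width).astype(np.int64), semantics="fg_bg")
    mask = orientation_fix(mask)
    if postprocess:
        mask = median_post(mask, k=median_kernel)
    return mask


def orientation_fix(mask: LabelMap) -> LabelMap:
    """Swap labels if foreground covers strictly more than half the border.

    The Fiedler sign split is orientation-free; the object of interest is
    assumed not to dominate the image border, so a border-majority
    "foreground" is relabelled as background.  Ties keep the input.
    """
    if mask.semantics != "fg_bg":
        raise ValueError("orientation_fix expects a binary fg_bg mask")
    lab = mask.labels
    border = np.concatenate([lab[0, :], lab[-1, :], lab[1:-1, 0], lab[1:-1, -1]])
    if border.sum() * 2 > border.size:
        return LabelMap(1 - lab, semantics="fg_bg")
    return mask


def median_post(mask: LabelMap, k: int = 5) -> LabelMap:
    """Majority (median) filter over a k x k window with reflected borders."""
    if mask.semantics != "fg_bg":
        raise ValueError("median_post expects a binary fg_bg mask")
    if k % 2 == 0:
        raise ValueError("kernel size must be odd")
    out = ndimage.median_filter(mask.labels.astype(np.uint8), size=k, mode="reflect")
    return LabelMap(out.astype(np.int64), semantics="fg_bg")


def _auto_k(lap: np.ndarray, max_k: int = 8) -> int:
    """Eigengap heuristic over lambda_1..lambda_max_k.

    The trivial gap above lambda_0 = 0 is excluded; k is the index whose
    following gap is largest, i.e. the number of eigenvalues sitting
    below the biggest spectral jump.
    """
    p = lap.shape[0]
    n_vec = min(max_k + 1, p)
    spec = eigensegments(lap, n_vec=n_vec)
    gaps = np.diff(spec.eigenvalues[1:])  # gap after lambda_i, i >= 1
    if gaps.size == 0:
        return 1
    return int(np.argmax(gaps)) + 2


def instance_segment(
    fmap: FeatureMap,
    fg: LabelMap,
    metric: str = "boc",
    k_instances: int | str = "auto",
    laplacian_kind: str = "normalized_sym",
    n_eigensegments: int = 4,
    seed: int = 0,
    n_restarts: int = 10,
) -> LabelMap:
    """Cluster foreground tokens into instances in eigensegment space.

    The affinity (under ``metric``) is built over foreground tokens only
    -- the graph restriction equivalent of multiplying the feature map by
    the foreground mask.  Tokens are embedded in the eigenvectors
    y_1 ... y_{n_eigensegments} of the Laplacian (y_0 is discarded as
    noise) and clustered with seeded k-means.  Background keeps label 0;
    instances are labelled 1..k in order of first appearance along the
    row-major grid.
    """
    require_same_grid(fmap, fg)
    tokens = flatten_tokens(fmap)
    fg_idx = np.flatnonzero(fg.labels.ravel() > 0)
    if fg_idx.size < 2:
        raise ValueError("foreground must contain at least 2 tokens")
    aff = build_affinity(tokens, metric=metric, mask=fg_idx)
    lap = laplacian(aff, laplacian_kind)
    if k_instances == "auto":
        k = _auto_k(lap)
    else:
        k = int(k_instances)
    if k < 1:
        raise ValueError("k_instances must be >= 1")
    if fg_idx.size < k:
        raise ValueError(f"foreground has {fg_idx.size} tokens, fewer than k={k}")
    out = np.zeros(tokens.shape[0], dtype=np.int64)
    if k == 1:
        out[fg_idx] = 1
        return LabelMap(out.reshape(fmap.height, fmap.width), semantics="instance")
    n_vec = min(n_eigensegments + 1, fg_idx.size)
    spec = eigensegments(lap, n_vec=n_vec, kind=laplacian_kind)
    embedding = spec.eigenvectors[:, 1:n_vec]
    km = KMeans(n_clusters=k, n_init=n_restarts, random_state=seed)
    raw = km.fit_predict(embedding)
    # relabel clusters by first appearance so labels are permutation-stable
    relabel: dict[int, int] = {}
    for c in raw:
        if int(c) not in relabel:
            relabel[int(c)] = len(relabel) + 1
    out[fg_idx] = np.array([relabel[int(c)] for c in raw])
    return LabelMap(out.reshape(fmap.height, fmap.width), semantics="instance")
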