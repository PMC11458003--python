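"""Core data types and I/O for feature maps, label masks, and reports.

Conventions fixed here and relied on everywhere else:

* grids are indexed ``(row, col[, channel])``, 0-based;
* tokens are the row-major flattening of the patch grid, so token
  ``p`` sits at ``(p // W, p % W)``;
* label masks use 0 for background; foreground/background masks contain
  only {0, 1}; instance masks use positive (not necessarily contiguous)
  integer labels.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Mapping

import numpy as np
from PIL import Image

__all__ = [
    "FeatureMap",
    "LabelMap",
    "EvalReport",
    "read_feature_map",
    "write_feature_map",
    "read_label_map",
    "write_label_map",
    "flatten_tokens",
    "unflatten_tokens",
]

_MAX_LABEL = np.iinfo(np.uint16).max


@dataclasses.dataclass(frozen=True)
class FeatureMap:
    """A dense H x W x C grid of real-valued per-patch descriptors."""

    values: np.ndarray
    provenance: str = ""

    def __post_init__(self) -> None:
        arr = np.asarray(self.values, dtype=np.float64)
        if arr.ndim != 3:
            raise ValueError(f"feature map must be 3-D (H, W, C), got shape {arr.shape}")
        if min(arr.shape) < 1:
            raise ValueError(f"feature map dimensions must be >= 1, got {arr.shape}")
        if not np.all(np.isfinite(arr)):
            raise ValueError("feature map contains non-finite values")
        object.__setattr__(self, "values", arr)

    @property
    def height(self) -> int:
        return self.values.shape[0]

    @property
    def width(self) -> int:
        return self.values.shape[1]

    @property
    def channels(self) -> int:
        return self.values.shape[2]

    @property
    def n_tokens(self) -> int:
        return self.height * self.width

    def select_channels(self, idx: Iterable[int], provenance: str | None = None) -> "FeatureMap":
        """Return a new map keeping channels ``idx`` in the given order."""
        idx = np.asarray(list(idx), dtype=int)
        return FeatureMap(
            self.values[:, :, idx],
            provenance=self.provenance if provenance is None else provenance,
        )


@dataclasses.dataclass(frozen=True)
class LabelMap:
    """An integer mask over the patch grid.

    ``semantics`` is ``"fg_bg"`` (labels in {0, 1}) or ``"instance"``
    (0 = background, positive integers = instances).
    """

    labels: np.ndarray
    semantics: str = "instance"

    def __post_init__(self) -> None:
        arr = np.asarray(self.labels)
        if arr.ndim != 2:
            raise ValueError(f"label map must be 2-D, got shape {arr.shape}")
        if not np.issubdtype(arr.dtype, np.integer):
            if not np.all(arr == np.round(arr)):
                raise ValueError("labels must be integers")
            arr = arr.astype(np.int64)
        if arr.min(initial=0) < 0:
            raise ValueError("labels must be nonnegative")
        if self.semantics not in ("fg_bg", "instance"):
            raise ValueError(f"unknown semantics {self.semantics!r}")
        if self.semantics == "fg_bg" and arr.max(initial=0) > 1:
            raise ValueError("fg_bg masks may only contain labels 0 and 1")
        object.__setattr__(self, "labels", arr.astype(np.int64))

    @property
    def height(self) -> int:
        return self.labels.shape[0]

    @property
    def width(self) -> int:
        return self.labels.shape[1]

    def instance_labels(self) -> np.ndarray:
        """Sorted positive labels present in the mask."""
        u = np.unique(self.labels)
        return u[u > 0]


@dataclasses.dataclass(frozen=True)
class EvalReport:
    """Segmentation quality report.

    F-score fields describe the foreground/background task; ``miou``,
    ``matching`` and ``per_instance_iou`` describe Hungarian-matched
    instance evaluation.  Fields not applicable to a task are None/empty.
    """

    precision: float = 0.0
    recall: float = 0.0
    f_score: float = 0.0
    miou: float | None = None
    matching: tuple[tuple[int, int], ...] = ()
    per_instance_iou: Mapping[int, float] = dataclasses.field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "precision": self.precision,
            "recall": self.recall,
            "f_score": self.f_score,
            "miou": self.miou,
            "matching": [list(pair) for pair in self.matching],
            "per_instance_iou": {str(k): v for k, v in self.per_instance_iou.items()},
        }

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))

    @classmethod
    def from_json(cls, path: str | Path) -> "EvalReport":
        d = json.loads(Path(path).read_text())
        return cls(
            precision=d["precision"],
            recall=d["recall"],
            f_score=d["f_score"],
            miou=d["miou"],
            matching=tuple((int(a), int(b)) for a, b in d["matching"]),
            per_instance_iou={int(k): v for k, v in d["per_instance_iou"].items()},
        )


def flatten_tokens(fmap: FeatureMap) -> np.ndarray:
    """Flatten an H x W x C map to a P x C token matrix, row-major."""
    return fmap.values.reshape(fmap.n_tokens, fmap.channels)


def unflatten_tokens(
    tokens: np.ndarray, height: int, width: int, provenance: str = ""
) -> FeatureMap:
    """Inverse of :func:`flatten_tokens`; validates the grid shape."""
    tokens = np.asarray(tokens, dtype=np.float64)
    if tokens.ndim != 2:
        raise ValueError(f"token matrix must be 2-D, got shape {tokens.shape}")
    if tokens.shape[0] != height * width:
        raise ValueError(
            f"token count {tokens.shape[0]} does not match grid {height}x{width}"
        )
    return FeatureMap(tokens.reshape(height, width, tokens.shape[1]), provenance=provenance)


def read_feature_map(path: str | Path, layout: str = "grid") -> FeatureMap:
    """Read a feature map from a ``.npy`` or ``.npz`` file.

    ``.npy`` files must hold a 3-D (H, W, C) array.  ``.npz`` files hold
    either a 3-D ``values`` array or a 2-D P x C ``tokens`` array plus a
    ``shape`` entry ``(H, W)``; tokens are assumed row-major.

    Parameters
    ----------
    path : file path
    layout : "grid" or "tokens"; for bare ``.npy`` files "tokens" is
        rejected because the grid shape is unrecoverable.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if path.suffix == ".npz":
        with np.load(path) as data:
            if "values" in data:
                return FeatureMap(data["values"], provenance=str(path))
            if "tokens" in data:
                if "shape" not in data:
                    raise ValueError("token-matrix file lacks grid 'shape' metadata")
                h, w = (int(x) for x in data["shape"])
                return unflatten_tokens(data["tokens"], h, w, provenance=str(path))
            raise ValueError("npz file must contain 'values' or 'tokens'+'shape'")
    arr = np.load(path)
    if layout == "tokens":
        raise ValueError("2-D token input requires an .npz file with grid 'shape' metadata")
    if arr.ndim != 3:
        raise ValueError(f"expected a 3-D (H, W, C) array, got rank {arr.ndim}")
    return FeatureMap(arr, provenance=str(path))


def write_feature_map(fmap: FeatureMap, path: str | Path) -> None:
    """Write a feature map to ``.npy`` (3-D grid) or ``.npz`` (grid + shape)."""
    path = Path(path)
    if path.suffix == ".npz":
        np.savez(path, values=fmap.values, shape=np.array([fmap.height, fmap.width]))
    else:
        np.save(path, fmap.values)


def write_label_map(mask: LabelMap, path: str | Path) -> None:
    """Write a mask as a single-channel 16-bit PNG (pixel value = label)."""
    if mask.labels.max(initial=0) > _MAX_LABEL:
        raise OverflowError(
            f"labels exceed 16-bit range (max {int(mask.labels.max())} > {_MAX_LABEL})"
        )
    img = Image.fromarray(mask.labels.astype(np.uint16))
    img.save(Path(path), format="PNG")


def read_label_map(path: str | Path, semantics: str = "instance") -> LabelMap:
    """Read a 16-bit (or 8-bit) grayscale PNG mask."""
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    arr = np.asarray(Image.open(path))
    if arr.ndim != 2:
        raise ValueError(f"mask PNG must be single-channel, got shape {arr.shape}")
    return LabelMap(arr.astype(np.int64), semantics=semantics)


def require_same_grid(fmap_or_mask, other) -> None:
    """Assert two grid-carrying objects share (H, W)."""
    a = (fmap_or_mask.height, fmap_or_mask.width)
    b = (other.height, other.width)
    if a != b:
        raise ValueError(f"grid shapes differ: {a} vs {b}")
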