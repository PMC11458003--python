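"""Evaluation metrics and scene-filtering rules.

* ``fg_fscore`` — pixel precision/recall/F-score for binary masks.
* ``hungarian_miou`` — optimal one-to-one matching of predicted to
  ground-truth instances (Hungarian algorithm on the IoU matrix), then
  the mean IoU over ground-truth instances; unmatched ground truth
  contributes 0, surplus predictions are ignored in the average.
* ``mvar_ratio`` — the mR coherence statistic: sample pixels per
  instance, compute pairwise similarities under a metric, and compare
  the mean within-instance variance to the mean between-instance
  variance.  Lower mR means the metric is more coherent inside
  instances relative to across them.
* ``scene_filter`` — drops scenes whose smallest object is under a
  fraction of the image or whose smallest/largest instance ratio is too
  low; an optional occlusion predicate over a precomputed score can be
  plugged in.
"""

from __future__ import annotations

import dataclasses
import itertools
import json
from pathlib import Path
from typing import Callable

import numpy as np
from scipy.optimize import linear_sum_assignment

from specseg.affinity import pairwise_similarity
from specseg.feature_model import EvalReport, FeatureMap, LabelMap, flatten_tokens

__all__ = [
    "SceneFilterRule",
    "MRReport",
    "fg_fscore",
    "hungarian_miou",
    "mvar_ratio",
    "scene_filter",
]


@dataclasses.dataclass(frozen=True)
class SceneFilterRule:
    """Exclusion thresholds for evaluation scenes."""

    min_object_fraction: float = 0.07
    min_instance_ratio: float = 0.3
    occlusion_predicate: Callable[[float], bool] | None = None

    def __post_init__(self) -> None:
        for v in (self.min_object_fraction, self.min_instance_ratio):
            if not 0.0 < v <= 1.0:
                raise ValueError("filter thresholds must lie in (0, 1]")


@dataclasses.dataclass(frozen=True)
class MRReport:
    """Intra/inter-instance similarity-variance statistic."""

    mvar_intra: float
    mvar_inter: float
    mr: float
    n_pixels_per_instance: int
    seed: int
    metric: str

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)

    def to_json(self, path: str | Path) -> None:
        Path(path).write_text(json.dumps(self.to_dict(), indent=2))


def _check_same_shape(pred: LabelMap, gt: LabelMap) -> None:
    if pred.labels.shape != gt.labels.shape:
        raise ValueError(
            f"shape mismatch: pred {pred.labels.shape} vs gt {gt.labels.shape}"
        )


def fg_fscore(pred: LabelMap, gt: LabelMap) -> EvalReport:
    """Precision, recall and F-score over foreground pixels.

    Empty predicted foreground gives precision 0; empty overlap gives
    F = 0.  Any positive label counts as foreground, so instance masks
    can be scored too.
    """
    _check_same_shape(pred, gt)
    p = pred.labels > 0
    g = gt.labels > 0
    tp = int(np.sum(p & g))
    n_pred = int(p.sum())
    n_gt = int(g.sum())
    precision = tp / n_pred if n_pred else 0.0
    recall = tp / n_gt if n_gt else 0.0
    f = 2 * precision * recall / (precision + recall) if precision + recall else 0.0
    return EvalReport(precision=precision, recall=recall, f_score=f)


def _iou_matrix(gt: LabelMap, pred: LabelMap) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    gl = gt.instance_labels()
    pl = pred.instance_labels()
    iou = np.zeros((gl.size, pl.size))
    for i, a in enumerate(gl):
        ga = gt.labels == a
        for j, b in enumerate(pl):
            pb = pred.labels == b
            inter = np.sum(ga & pb)
            if inter:
                iou[i, j] = inter / np.sum(ga | pb)
    return iou, gl, pl


def hungarian_miou(pred: LabelMap, gt: LabelMap) -> EvalReport:
    """Hungarian-matched mean IoU of instances.

    Builds the ground-truth x prediction IoU matrix, finds the one-to-one
    assignment maximizing total IoU, and averages the matched IoU over
    *all* ground-truth instances (unmatched ones contribute 0).
    Background (label 0) is excluded throughout.
    """
    _check_same_shape(pred, gt)
    iou, gl, pl = _iou_matrix(gt, pred)
    if gl.size == 0:
        raise ValueError("ground truth has no instances")
    matching: list[tuple[int, int]] = []
    per_instance = {int(a): 0.0 for a in gl}
    if pl.size:
        rows, cols = linear_sum_assignment(-iou)
        for i, j in zip(rows, cols):
            matching.append((int(gl[i]), int(pl[j])))
            per_instance[int(gl[i])] = float(iou[i, j])
    miou = float(np.mean(list(per_instance.values())))
    fs = fg_fscore(pred, gt)
    return EvalReport(
        precision=fs.precision,
        recall=fs.recall,
        f_score=fs.f_score,
        miou=miou,
        matching=tuple(matching),
        per_instance_iou=per_instance,
    )


def mvar_ratio(
    fmap: FeatureMap,
    gt: LabelMap,
    metric: str = "boc",
    n: int = 10,
    seed: int = 0,
) -> MRReport:
    """mR statistic: mean intra-instance similarity variance over mean
    inter-instance similarity variance.

    ``n`` pixels are sampled (seeded, without replacement) from each
    ground-truth instance.  For each instance, the variance of the
    pairwise similarity values within its sample is computed; the mean
    over instances is ``mvar_intra``.  For each instance pair, the
    variance of the cross-instance similarity values is computed; the
    mean over pairs is ``mvar_inter``.
    """
    if fmap.values.shape[:2] != gt.labels.shape:
        raise ValueError("feature map and mask shapes differ")
    labels = gt.instance_labels()
    if labels.size < 2:
        raise ValueError("mR requires at least 2 instances")
    tokens = flatten_tokens(fmap)
    flat_gt = gt.labels.ravel()
    rng = np.random.default_rng(seed)
    samples: dict[int, np.ndarray] = {}
    for lab in labels:
        idx = np.flatnonzero(flat_gt == lab)
        if idx.size < n:
            raise ValueError(f"instance {int(lab)} has {idx.size} pixels < n={n}")
        samples[int(lab)] = rng.choice(idx, size=n, replace=False)
    intra = []
    for lab in labels:
        sim = pairwise_similarity(tokens[samples[int(lab)]], metric)
        iu = np.triu_indices(n, k=1)
        intra.append(float(np.var(sim[iu])))
    inter = []
    for a, b in itertools.combinations([int(x) for x in labels], 2):
        both = np.concatenate([samples[a], samples[b]])
        sim = pairwise_similarity(tokens[both], metric)
        cross = sim[:n, n:]
        inter.append(float(np.var(cross)))
    mvar_intra = float(np.mean(intra))
    mvar_inter = float(np.mean(inter))
    if mvar_inter > 0:
        mr = mvar_intra / mvar_inter
    else:
        # degenerate inter spread: perfectly coherent metric scores 0
        mr = 0.0 if mvar_intra == 0 else float("inf")
    return MRReport(
        mvar_intra=mvar_intra,
        mvar_inter=mvar_inter,
        mr=mr,
        n_pixels_per_instance=n,
        seed=seed,
        metric=metric,
    )


def scene_filter(
    gt: LabelMap,
    rule: SceneFilterRule = SceneFilterRule(),
    occlusion_score: float | None = None,
) -> tuple[bool, list[str]]:
    """Decide whether a scene's ground truth qualifies for evaluation.

    Returns ``(keep, reasons)``; ``reasons`` lists every failed
    criterion.  A scene is dropped if any instance occupies less than
    ``min_object_fraction`` of the image, or if the smallest-to-largest
    instance size ratio falls below ``min_instance_ratio``, or if the
    optional occlusion predicate rejects the supplied score.
    """
    labels = gt.instance_labels()
    if labels.size == 0:
        raise ValueError("ground truth has no instances")
    total = gt.labels.size
    sizes = np.array([np.sum(gt.labels == lab) for lab in labels], dtype=float)
    reasons: list[str] = []
    if (sizes / total).min() < rule.min_object_fraction:
        reasons.append(
            f"smallest object fraction {sizes.min() / total:.4f} "
            f"< {rule.min_object_fraction}"
        )
    ratio = sizes.min() / sizes.max()
    if ratio < rule.min_instance_ratio:
        reasons.append(
            f"instance size ratio {ratio:.4f} < {rule.min_instance_ratio}"
        )
    if rule.occlusion_predicate is not None and occlusion_score is not None:
        if not rule.occlusion_predicate(occlusion_score):
            reasons.append(f"occlusion score {occlusion_score} rejected")
    return (len(reasons) == 0, reasons)
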