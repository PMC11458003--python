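"""Channel pruning for backbone feature maps.

Two complementary criteria:

* **NCR** (noise channel reduction) keeps the ``M`` channels with the
  *lowest* histogram entropy.  A channel's values are binned into ``B``
  equal-width bins over its own [min, max]; entropy is
  ``-sum_b p_b log2 p_b``.  High-entropy channels look like noise.
* **DCR** (deviation-based channel reduction) keeps the ``N`` channels
  with the *highest* population standard deviation: near-constant
  channels cannot separate instances.

The Delta diagnostic quantifies, per channel, the mean absolute pairwise
difference of per-instance mean values given a ground-truth mask; it is
the per-channel instance contrast the DCR criterion is a proxy for.
"""

from __future__ import annotations

import dataclasses
import itertools

import numpy as np

from specseg.feature_model import FeatureMap, LabelMap

__all__ = [
    "HistogramSpec",
    "ChannelScores",
    "channel_pdf",
    "channel_entropy",
    "channel_std",
    "instance_delta",
    "ncr_select",
    "dcr_select",
]


@dataclasses.dataclass(frozen=True)
class HistogramSpec:
    """Binning used for channel entropy: B equal-width bins over the
    channel's own [min, max] (so entropy is invariant to affine rescaling)."""

    bins: int = 30

    def __post_init__(self) -> None:
        if self.bins < 2:
            raise ValueError("need at least 2 bins")

    @property
    def max_entropy(self) -> float:
        return float(np.log2(self.bins))


@dataclasses.dataclass(frozen=True)
class ChannelScores:
    """Per-channel scores and the selection ranking.

    ``order`` is the permutation of original channel indices sorted by the
    selection criterion (ascending entropy for NCR, descending STD for
    DCR), ties broken by original index.  ``kept`` are the retained
    original indices in their original relative order.
    """

    entropy: np.ndarray | None = None
    std: np.ndarray | None = None
    delta: np.ndarray | None = None
    order: np.ndarray | None = None
    kept: np.ndarray | None = None

    def to_dict(self) -> dict:
        out: dict = {}
        for name in ("entropy", "std", "delta"):
            v = getattr(self, name)
            out[name] = None if v is None else [float(x) for x in v]
        for name in ("order", "kept"):
            v = getattr(self, name)
            out[name] = None if v is None else [int(x) for x in v]
        return out


def _as_channel(channel: np.ndarray) -> np.ndarray:
    arr = np.asarray(channel, dtype=np.float64)
    if arr.size == 0:
        raise ValueError("empty channel")
    if not np.all(np.isfinite(arr)):
        raise ValueError("channel contains non-finite values")
    return arr.ravel()


def channel_pdf(channel: np.ndarray, spec: HistogramSpec = HistogramSpec()) -> np.ndarray:
    """Histogram of a channel normalized to a probability vector.

    A constant channel puts all its mass in a single bin.
    """
    x = _as_channel(channel)
    lo, hi = x.min(), x.max()
    if lo == hi:
        pdf = np.zeros(spec.bins)
        pdf[0] = 1.0
        return pdf
    counts, _ = np.histogram(x, bins=spec.bins, range=(lo, hi))
    return counts / x.size


def channel_entropy(channel: np.ndarray, spec: HistogramSpec = HistogramSpec()) -> float:
    """Shannon entropy (bits) of the channel's bin-occupancy distribution.

    Zero-probability bins contribute nothing; the result lies in
    [0, log2 B].
    """
    pdf = channel_pdf(channel, spec)
    nz = pdf[pdf > 0]
    return float(-np.sum(nz * np.log2(nz)))


def channel_std(channel: np.ndarray) -> float:
    """Population standard deviation (divisor H*W) of a channel."""
    x = _as_channel(channel)
    return float(np.sqrt(np.mean((x - x.mean()) ** 2)))


def instance_delta(channel: np.ndarray, gt: LabelMap) -> float:
    """Mean absolute pairwise difference between per-instance channel means.

    Background (label 0) is excluded; fewer than two instances give 0.
    """
    arr = np.asarray(channel, dtype=np.float64)
    if arr.shape != gt.labels.shape:
        raise ValueError(f"channel shape {arr.shape} != mask shape {gt.labels.shape}")
    labels = gt.instance_labels()
    if labels.size == 0:
        raise ValueError("ground truth has no instances")
    if labels.size < 2:
        return 0.0
    means = [arr[gt.labels == lab].mean() for lab in labels]
    diffs = [abs(a - b) for a, b in itertools.combinations(means, 2)]
    return float(np.mean(diffs))


def _entropies(fmap: FeatureMap, spec: HistogramSpec) -> np.ndarray:
    return np.array(
        [channel_entropy(fmap.values[:, :, c], spec) for c in range(fmap.channels)]
    )


def _stds(fmap: FeatureMap) -> np.ndarray:
    flat = fmap.values.reshape(-1, fmap.channels)
    return np.sqrt(np.mean((flat - flat.mean(axis=0)) ** 2, axis=0))


def ncr_select(
    fmap: FeatureMap, m: int, spec: HistogramSpec = HistogramSpec()
) -> tuple[FeatureMap, ChannelScores]:
    """Keep the ``m`` lowest-entropy channels of ``fmap``.

    Kept channels retain their original relative order.  Ties in entropy
    are broken by original channel index (stable sort), so the selection
    is deterministic.
    """
    if not 1 <= m <= fmap.channels:
        raise ValueError(f"M={m} out of range [1, {fmap.channels}]")
    ent = _entropies(fmap, spec)
    order = np.argsort(ent, kind="stable")
    kept = np.sort(order[:m])
    scores = ChannelScores(entropy=ent, order=order, kept=kept)
    return fmap.select_channels(kept), scores


def dcr_select(fmap: FeatureMap, n: int) -> tuple[FeatureMap, ChannelScores]:
    """Keep the ``n`` highest-STD channels of ``fmap``.

    Kept channels retain their original relative order; STD ties are
    broken by original channel index.
    """
    if not 1 <= n <= fmap.channels:
        raise ValueError(f"N={n} out of range [1, {fmap.channels}]")
    std = _stds(fmap)
    order = np.argsort(-std, kind="stable")
    kept = np.sort(order[:n])
    scores = ChannelScores(std=std, order=order, kept=kept)
    return fmap.select_channels(kept), scores
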