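"""Seeded synthetic scenes with backbone-like feature maps.

Real self-supervised backbones (e.g. ViT-s16) emit an H x W grid of
C-dimensional patch tokens whose channels are of very different quality.
The generator emulates the four channel populations the segmentation
pipeline must cope with:

* **signal** channels: piecewise-constant per region with zero-centered
  instance means (separated by a per-channel contrast, background near 0)
  plus Gaussian pixel noise — low histogram entropy, the highest STD, and
  the sign cancellation across instances that distribution-aware metrics
  exploit;
* **fg/bg-signature** channels: uniformly high on every instance (resp.
  on the background) and low elsewhere — the shared "objectness" and
  "stuff" directions that make foreground (resp. background) tokens
  mutually similar under dot products, as in real backbone features;
* **noise** channels: uniform random values — maximal entropy;
* **lowstd** channels: a constant plus a tiny Gaussian — no instance
  information, near-zero STD;
* **irregular** channels: a signal channel with sparse +/- spikes inside
  one instance — the extreme "irregular values" that break dot-product
  affinities while leaving the feature distribution intact.

Everything is a pure function of its spec and seed, and each generated
map carries a channel manifest so selection behaviour can be verified
against ground truth.

What the generator does **not** model: spatially correlated textures,
soft instance boundaries, occlusion, or the long-range channel
correlations of a trained transformer.
"""

from __future__ import annotations

import dataclasses
from typing import Literal

import numpy as np

from specseg.feature_model import FeatureMap, LabelMap

__all__ = [
    "SceneSpec",
    "ChannelMixSpec",
    "SyntheticScene",
    "make_scene",
    "make_feature_map",
    "make_benchmark_suite",
]

# fraction of the grid the union of instances may occupy; keeps a
# substantial background so the Fg-Bg stage has a cut to find
_MAX_FOREGROUND_FRACTION = 0.55


@dataclasses.dataclass(frozen=True)
class SceneSpec:
    """Layout of a ground-truth scene on the patch grid.

    The default 24 x 42 grid mirrors ViT-s16 tokenization of a
    384 x 672 frame.  Instances are connected, non-overlapping, and each
    covers at least ``min_instance_fraction`` of the grid.
    """

    height: int = 24
    width: int = 42
    k_instances: int = 3
    min_instance_fraction: float = 0.08
    layout: Literal["blobs", "grid_cells"] = "blobs"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.height < 2 or self.width < 2:
            raise ValueError("grid must be at least 2 x 2")
        if self.k_instances < 1:
            raise ValueError("need at least one instance")
        if not 0.0 < self.min_instance_fraction <= 1.0:
            raise ValueError("min_instance_fraction must lie in (0, 1]")
        if self.k_instances * self.min_instance_fraction > _MAX_FOREGROUND_FRACTION:
            raise ValueError(
                "infeasible spec: instances cannot fit while leaving background"
            )
        if self.layout not in ("blobs", "grid_cells"):
            raise ValueError(f"unknown layout {self.layout!r}")


@dataclasses.dataclass(frozen=True)
class ChannelMixSpec:
    """Composition and noise levels of a generated feature map.

    Defaults give C = 384 channels, the ViT-s16 embedding width, and
    feature values of order 1 or below -- the regime of centered backbone
    tokens, where the absolute Chebyshev term and the relative
    Bray-Curtis term of the BoC metric are commensurate.

    Each signal channel is an activation code: every instance is
    independently "on" (level ``signal_contrast``) with probability
    ``signal_on_fraction`` or "off" (level 0, like the background), so
    instance identity is a sparse binary code across channels -- the
    presence/absence regime the Bray-Curtis measure was designed for.
    Per-channel cross-instance differences stay bounded by the contrast
    (so the Chebyshev term stays small), the summed discrepancy over
    disjoint activations is large (so the Bray-Curtis term is
    discriminative), and cross-instance dot products are nonnegative,
    which keeps the foreground connected in the dot-affinity graph.
    The fg/bg-signature strengths set the active level of the
    "objectness"/"stuff" channels; they are cleaner than signal channels
    (``signature_noise_sigma``), as semantic channels of real backbones
    are.  Signature amplitudes sit below the active-signal STD so that
    deviation-based selection prefers instance-discriminative channels,
    while entropy-based selection still retains the signatures that hold
    the foreground and background components together in the
    dot-affinity graph.  ``spike_magnitude`` is roughly ten times the
    signal contrast, so spiked pixels are genuine outliers for
    value-sensitive metrics.
    """

    n_signal: int = 140
    n_fg_signal: int = 40
    n_bg_signal: int = 40
    n_noise: int = 100
    n_lowstd: int = 40
    n_irregular: int = 24
    signal_contrast: float = 0.5
    signal_on_fraction: float = 0.3
    fg_signature_strength: float = 0.2
    bg_signature_strength: float = 0.25
    signature_noise_sigma: float = 0.003
    noise_amplitude: float = 2.0
    lowstd_sigma: float = 0.01
    spike_magnitude: float = 5.0
    spike_rate: float = 0.15
    pixel_noise_sigma: float = 0.01
    seed: int = 0

    def __post_init__(self) -> None:
        counts = (
            self.n_signal,
            self.n_fg_signal,
            self.n_bg_signal,
            self.n_noise,
            self.n_lowstd,
            self.n_irregular,
        )
        if any(c < 0 for c in counts):
            raise ValueError("channel counts must be nonnegative")
        if self.n_signal < 1:
            raise ValueError("need at least one signal channel")
        if not 0.0 <= self.spike_rate <= 1.0:
            raise ValueError("spike_rate must lie in [0, 1]")

    @property
    def n_channels(self) -> int:
        return (
            self.n_signal
            + self.n_fg_signal
            + self.n_bg_signal
            + self.n_noise
            + self.n_lowstd
            + self.n_irregular
        )


@dataclasses.dataclass(frozen=True)
class SyntheticScene:
    """A generated benchmark scene: ground truth, features, provenance."""

    gt: LabelMap
    fg: LabelMap
    features: FeatureMap
    manifest: tuple[dict, ...]
    scene_spec: SceneSpec
    mix_spec: ChannelMixSpec

    @property
    def k_instances(self) -> int:
        return self.scene_spec.k_instances

    def channel_indices(self, kind: str) -> np.ndarray:
        """Original indices of channels of one class ('signal', 'noise', ...)."""
        return np.array([m["index"] for m in self.manifest if m["kind"] == kind])


def _grow_blobs(spec: SceneSpec, rng: np.random.Generator) -> np.ndarray | None:
    h, w, k = spec.height, spec.width, spec.k_instances
    total = h * w
    min_size = int(np.ceil(spec.min_instance_fraction * total))
    budget = int(_MAX_FOREGROUND_FRACTION * total)
    targets = [
        int(round(min_size * rng.uniform(1.0, 1.5))) for _ in range(k)
    ]
    if sum(targets) > budget:
        scale = budget / sum(targets)
        targets = [max(min_size, int(t * scale)) for t in targets]
        if sum(targets) > budget:
            targets = [min_size] * k
    labels = np.zeros((h, w), dtype=np.int64)
    # seeds: rejection-sample for mutual separation
    seeds: list[tuple[int, int]] = []
    sep = max(2, int(0.25 * min(h, w)))
    for _ in range(500):
        r, c = int(rng.integers(1, h - 1)), int(rng.integers(1, w - 1))
        if all(max(abs(r - r0), abs(c - c0)) >= sep for r0, c0 in seeds):
            seeds.append((r, c))
        if len(seeds) == k:
            break
    if len(seeds) < k:
        return None
    frontiers: list[list[tuple[int, int]]] = []
    sizes = [0] * k
    for i, (r, c) in enumerate(seeds):
        labels[r, c] = i + 1
        sizes[i] = 1
        frontiers.append([(r, c)])
    active = True
    while active:
        active = False
        for i in range(k):
            if sizes[i] >= targets[i]:
                continue
            # pick a random free neighbour of the blob frontier
            while frontiers[i]:
                j = int(rng.integers(len(frontiers[i])))
                r, c = frontiers[i][j]
                free = [
                    (rr, cc)
                    for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1))
                    if 0 <= rr < h and 0 <= cc < w and labels[rr, cc] == 0
                ]
                if not free:
                    frontiers[i].pop(j)
                    continue
                rr, cc = free[int(rng.integers(len(free)))]
                labels[rr, cc] = i + 1
                sizes[i] += 1
                frontiers[i].append((rr, cc))
                active = True
                break
    if any(s < min_size for s in sizes):
        return None
    return labels


def _grid_cells(spec: SceneSpec) -> np.ndarray:
    h, w, k = spec.height, spec.width, spec.k_instances
    labels = np.zeros((h, w), dtype=np.int64)
    band = w // k
    if band < 4 or h < 4:
        raise ValueError("grid too small for grid_cells layout")
    for i in range(k):
        c0 = i * band + 1
        c1 = (i + 1) * band - 1
        labels[1 : h - 1, c0:c1] = i + 1
    min_size = int(np.ceil(spec.min_instance_fraction * h * w))
    if (h - 2) * (band - 2) < min_size:
        raise ValueError("grid_cells instances smaller than min_instance_fraction")
    return labels


def make_scene(spec: SceneSpec) -> tuple[LabelMap, LabelMap]:
    """Generate a ground-truth instance mask and its binary fg mask.

    ``blobs`` grows k connected random blobs from separated seeds;
    ``grid_cells`` tiles k rectangles.  Deterministic in ``spec.seed``.
    """
    if spec.layout == "grid_cells":
        labels = _grid_cells(spec)
    else:
        labels = None
        for attempt in range(50):
            rng = np.random.default_rng((spec.seed, attempt))
            labels = _grow_blobs(spec, rng)
            if labels is not None:
                break
        if labels is None:
            raise ValueError(f"could not realise scene spec {spec}")
    gt = LabelMap(labels, semantics="instance")
    fg = LabelMap((labels > 0).astype(np.int64), semantics="fg_bg")
    return gt, fg


def _signal_channel(
    region: np.ndarray, k: int, mix: ChannelMixSpec, rng: np.random.Generator
) -> np.ndarray:
    """Instance-discriminative channel: sparse on/off activation code.

    Each channel draws its own contrast scale and independently
    activates each instance with probability ``signal_on_fraction``;
    inactive instances sit at the background level near 0.
    """
    scale = mix.signal_contrast * rng.uniform(0.9, 1.1)
    means = np.empty(k + 1)
    means[0] = rng.uniform(-0.02, 0.02)
    while True:
        on = rng.random(k) < mix.signal_on_fraction
        if on.any():  # a signal channel activates at least one instance
            break
    means[1:] = np.where(on, scale, 0.0)
    ch = means[region]
    if mix.pixel_noise_sigma > 0:
        ch = ch + rng.normal(0.0, mix.pixel_noise_sigma, size=ch.shape)
    return ch


def _signature_channel(
    region: np.ndarray, mix: ChannelMixSpec, rng: np.random.Generator, on_fg: bool
) -> np.ndarray:
    """Objectness/stuff channel: one level on all instances, another on bg."""
    strength = mix.fg_signature_strength if on_fg else mix.bg_signature_strength
    high = strength * rng.uniform(0.8, 1.2)
    low = 0.02 * rng.uniform(0.5, 1.5)
    fg_level, bg_level = (high, low) if on_fg else (low, high)
    ch = np.where(region > 0, fg_level, bg_level).astype(np.float64)
    if mix.signature_noise_sigma > 0:
        ch = ch + rng.normal(0.0, mix.signature_noise_sigma, size=ch.shape)
    return ch


def make_feature_map(
    gt: LabelMap, mix: ChannelMixSpec
) -> tuple[FeatureMap, tuple[dict, ...]]:
    """Generate a feature map over ``gt`` plus a per-channel manifest.

    Channel order is a seeded shuffle of the four populations; the
    manifest entry at position ``index`` records each channel's class
    (``signal`` / ``noise`` / ``lowstd`` / ``irregular``) and, for
    irregular channels, the spiked instance and spike count.
    """
    rng = np.random.default_rng(mix.seed)
    region = gt.labels
    k = int(region.max())
    h, w = region.shape
    channels: list[np.ndarray] = []
    kinds: list[dict] = []
    for _ in range(mix.n_signal):
        channels.append(_signal_channel(region, k, mix, rng))
        kinds.append({"kind": "signal"})
    for _ in range(mix.n_fg_signal):
        channels.append(_signature_channel(region, mix, rng, on_fg=True))
        kinds.append({"kind": "fg_signal"})
    for _ in range(mix.n_bg_signal):
        channels.append(_signature_channel(region, mix, rng, on_fg=False))
        kinds.append({"kind": "bg_signal"})
    for _ in range(mix.n_noise):
        channels.append(rng.uniform(-mix.noise_amplitude, mix.noise_amplitude, (h, w)))
        kinds.append({"kind": "noise"})
    for _ in range(mix.n_lowstd):
        base = rng.uniform(0.0, 1.0)
        channels.append(base + rng.normal(0.0, mix.lowstd_sigma, (h, w)))
        kinds.append({"kind": "lowstd"})
    for _ in range(mix.n_irregular):
        ch = _signal_channel(region, k, mix, rng)
        target = int(rng.integers(1, k + 1)) if k >= 1 else 0
        inside = region == target
        spikes = inside & (rng.random((h, w)) < mix.spike_rate)
        signs = np.where(rng.random((h, w)) < 0.5, -1.0, 1.0)
        ch = ch + spikes * signs * mix.spike_magnitude
        kinds.append(
            {"kind": "irregular", "spiked_instance": target, "n_spikes": int(spikes.sum())}
        )
        channels.append(ch)
    order = rng.permutation(len(channels))
    stacked = np.stack([channels[i] for i in order], axis=-1)
    manifest = tuple(
        {"index": pos, **kinds[int(src)]} for pos, src in enumerate(order)
    )
    fmap = FeatureMap(stacked, provenance=f"synthetic(seed={mix.seed})")
    return fmap, manifest


def make_benchmark_suite(
    n_scenes: int,
    seed: int = 0,
    irregular: Literal["mixed", "always", "never"] = "mixed",
    scene_spec: SceneSpec | None = None,
    mix_spec: ChannelMixSpec | None = None,
) -> list[SyntheticScene]:
    """Deterministic benchmark suite cycling k through {2, 3, 4}.

    ``irregular`` controls whether scenes carry spiked channels:
    ``mixed`` alternates, ``always``/``never`` force it.  Scene and
    channel seeds are derived from ``seed`` and the scene number, so the
    suite is reproducible bit-for-bit.
    """
    if n_scenes < 1:
        raise ValueError("n_scenes must be >= 1")
    base_scene = scene_spec or SceneSpec()
    base_mix = mix_spec or ChannelMixSpec()
    suite: list[SyntheticScene] = []
    for i in range(n_scenes):
        k = 2 + i % 3
        with_spikes = {"mixed": i % 2 == 0, "always": True, "never": False}[irregular]
        sspec = dataclasses.replace(
            base_scene, k_instances=k, seed=int(np.random.default_rng((seed, i, 0)).integers(2**31))
        )
        n_irr = base_mix.n_irregular if with_spikes else 0
        n_sig = base_mix.n_signal + (0 if with_spikes else base_mix.n_irregular)
        mspec = dataclasses.replace(
            base_mix,
            n_irregular=n_irr,
            n_signal=n_sig,
            seed=int(np.random.default_rng((seed, i, 1)).integers(2**31)),
        )
        gt, fg = make_scene(sspec)
        fmap, manifest = make_feature_map(gt, mspec)
        suite.append(
            SyntheticScene(
                gt=gt, fg=fg, features=fmap, manifest=manifest,
                scene_spec=sspec, mix_spec=mspec,
            )
        )
    return suite
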