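# specseg

Unsupervised foreground/background and instance segmentation over dense
feature maps from self-supervised vision backbones, by spectral graph
partitioning — with entropy- and deviation-based channel pruning and a
distribution-aware affinity metric (Bray-Curtis over Chebyshev, *BoC*).

## Who this is for

Deep spectral methods segment an image without labels: a self-supervised
backbone (e.g. ViT-s16/DINO) turns the image into an `H x W` grid of
C-dimensional patch tokens, the tokens become vertices of a weighted graph,
and eigenvectors of the graph Laplacian ("eigensegments") decompose the image
into regions.  Two practical problems limit this recipe for *instance*
segmentation:

1. **Not all channels help.**  Some backbone channels are noise-like; others
   are nearly constant and carry no instance contrast.
2. **The dot product is the wrong affinity.**  A handful of extreme values
   ("irregular values") in a few channels dominate inner products, so pixels
   of one object get split into separate regions.

`specseg` implements the remedies as a reusable library + CLI, together with
a synthetic feature-map generator with known ground truth, so every stage is
testable end to end without a GPU or any external dataset.

## Method

Given a feature map `F ∈ R^{H×W×C}`:

* **NCR (noise channel reduction).**  Per channel `c`, bin its values into
  `B = 30` equal-width bins over its own range, `PDF(c) = Hist(c)/(H·W)`, and
  score `Entropy(c) = −Σ_b PDF_b(c)·log2 PDF_b(c)`.  Keep the `M` channels
  with the lowest entropy → `F′` (default `M = 128`, or `C/3`).
* **Fg-Bg segmentation.**  Build the patch affinity `W = F′F′ᵀ` (dot product,
  negatives clamped), form the normalized Laplacian
  `L = I − D^{−1/2} W D^{−1/2}`, threshold the Fiedler eigenvector `y₁` at 0;
  a border-majority heuristic fixes the orientation and an optional 5×5
  median filter removes small regions.
* **DCR (deviation-based channel reduction).**  Keep the `N` channels of `F′`
  with the highest population standard deviation → `F″` (default `N = 60`).
* **Instance segmentation.**  Over foreground tokens only, build the affinity
  with the **BoC** metric

      BC_diss = Σ|uᵢ−tᵢ| / Σ|uᵢ+tᵢ|      BC_sim = 1/(1+BC_diss)
      CH_diss = maxᵢ|uᵢ−tᵢ|              CH_sim = 1/(1+CH_diss)
      BoC     = BC_sim / CH_sim = (1+CH_diss)/(1+BC_diss)

  then cluster the eigensegments `y₁..y₄` of its Laplacian with k-means.
  Eight further metrics (dot, Bray-Curtis, Chebyshev, and reversed cosine /
  correlation / L1 / L2 / Mahalanobis similarities) are available for
  comparison sweeps.
* **Evaluation.**  Pixel F-score for Fg-Bg; Hungarian-matched mean IoU over
  ground-truth instances for instance masks; the `mR` statistic (mean
  intra-instance similarity variance over mean inter-instance similarity
  variance — lower is more coherent); and scene filters that drop ground
  truth with objects under 7% of the image or a smallest/largest instance
  ratio under 0.3.

The synthetic generator emulates backbone feature maps on a 24×42 ViT-s16
token grid with 384 channels: sparse on/off instance-coding channels,
foreground/background "objectness" signature channels, uniform-noise
channels, near-constant channels, and irregular-value channels that spike
inside a single instance.  A per-channel manifest makes selection behaviour
verifiable.

## Worked example

```python
import dataclasses
from specseg import (ChannelMixSpec, PipelineConfig, SceneSpec,
                     make_feature_map, make_scene, run_fgbg, run_instance)

gt, fg = make_scene(SceneSpec(k_instances=3, seed=0))       # 24x42 ground truth
features, manifest = make_feature_map(gt, ChannelMixSpec(seed=0))  # 384 channels

cfg = PipelineConfig()                       # M=128, N=60, metric="boc"
fg_mask, fg_report, _ = run_fgbg(cfg, fmap=features, gt=fg)
print(f"Fg-Bg F-score:  {fg_report.f_score:.3f}")

inst_cfg = dataclasses.replace(cfg, cluster_k=3)
inst_mask, inst_report, _ = run_instance(inst_cfg, fmap=features, gt=gt)
print(f"Hungarian mIoU: {inst_report.miou:.3f}")

dot_cfg = dataclasses.replace(inst_cfg, metric="dot")
_, dot_report, _ = run_instance(dot_cfg, fmap=features, gt=gt)
print(f"dot-product mIoU on the same scene: {dot_report.miou:.3f}")
```

prints

```
Fg-Bg F-score:  1.000
Hungarian mIoU: 1.000
dot-product mIoU on the same scene: 0.533
```

The scene contains irregular-value channels; the BoC affinity recovers all
three instances exactly while the dot-product affinity splits the spiked
instance and lands at mIoU 0.53.

The same pipelines are available from a shell:

```sh
specseg synth --scenes 1 --k 3 --seed 0 --out data/
specseg segment instance --features data/scene000_features.npy \
        --gt data/scene000_gt.png --k 3 --out out/
specseg evaluate --pred out/instance_mask.png --gt data/scene000_gt.png
specseg mr-stat --features data/scene000_features.npy \
        --gt data/scene000_gt.png --metric boc
specseg sweep --metrics boc,dot,l2 --scenes 5
```

Feature maps are dense `.npy`/`.npz` arrays, masks are 16-bit grayscale
PNGs (0 = background), reports are JSON.

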