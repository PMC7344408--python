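# dermoseg

Training-free border detection for pigmented skin lesions in dermoscopic
images, with a pixel-accuracy evaluation harness and a synthetic fixture
generator that provides exact ground truth.

## Who this is for

Dermoscopic computer-aided diagnosis pipelines need a lesion mask and a
border path before any clinical scoring (asymmetry, border irregularity,
colour distribution) can be computed. `dermoseg` implements a deliberately
simple, deterministic segmentation that needs no training data, no hair
removal and no image enhancement, so it can serve as a fast baseline or a
preprocessing stage, and as a reference implementation for teaching
bit-plane methods in biomedical image analysis.

## The method

Each 8-bit channel of an RGB image decomposes into bit planes,

```
C(x, y) = Σ_{i=0..7} c_i(x, y) · 2^i,   C ∈ {R, G, B},  c_i ∈ {0, 1},
```

and only the most significant plane is kept: `c_7(x, y) = 1 ⇔ C(x, y) ≥ 128`.
Lesions are darker than surrounding skin, so lesion pixels tend to lose the
MSB in one or more channels. Each binary MSB plane is cleaned by convolution
with a unit-gain 7×7 Hann-window kernel (separable outer product of
`w[n] = 0.5·(1 − cos(2πn/6))`) followed by one-bit re-quantization at 0.5,
which removes isolated spurious pixels while preserving solid regions. The
three cleaned planes are summed into a 4-level map,

```
L(x, y) = r_7(x, y) + g_7(x, y) + b_7(x, y) ∈ {0, 1, 2, 3},
```

where level 3 is bright skin and level 0 covers the darkest regions,
including the field outside the dermoscope circle. The lesion mask is the
largest 8-connected component of `L ≤ 2` that does not touch an image
corner, with interior holes filled; its closed border path is traced with
Moore-neighbour tracing. Segmentation quality against an expert mask is
scored by pixel accuracy,

```
Accuracy = (TP + TN) / (TP + FP + TN + FN).
```

## Worked example

```python
from dermoseg import (SyntheticSpec, generate_fixture, segment,
                      confusion_counts, accuracy)
import numpy as np

img, truth = generate_fixture(SyntheticSpec(seed=0))   # 256×256 fixture
res = segment(img)                                     # levels, mask, contour
c = confusion_counts(res.mask, truth)
print("lesion area (px):", int(res.mask.sum()))
print("contour length  :", len(res.contour))
print("accuracy vs truth:", round(accuracy(c), 4))
print("level histogram :", np.bincount(res.levels.ravel(), minlength=4).tolist())
```

prints

```
lesion area (px): 11956
contour length  : 413
accuracy vs truth: 0.9908
level histogram : [12762, 368, 631, 51775]
```

The fixture is a dark irregular lesion (~12k px) on lighter skin with
sensor noise, hair strokes and a corner vignette; the pipeline recovers the
generator's exact ground-truth mask to 99.1% pixel accuracy, and the level
histogram shows the expected split between dark lesion/vignette pixels
(level 0) and bright skin (level 3).

The same object is available as a scikit-learn estimator:

```python
from dermoseg import LesionSegmenter
mask = LesionSegmenter(lesion_level_max=2).fit().predict(img)
```

## Command line

```
dermoseg synth -n 20 --seed 0 -o suite/          # synthetic image/mask pairs
dermoseg segment suite/synth_000.png -o out/     # mask, levels, overlay, histograms
dermoseg evaluate suite/ -o report/              # per-image CSV + JSON summary
```

`evaluate` also understands PH2-style dataset layouts (per-case
subdirectories, masks named `<id>_lesion.*`), so pointing it at a local
copy of the PH2 dermoscopy benchmark reproduces the pixel-accuracy
evaluation on real data.

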