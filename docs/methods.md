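# Methods

## Segmentation model

The pipeline assumes the standard dermoscopic contrast regime: a pigmented
lesion darker than the surrounding skin, imaged through a circular
dermoscope field whose outside appears as dark corners. Under 8-bit
quantization the most significant bit of a channel is simply the predicate
`value ≥ 128`, so the per-channel MSB planes act as three fixed mid-scale
thresholds. No contrast normalisation, resizing, colour-space conversion or
hair removal is performed anywhere; robustness to noise and thin artifacts
comes entirely from the low-pass/re-quantization stage.

Stages, in order:

1. **MSB extraction.** `extract_msb_planes` returns the bit-7 plane of each
   channel. Lower bit planes are reachable through `bit_index` for
   exploratory use, but only bit 7 is part of the validated pipeline.
2. **Hann low-pass + one-bit re-quantization.** Each binary plane is
   convolved with the unit-sum 7×7 kernel `outer(w, w)/9`,
   `w = [0, .25, .75, 1, .75, .25, 0]` (symmetric Hann window; the zero
   endpoints make the effective support 5×5 inside the 7×7 frame), then
   re-binarized at 0.5. An isolated flipped pixel can move the filtered
   value by at most the largest kernel weight (1/9 < 0.5), so single
   spurious pixels — sensor noise crossing the 128 boundary, 1 px hair
   strokes — never survive, while pixels at Chebyshev distance ≥ 3 inside a
   solid region are untouched.
3. **Level summation.** The three cleaned planes sum to a 4-level map:
   level 3 = bright skin (MSB set in all channels), level 0 = darkest
   pixels (lesion core, vignette), levels 1–2 = transitional.
4. **Mask extraction.** Lesion candidates are pixels with level ≤ 2, i.e.
   missing the MSB in at least one channel. Because the dark field outside
   the dermoscope circle is also low-level, 8-connected candidate
   components touching any image corner are discarded first; then the
   largest remaining component is kept and its interior holes (4-connected
   background regions) are filled. Each step is individually switchable.
5. **Border tracing.** Moore-neighbour tracing with a repeat-from-start
   stopping rule yields a closed 8-connected path, counterclockwise as
   displayed, starting at the topmost-then-leftmost boundary pixel. The
   traced pixel set equals the morphological inner boundary (mask pixels
   with a 4-neighbour of background), which the tests verify directly.

## Parameters

| parameter | default | meaning |
|---|---|---|
| `bit_index` | 7 | bit plane used per channel; 7 ⇔ threshold at 128 |
| `kernel_size` | 7 | side of the Hann kernel, odd ≥ 3 |
| `quantize_threshold` | 0.5 | re-binarization level on the unit-gain filtered plane; ties map to 1 |
| `lesion_level_max` | 2 | highest level counted as lesion candidate |
| post-processing flags | all on | corner exclusion, largest component, hole fill |

The 0.5 threshold is the majority-vote rule on a normalized kernel.
`lesion_level_max = 2` encodes "dark in at least one channel"; lowering it
to 1 or 0 demands darkness in two or all three channels and strictly
shrinks the candidate set (a tested monotonicity property).

## Numerical choices

- Convolution uses reflect (edge-repeat) padding, so a uniformly bright
  frame stays uniformly 1 after filtering; zero padding would fabricate a
  dark border. The brute-force oracle in the tests uses
  `np.pad(mode="symmetric")`, the same convention.
- Attainable filtered values are multiples of 1/144 (kernel entries are
  products of {0, ¼, ¾, 1} divided by 9). The quantizer compares against
  `threshold − 1e−9`: the slack only absorbs floating-point roundoff of an
  exact tie — the nearest non-tie value is 1/144 ≈ 0.007 away — and
  implements ties-to-1 deterministically.
- Component-size ties in largest-component selection resolve to the lowest
  label (row-major first occurrence), keeping the pipeline bit-reproducible.
- Degenerate inputs yield empty results rather than errors: an all-bright
  image has no candidates; an all-dark image is one component touching all
  corners and is excluded; both give an empty mask and an empty contour.

## Synthetic fixtures

The generator emulates exactly the statistics the method exploits, with
every draw taken from a seeded `numpy` generator so fixtures are
bit-reproducible:

- **Boundary**: a star-shaped harmonic curve
  `r(θ) = r₀(1 + a Σ_{k=1..K} c_k cos(kθ + φ_k))`, `c_k ~ U(−1,1)/k`,
  `φ_k ~ U(0,2π)`; K = 6, a = 0.15, r₀ = 60 px in a 256×256 frame. If a
  draw would push the perturbation past 0.9 it is rescaled to keep the
  boundary star-shaped and strictly positive.
- **Colours**: skin mean (200, 160, 140) and lesion core (90, 60, 50)
  straddle 128 in every channel — the contrast regime in which MSB
  thresholding is meaningful. Pixel colour blends the two means by
  `s = expit(6d/w)` of the radial signed distance `d` to the boundary, so
  the transition width `w = 4 px` spans the central ~5–95 % of the blend.
- **Noise and artifacts**: Gaussian noise (sd 10) is added after blending
  and clipped (wrap-around would fabricate MSB flips); dark 1–2 px
  polyline hairs are painted after the noise, without anti-aliasing, to
  exercise the spurious-pixel suppression; the vignette sets pixels beyond
  0.9 of the half-diagonal to a dark shade, producing the corner wedges
  the mask extraction must reject. Ground truth is the set of pixel
  centres strictly inside the analytic boundary.
- **Suites** derive per-image render seeds from one master seed
  (`numpy.random.SeedSequence`) and vary centre (±8 % of the frame),
  radius (0.75–1.25×), irregularity (0.5–1.5×) and hair count (0–3) —
  chosen once as plausible PH2-like variation.

What the fixtures do **not** model: pigment networks, globules and other
dermoscopic microstructures, specular reflections, air/oil bubbles,
illumination gradients, camera colour profiles, or lesions whose mean
intensity straddles 128 within a single channel. Passing the synthetic
recovery tests therefore demonstrates correctness of the algorithm under
its own contrast assumption, not clinical-grade performance; evaluation on
real dermoscopy (e.g. the PH2 benchmark via `dermoseg evaluate`) is the
appropriate check for the latter.

With the default fixture conditions the residual segmentation error is
geometric and predictable: the blue channel (140 → 50 across the blend)
crosses 128 about 1.25 px outside the true boundary, so the predicted mask
is a thin dilation of the truth. The measured values — 99.3 % accuracy on
the noise-free fixture, ~98 % mean accuracy on the default 20-image suite
(the quantities `scripts/acceptance.py` recomputes) — match this estimate.

## Evaluation conventions

Accuracy, Dice, Jaccard, sensitivity and specificity are computed from
per-image pixel confusion counts; the dataset aggregate is the unweighted
per-image mean (the common convention for segmentation benchmarks), not a
pooled pixel count. Images that fail to evaluate (decoding errors, shape
mismatches) are skipped and reported, not fatal. Problem sizes in the test
suite and acceptance script — 20 images of 256×256 — were chosen as the
smallest suite at which the suite-level mean is stable across seeds.

## Design choices and limitations

- "Hanning shaped" is read as the separable outer-product kernel; a
  rotationally symmetric Hann window is a plausible alternative reading
  that was not adopted.
- Filtering is applied once per MSB plane, before summation; the level map
  itself is not re-filtered.
- The level→lesion rule and the corner-exclusion disambiguation of the
  dark vignette from level-0 lesion cores are the package's reading of an
  under-determined step; both are configurable.
- Multiple lesions are reduced to the largest component by design; there
  is no multi-lesion output and no sub-pixel border refinement.
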