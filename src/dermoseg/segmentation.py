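"""Bit-plane based lesion segmentation.

The pipeline segments a pigmented skin lesion in a dermoscopic RGB image
without any training, enhancement or hair removal:

1. each 8-bit colour channel is split into bit planes and only the most
   significant bit plane (MSB, bit 7, i.e. value >= 128) is retained;
2. each binary MSB plane is low-pass filtered with a 7x7 Hann-window kernel
   and re-quantized to one bit, which removes spurious isolated pixels;
3. the three cleaned planes are summed into a 4-level map (level 3 = bright
   skin, level 0 = darkest regions / outside the dermoscope field);
4. the lesion mask is extracted from the low levels by light binary
   post-processing (corner-component exclusion, largest component, hole
   fill) and its closed border path is traced.

The user-facing object is :class:`LesionSegmenter`, a scikit-learn style
estimator; the module-level functions expose the individual stages and a
one-shot :func:`segment`.
"""

from __future__ import annotations

import configparser
import dataclasses
from typing import NamedTuple, Sequence

import numpy as np
from scipy import ndimage
from sklearn.base import BaseEstimator

__all__ = [
    "SegmentationConfig",
    "SegmentationResult",
    "LesionSegmenter",
    "decompose_bit_plane",
    "extract_msb_planes",
    "make_hanning_kernel",
    "lowpass_quantize",
    "sum_planes",
    "lesion_mask_from_levels",
    "trace_border",
    "segment",
]

_CHANNEL_INDEX = {"R": 0, "G": 1, "B": 2, "r": 0, "g": 1, "b": 2}
_EIGHT_CONN = np.ones((3, 3), dtype=bool)
# Attainable filtered values are multiples of 1/144 (kernel entries are
# products of {0, 1/4, 3/4, 1} divided by 9), so this slack can only ever
# absorb floating-point roundoff of an exact tie, never flip a non-tie.
_TIE_EPS = 1e-9


def as_rgb_array(image) -> np.ndarray:
    """Validate and return an (H, W, 3) uint8 view of *image*."""
    arr = np.asarray(image)
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise ValueError(f"expected an (H, W, 3) RGB array, got shape {arr.shape}")
    if arr.dtype != np.uint8:
        if not np.issubdtype(arr.dtype, np.integer):
            raise ValueError(f"expected integer pixel values, got dtype {arr.dtype}")
        if arr.min() < 0 or arr.max() > 255:
            raise ValueError("pixel values outside [0, 255]")
        arr = arr.astype(np.uint8)
    return arr


def _as_binary_plane(plane) -> np.ndarray:
    arr = np.asarray(plane)
    if arr.ndim != 2:
        raise ValueError(f"expected a 2D plane, got shape {arr.shape}")
    if arr.dtype == bool:
        return arr.astype(np.uint8)
    vals = np.unique(arr)
    if not np.isin(vals, (0, 1)).all():
        raise ValueError("plane is not {0,1}-valued")
    return arr.astype(np.uint8)


@dataclasses.dataclass
class SegmentationConfig:
    """Tunable parameters of the segmentation pipeline.

    bit_index
        Which bit plane to use per channel. Bit 7 (the MSB) is the
        validated pipeline; lower planes are exposed as a hook only.
    lesion_level_max
        Highest level of the 4-level map counted as lesion candidate.
        Default 2: any pixel missing the MSB in at least one channel.
    quantize_threshold
        One-bit re-quantization threshold on the unit-gain filtered plane.
    kernel_size
        Side of the square Hann low-pass kernel (odd, >= 3).
    exclude_corner_components / keep_largest_component / fill_holes
        Binary post-processing toggles, all on by default.
    """

    bit_index: int = 7
    lesion_level_max: int = 2
    quantize_threshold: float = 0.5
    kernel_size: int = 7
    exclude_corner_components: bool = True
    keep_largest_component: bool = True
    fill_holes: bool = True

    def validate(self) -> "SegmentationConfig":
        if not 0 <= self.bit_index <= 7:
            raise ValueError(f"bit_index must be in [0, 7], got {self.bit_index}")
        if not 0 <= self.lesion_level_max <= 2:
            raise ValueError(
                f"lesion_level_max must be in [0, 2], got {self.lesion_level_max}"
            )
        if not 0.0 < self.quantize_threshold < 1.0:
            raise ValueError(
                f"quantize_threshold must be in (0, 1), got {self.quantize_threshold}"
            )
        if self.kernel_size < 3 or self.kernel_size % 2 == 0:
            raise ValueError(f"kernel_size must be odd and >= 3, got {self.kernel_size}")
        return self

    def to_ini(self, path) -> None:
        """Write a flat key=value config file."""
        parser = configparser.ConfigParser()
        parser["segmentation"] = {
            k: str(v) for k, v in dataclasses.asdict(self).items()
        }
        with open(path, "w") as fh:
            parser.write(fh)

    @classmethod
    def from_ini(cls, path) -> "SegmentationConfig":
        parser = configparser.ConfigParser()
        if not parser.read(path):
            raise IOError(f"cannot read config file: {path}")
        sec = parser["segmentation"]
        return cls(
            bit_index=sec.getint("bit_index", cls.bit_index),
            lesion_level_max=sec.getint("lesion_level_max", cls.lesion_level_max),
            quantize_threshold=sec.getfloat("quantize_threshold", cls.quantize_threshold),
            kernel_size=sec.getint("kernel_size", cls.kernel_size),
            exclude_corner_components=sec.getboolean(
                "exclude_corner_components", cls.exclude_corner_components
            ),
            keep_largest_component=sec.getboolean(
                "keep_largest_component", cls.keep_largest_component
            ),
            fill_holes=sec.getboolean("fill_holes", cls.fill_holes),
        ).validate()


class SegmentationResult(NamedTuple):
    levels: np.ndarray  # (H, W) int in {0..3}
    mask: np.ndarray  # (H, W) uint8 in {0, 1}
    contour: np.ndarray  # (N, 2) int (row, col), closed 8-connected path


def decompose_bit_plane(image, channel, bit: int) -> np.ndarray:
    """Extract bit plane *bit* of one colour channel as a {0,1} uint8 grid.

    The planes reconstruct the channel exactly: sum_i 2**i * plane_i.
    """
    if not 0 <= bit <= 7:
        raise ValueError(f"bit must be in [0, 7], got {bit}")
    arr = as_rgb_array(image)
    if isinstance(channel, str):
        try:
            channel = _CHANNEL_INDEX[channel]
        except KeyError:
            raise ValueError(f"unknown channel {channel!r}") from None
    if channel not in (0, 1, 2):
        raise ValueError(f"channel must be R/G/B or 0/1/2, got {channel}")
    return ((arr[:, :, channel] >> bit) & 1).astype(np.uint8)


def extract_msb_planes(image, bit: int = 7):
    """Return the (R, G, B) bit-*bit* planes; for bit 7, plane = (channel >= 128)."""
    return tuple(decompose_bit_plane(image, c, bit) for c in (0, 1, 2))


def make_hanning_kernel(size: int = 7) -> np.ndarray:
    """Separable 2D Hann-window low-pass kernel, normalized to unit sum.

    Built as the outer product of the symmetric Hann window
    w[n] = 0.5 * (1 - cos(2*pi*n / (size-1))), whose endpoints are exactly
    zero, so the effective support of the default 7x7 kernel is 5x5.
    """
    if size < 3 or size % 2 == 0:
        raise ValueError(f"kernel size must be odd and >= 3, got {size}")
    window = np.hanning(size)
    kernel = np.outer(window, window)
    return kernel / kernel.sum()


def lowpass_quantize(plane, kernel=None, threshold: float = 0.5) -> np.ndarray:
    """Low-pass filter a binary plane and re-quantize to one bit.

    Convolution uses reflect (edge-repeat) padding; the output is 1 where
    the filtered value reaches *threshold* (ties resolve to 1). With the
    unit-gain Hann kernel this removes isolated spurious pixels while
    preserving solid regions.
    """
    if not 0.0 < threshold < 1.0:
        raise ValueError(f"threshold must be in (0, 1), got {threshold}")
    arr = _as_binary_plane(plane)
    if kernel is None:
        kernel = make_hanning_kernel()
    kernel = np.asarray(kernel, dtype=np.float64)
    filtered = ndimage.convolve(arr.astype(np.float64), kernel, mode="reflect")
    return (filtered >= threshold - _TIE_EPS).astype(np.uint8)


def sum_planes(plane_r, plane_g, plane_b) -> np.ndarray:
    """Pointwise sum of the three binary channel planes: the 4-level map."""
    planes = [_as_binary_plane(p) for p in (plane_r, plane_g, plane_b)]
    if not (planes[0].shape == planes[1].shape == planes[2].shape):
        raise ValueError(
            "plane shapes differ: "
            f"{planes[0].shape}, {planes[1].shape}, {planes[2].shape}"
        )
    return (
        planes[0].astype(np.uint8) + planes[1] + planes[2]
    ).astype(np.uint8)


def lesion_mask_from_levels(levels, config: SegmentationConfig | None = None) -> np.ndarray:
    """Extract the binary lesion mask from the 4-level map.

    Candidate pixels are those with level <= ``lesion_level_max`` (the
    lesion is darker than the surrounding skin, so it lacks the MSB in at
    least one channel). Per enabled flag: 8-connected candidate components
    touching any image corner are discarded (the dark field outside the
    dermoscope circle), the largest remaining component is kept, and its
    interior holes are filled. Returns an all-zero mask if nothing survives.
    """
    cfg = (config or SegmentationConfig()).validate()
    lv = np.asarray(levels)
    if lv.ndim != 2:
        raise ValueError(f"expected a 2D level map, got shape {lv.shape}")
    if lv.size and (lv.min() < 0 or lv.max() > 3):
        raise ValueError("level map values outside {0..3}")
    cand = lv <= cfg.lesion_level_max

    if cfg.exclude_corner_components and cand.any():
        labels, _ = ndimage.label(cand, structure=_EIGHT_CONN)
        corners = {labels[0, 0], labels[0, -1], labels[-1, 0], labels[-1, -1]} - {0}
        if corners:
            cand &= ~np.isin(labels, sorted(corners))

    if cfg.keep_largest_component and cand.any():
        labels, n = ndimage.label(cand, structure=_EIGHT_CONN)
        if n > 1:
            sizes = np.bincount(labels.ravel())
            sizes[0] = 0
            cand = labels == sizes.argmax()  # ties: lowest label, deterministic

    if cfg.fill_holes and cand.any():
        # default cross structure: holes are 4-connected background regions
        cand = ndimage.binary_fill_holes(cand)

    return cand.astype(np.uint8)


# Moore neighbourhood in counterclockwise display order (row 0 at top),
# starting at west: W, SW, S, SE, E, NE, N, NW.
_RING = ((0, -1), (1, -1), (1, 0), (1, 1), (0, 1), (-1, 1), (-1, 0), (-1, -1))
_RING_INDEX = {d: i for i, d in enumerate(_RING)}


def _next_on_boundary(padded, cur, back_dir):
    """One Moore-tracing step: next boundary pixel and its backtrack direction."""
    for k in range(1, 9):
        d = (back_dir + k) % 8
        nxt = (cur[0] + _RING[d][0], cur[1] + _RING[d][1])
        if padded[nxt]:
            prev_bg = (cur[0] + _RING[(d - 1) % 8][0], cur[1] + _RING[(d - 1) % 8][1])
            return nxt, _RING_INDEX[(prev_bg[0] - nxt[0], prev_bg[1] - nxt[1])]
    return None, None


def trace_border(mask) -> np.ndarray:
    """Trace the closed border path of a binary mask (Moore-neighbour tracing).

    Returns an (N, 2) array of (row, col) coordinates: a counterclockwise
    (as displayed, row 0 at top) 8-connected closed path starting at the
    topmost-then-leftmost boundary pixel. Every contour pixel is a mask
    pixel with at least one 4-neighbour outside the mask. An empty mask
    yields an empty (0, 2) contour.
    """
    m = _as_binary_plane(mask).astype(bool)
    if not m.any():
        return np.empty((0, 2), dtype=np.intp)
    padded = np.pad(m, 1)
    rows, cols = np.nonzero(padded)
    start = (int(rows[0]), int(cols[0]))  # row-major: topmost, then leftmost

    contour = [start]
    start_back = 0  # west neighbour of the start pixel is background
    cur, back = start, start_back
    limit = 8 * int(m.sum()) + 16
    for _ in range(limit):
        nxt, nback = _next_on_boundary(padded, cur, back)
        if nxt is None:  # isolated pixel
            break
        if nxt == start:
            # stop once the path would repeat itself from the start pixel
            follow, _ = _next_on_boundary(padded, nxt, nback)
            if len(contour) == 1 or follow == contour[1]:
                break
        contour.append(nxt)
        cur, back = nxt, nback
    return np.asarray(contour, dtype=np.intp) - 1


class LesionSegmenter(BaseEstimator):
    """Training-free lesion segmenter with a scikit-learn estimator surface.

    Parameters mirror :class:`SegmentationConfig`. ``fit`` only validates
    parameters and builds the filter kernel (the method needs no training);
    ``predict`` maps an RGB image — or a sequence of images — to binary
    lesion mask(s), ``transform`` to 4-level map(s).

    Attributes set by ``fit``: ``kernel_`` (the normalized Hann kernel) and
    ``config_`` (the validated :class:`SegmentationConfig`).
    """

    def __init__(
        self,
        bit_index: int = 7,
        lesion_level_max: int = 2,
        quantize_threshold: float = 0.5,
        kernel_size: int = 7,
        exclude_corner_components: bool = True,
        keep_largest_component: bool = True,
        fill_holes: bool = True,
    ):
        self.bit_index = bit_index
        self.lesion_level_max = lesion_level_max
        self.quantize_threshold = quantize_threshold
        self.kernel_size = kernel_size
        self.exclude_corner_components = exclude_corner_components
        self.keep_largest_component = keep_largest_component
        self.fill_holes = fill_holes

    # -- estimator surface -------------------------------------------------
    def fit(self, X=None, y=None) -> "LesionSegmenter":
        """Validate parameters and build the kernel; no estimation happens."""
        self.config_ = SegmentationConfig(**self.get_params()).validate()
        self.kernel_ = make_hanning_kernel(self.kernel_size)
        return self

    def _ensure_fitted(self) -> None:
        if not hasattr(self, "kernel_"):
            self.fit()

    def segment(self, image) -> SegmentationResult:
        """Run the full pipeline on one RGB image."""
        self._ensure_fitted()
        cfg = self.config_
        arr = as_rgb_array(image)
        planes = extract_msb_planes(arr, cfg.bit_index)
        cleaned = tuple(
            lowpass_quantize(p, self.kernel_, cfg.quantize_threshold) for p in planes
        )
        levels = sum_planes(*cleaned)
        mask = lesion_mask_from_levels(levels, cfg)
        contour = trace_border(mask)
        return SegmentationResult(levels, mask, contour)

    def level_map(self, image) -> np.ndarray:
        return self.segment(image).levels

    def predict(self, X):
        """Binary lesion mask(s) for an image or a sequence of images."""
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return self.segment(X).mask
        return [self.segment(img).mask for img in X]

    def transform(self, X):
        """4-level map(s) for an image or a sequence of images."""
        if isinstance(X, np.ndarray) and X.ndim == 3:
            return self.segment(X).levels
        return [self.segment(img).levels for img in X]

    @classmethod
    def from_config(cls, config: SegmentationConfig) -> "LesionSegmenter":
        return cls(**dataclasses.asdict(config))


def segment(image, config: SegmentationConfig | None = None) -> SegmentationResult:
    """One-shot pipeline: RGB image -> (level map, lesion mask, contour)."""
    est = (
        LesionSegmenter.from_config(config) if config is not None else LesionSegmenter()
    )
    return est.fit().segment(image)
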