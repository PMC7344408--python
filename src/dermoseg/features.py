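"""Per-region colour histograms of the segmented image.

For each level of the 4-level segmentation map (or for each side of a
binary mask) the raw 256-bin count histogram of every colour channel is
tallied. Counts are kept un-normalized — they are lossless and any density
normalization is a presentation concern.
"""

from __future__ import annotations

import dataclasses

import numpy as np

from .segmentation import as_rgb_array

__all__ = ["RegionHistograms", "region_color_histograms", "lesion_color_histograms"]

_CHANNEL_NAMES = ("R", "G", "B")


@dataclasses.dataclass(frozen=True)
class RegionHistograms:
    """Colour histograms per region.

    counts
        ``(n_regions, 3, 256)`` int64 array; ``counts[l, c, v]`` is the
        number of pixels of region *l* whose channel-*c* value is *v*.
    pixel_counts
        ``(n_regions,)`` pixel count per region; for every (region,
        channel) the bins sum to this count, and region counts sum to the
        image pixel count.
    """

    counts: np.ndarray
    pixel_counts: np.ndarray

    @property
    def n_regions(self) -> int:
        return self.counts.shape[0]

    def to_dict(self) -> dict:
        """JSON-ready mapping: region -> pixel count + per-channel bins."""
        out = {}
        for lvl in range(self.n_regions):
            entry = {"pixel_count": int(self.pixel_counts[lvl])}
            for c, name in enumerate(_CHANNEL_NAMES):
                entry[name] = self.counts[lvl, c].tolist()
            out[str(lvl)] = entry
        return out


def _histograms(image, labels, n_regions: int) -> RegionHistograms:
    arr = as_rgb_array(image)
    lab = np.asarray(labels)
    if lab.shape != arr.shape[:2]:
        raise ValueError(f"label shape {lab.shape} != image shape {arr.shape[:2]}")
    if lab.size and (lab.min() < 0 or lab.max() >= n_regions):
        raise ValueError(f"labels outside [0, {n_regions - 1}]")
    flat = lab.ravel().astype(np.int64)
    counts = np.zeros((n_regions, 3, 256), dtype=np.int64)
    for c in range(3):
        code = flat * 256 + arr[:, :, c].ravel().astype(np.int64)
        counts[:, c, :] = np.bincount(code, minlength=n_regions * 256).reshape(
            n_regions, 256
        )
    pixel_counts = np.bincount(flat, minlength=n_regions)
    return RegionHistograms(counts, pixel_counts)


def region_color_histograms(image, levels) -> RegionHistograms:
    """Histograms of each of the 4 segmentation levels (0..3)."""
    return _histograms(image, levels, 4)


def lesion_color_histograms(image, mask) -> RegionHistograms:
    """Histograms keyed by the binary lesion mask: region 0 = skin, 1 = lesion."""
    return _histograms(image, (np.asarray(mask) > 0).astype(np.int64), 2)
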