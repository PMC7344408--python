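"""Raster I/O: dermoscopic images, ground-truth masks, result artifacts.

Reads PNG/BMP/JPEG; all outputs are written lossless (PNG) because the
bit-plane logic is sensitive to compression noise. Coordinates are
(row, col), 0-based, row 0 at top.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np

__all__ = [
    "UnsupportedFormatError",
    "load_rgb_image",
    "load_mask",
    "write_image",
    "write_mask",
    "write_level_map",
    "write_overlay",
    "find_pairs",
]

#: colour used to paint contour pixels in overlays
OVERLAY_COLOR = (255, 0, 0)

#: grey shades used to render the 4 levels of a level map
LEVEL_SHADES = np.array([0, 85, 170, 255], dtype=np.uint8)

_RASTER_EXTS = (".png", ".bmp", ".jpg", ".jpeg")


class UnsupportedFormatError(ValueError):
    """Raised for decodable images the pipeline cannot process (e.g. 16-bit)."""


def _read(path) -> np.ndarray:
    try:
        return iio.imread(path)
    except UnsupportedFormatError:
        raise
    except Exception as exc:
        raise IOError(f"cannot read image file: {path}") from exc


def load_rgb_image(path) -> np.ndarray:
    """Load an image as an (H, W, 3) uint8 RGB array.

    Grayscale inputs are replicated to three channels; an alpha channel is
    dropped. Images deeper than 8 bits per sample are rejected.
    """
    arr = _read(path)
    if arr.dtype == bool:
        arr = arr.astype(np.uint8) * 255
    if arr.dtype != np.uint8:
        raise UnsupportedFormatError(
            f"{path}: unsupported sample depth {arr.dtype}, expected 8-bit"
        )
    if arr.ndim == 2:
        arr = np.stack([arr] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 2:  # gray + alpha
        arr = np.stack([arr[:, :, 0]] * 3, axis=-1)
    elif arr.ndim == 3 and arr.shape[2] == 4:
        arr = arr[:, :, :3]
    if arr.ndim != 3 or arr.shape[2] != 3:
        raise UnsupportedFormatError(f"{path}: unsupported image shape {arr.shape}")
    return np.ascontiguousarray(arr)


def load_mask(path) -> np.ndarray:
    """Load a ground-truth lesion mask as an (H, W) uint8 {0,1} array.

    Any nonzero pixel (max over channels if multi-channel) maps to 1;
    PH2-style 0/255 masks and already-binary masks load identically.
    """
    arr = _read(path)
    if arr.ndim == 3:
        arr = arr.max(axis=2)
    if arr.ndim != 2:
        raise UnsupportedFormatError(f"{path}: unsupported mask shape {arr.shape}")
    return (arr > 0).astype(np.uint8)


def write_image(image, path) -> None:
    try:
        iio.imwrite(path, np.asarray(image))
    except Exception as exc:
        raise IOError(f"cannot write image file: {path}") from exc


def write_mask(mask, path) -> None:
    """Write a {0,1} mask as a 0/255 PNG."""
    write_image((np.asarray(mask) > 0).astype(np.uint8) * 255, path)


def write_level_map(levels, path) -> None:
    """Render the 4-level map as a grayscale PNG (level 0 dark, 3 bright)."""
    write_image(LEVEL_SHADES[np.asarray(levels)], path)


def write_overlay(image, contour, path, color=OVERLAY_COLOR) -> None:
    """Write a copy of *image* with the contour pixels painted *color*.

    Repeated contour vertices are painted once; the input array is not
    modified. An empty contour writes the image unchanged.
    """
    out = np.ascontiguousarray(image).copy()
    contour = np.asarray(contour, dtype=np.intp).reshape(-1, 2)
    if len(contour):
        if (
            contour.min() < 0
            or contour[:, 0].max() >= out.shape[0]
            or contour[:, 1].max() >= out.shape[1]
        ):
            raise ValueError("contour coordinates outside image bounds")
        out[contour[:, 0], contour[:, 1]] = color
    write_image(out, path)


def _find_mask_for(stem: str, directory: Path, mask_suffix: str) -> Path | None:
    for ext in _RASTER_EXTS:
        cand = directory / f"{stem}{mask_suffix}{ext}"
        if cand.exists():
            return cand
    return None


def find_pairs(image_dir, mask_dir=None, mask_suffix: str = "_lesion"):
    """Discover (image_path, mask_path_or_None, identifier) triples.

    Layouts supported:

    * flat: images and ``<stem><mask_suffix>.<ext>`` masks, either in one
      directory (``mask_dir`` omitted) or in two parallel directories;
    * per-case subdirectories (PH2-style): ``<root>/<id>/.../<id>.<ext>``
      with a mask named ``<id><mask_suffix>.<ext>`` anywhere under the
      case directory.

    Images without a discoverable mask are returned with mask ``None`` so
    the caller can decide to skip or fail.
    """
    root = Path(image_dir)
    if not root.is_dir():
        raise IOError(f"not a directory: {root}")

    pairs = []
    if mask_dir is None and any(p.is_dir() for p in root.iterdir()):
        for case in sorted(p for p in root.iterdir() if p.is_dir()):
            image = None
            for ext in _RASTER_EXTS:
                hits = sorted(case.rglob(f"{case.name}{ext}"))
                if hits:
                    image = hits[0]
                    break
            if image is None:
                continue
            mask = None
            for ext in _RASTER_EXTS:
                hits = sorted(case.rglob(f"{case.name}{mask_suffix}{ext}"))
                if hits:
                    mask = hits[0]
                    break
            pairs.append((image, mask, case.name))
        return pairs

    mdir = Path(mask_dir) if mask_dir is not None else root
    for image in sorted(p for p in root.iterdir() if p.suffix.lower() in _RASTER_EXTS):
        stem = image.stem
        if mask_suffix and stem.endswith(mask_suffix):
            continue  # a mask file, not an image
        mask = _find_mask_for(stem, mdir, mask_suffix)
        if mask is None and mask_dir is not None:
            mask = _find_mask_for(stem, mdir, "")
        pairs.append((image, mask, stem))
    return pairs
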