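"""Synthetic dermoscopy-like fixtures with exact ground truth.

The generator emulates the image statistics the segmentation pipeline
exploits: a dark, irregularly-bordered lesion (core channel values below
128) on lighter skin (channel values predominantly at or above 128), a
smooth lesion/skin transition band, additive sensor noise, optional dark
hair strokes and the dark vignette outside the circular dermoscope field
at the image corners. Every fixture is a deterministic function of its
spec, including the seed.

The lesion boundary is a star-shaped harmonic perturbation of a circle:

    r(theta) = r0 * (1 + a * sum_k c_k * cos(k*theta + phi_k)),  k = 1..K

with c_k ~ U(-1, 1)/k and phi_k ~ U(0, 2*pi) drawn from the seeded
generator. Pixel colour blends skin and lesion means by a logistic
function of the radial signed distance d to the boundary,
s = 1 / (1 + exp(-6 d / w)), so the stated transition width w spans the
central ~5-95% of the blend. The truth mask is the set of pixel centres
strictly inside the boundary.
"""

from __future__ import annotations

import dataclasses

import numpy as np
from scipy.special import expit
from skimage.draw import line as _draw_line

__all__ = [
    "SyntheticSpec",
    "generate_fixture",
    "generate_suite",
    "suite_specs",
    "boundary_area",
]

#: intensity of the dark field outside the dermoscope circle
_VIGNETTE_SHADE = 12


@dataclasses.dataclass
class SyntheticSpec:
    """Parameters of one synthetic fixture.

    Defaults place the skin/lesion means on opposite sides of the 128
    most-significant-bit boundary in every channel, the contrast regime
    on which MSB thresholding is meaningful: skin (200, 160, 140), lesion
    core (90, 60, 50), transition width 4 px, Gaussian noise sd 10.
    """

    height: int = 256
    width: int = 256
    center: tuple | None = None  # (row, col); None = image centre
    radius: float = 60.0  # base lesion radius, px
    n_harmonics: int = 6  # K radial harmonics of the border
    irregularity: float = 0.15  # amplitude scale a, fraction of radius
    skin_color: tuple = (200, 160, 140)
    lesion_color: tuple = (90, 60, 50)
    transition_width: float = 4.0  # px, ~5-95% span of the blend
    noise_sd: float = 10.0  # additive Gaussian noise, intensity units
    hair_count: int = 3
    hair_darkness: int = 45  # mean intensity of hair strokes
    vignette_frac: float = 0.9  # field radius / half-diagonal; 0 disables
    seed: int = 0

    def validate(self) -> "SyntheticSpec":
        if self.height < 16 or self.width < 16:
            raise ValueError("image too small")
        if not 0 < self.radius < min(self.height, self.width) / 2:
            raise ValueError(
                "radius must be positive and below half the smallest dimension"
            )
        for col in (self.skin_color, self.lesion_color):
            if len(col) != 3 or any(not 0 <= v <= 255 for v in col):
                raise ValueError(f"colour {col} outside [0, 255]")
        if not 0 <= self.irregularity < 1:
            raise ValueError("irregularity (amplitude scale) must be in [0, 1)")
        if self.n_harmonics < 0 or self.transition_width < 0 or self.noise_sd < 0:
            raise ValueError("n_harmonics, transition_width, noise_sd must be >= 0")
        if self.hair_count < 0 or not 0 <= self.vignette_frac <= 1:
            raise ValueError("hair_count must be >= 0, vignette_frac in [0, 1]")
        return self


def _sample_harmonics(rng: np.random.Generator, spec: SyntheticSpec):
    """Draw the border harmonics; rescale if the perturbation could close r to 0."""
    k = np.arange(1, spec.n_harmonics + 1)
    coeffs = rng.uniform(-1.0, 1.0, size=spec.n_harmonics) / np.maximum(k, 1)
    phases = rng.uniform(0.0, 2.0 * np.pi, size=spec.n_harmonics)
    if spec.n_harmonics and spec.irregularity:
        theta = np.linspace(0.0, 2.0 * np.pi, 1024, endpoint=False)
        pert = spec.irregularity * (
            coeffs[None, :] * np.cos(np.outer(theta, k) + phases[None, :])
        ).sum(axis=1)
        worst = np.abs(pert).max()
        if worst > 0.9:  # keep the boundary star-shaped and strictly positive
            coeffs *= 0.9 / worst
    return coeffs, phases


def _radius_at(theta, spec: SyntheticSpec, coeffs, phases):
    r = np.full_like(np.asarray(theta, dtype=np.float64), spec.radius)
    for k, (c, phi) in enumerate(zip(coeffs, phases), start=1):
        r += spec.radius * spec.irregularity * c * np.cos(k * np.asarray(theta) + phi)
    return r


def _draw_hair(rng: np.random.Generator, img: np.ndarray, spec: SyntheticSpec) -> None:
    """Paint one dark 1-2 px polyline from border to border, no anti-aliasing."""
    h, w = img.shape[:2]
    sides = rng.choice(4, size=2, replace=False)

    def border_point(side):
        if side == 0:
            return (0, int(rng.integers(0, w)))
        if side == 1:
            return (h - 1, int(rng.integers(0, w)))
        if side == 2:
            return (int(rng.integers(0, h)), 0)
        return (int(rng.integers(0, h)), w - 1)

    p0, p1 = border_point(sides[0]), border_point(sides[1])
    jitter = int(0.15 * min(h, w))
    mid = (
        int(np.clip((p0[0] + p1[0]) // 2 + rng.integers(-jitter, jitter + 1), 0, h - 1)),
        int(np.clip((p0[1] + p1[1]) // 2 + rng.integers(-jitter, jitter + 1), 0, w - 1)),
    )
    width = int(rng.integers(1, 3))
    shade = int(np.clip(spec.hair_darkness + rng.integers(-10, 11), 0, 127))
    offsets = [(0, 0)] if width == 1 else [(0, 0), (int(rng.integers(0, 2)), 1)]
    # second stroke offset: (0,1) or (1,1) — a 2 px wide line either way
    for a, b in ((p0, mid), (mid, p1)):
        rr, cc = _draw_line(a[0], a[1], b[0], b[1])
        for dr, dc in offsets:
            r2 = np.clip(rr + dr, 0, h - 1)
            c2 = np.clip(cc + dc, 0, w - 1)
            img[r2, c2, :] = shade


def generate_fixture(spec: SyntheticSpec | None = None):
    """Render one fixture: (RGB uint8 image, {0,1} uint8 ground-truth mask)."""
    spec = (spec or SyntheticSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    coeffs, phases = _sample_harmonics(rng, spec)

    h, w = spec.height, spec.width
    cy, cx = spec.center if spec.center is not None else ((h - 1) / 2.0, (w - 1) / 2.0)
    rows, cols = np.mgrid[0:h, 0:w]
    dy = rows - cy
    dx = cols - cx
    rho = np.hypot(dy, dx)
    theta = np.arctan2(dy, dx)
    r_border = _radius_at(theta, spec, coeffs, phases)
    d = r_border - rho  # radial signed distance, > 0 inside the lesion

    if spec.transition_width > 0:
        s = expit(6.0 * d / spec.transition_width)
    else:
        s = (d > 0).astype(np.float64)
    skin = np.asarray(spec.skin_color, dtype=np.float64)
    lesion = np.asarray(spec.lesion_color, dtype=np.float64)
    img = skin[None, None, :] + s[:, :, None] * (lesion - skin)[None, None, :]

    if spec.noise_sd > 0:
        img = img + rng.normal(0.0, spec.noise_sd, size=img.shape)
    img = np.clip(img, 0.0, 255.0)

    img8 = np.rint(img).astype(np.uint8)
    for _ in range(spec.hair_count):
        _draw_hair(rng, img8, spec)

    if spec.vignette_frac > 0:
        field_radius = spec.vignette_frac * np.hypot(h, w) / 2.0
        centre_dist = np.hypot(rows - (h - 1) / 2.0, cols - (w - 1) / 2.0)
        img8[centre_dist > field_radius] = _VIGNETTE_SHADE

    mask = (rho < r_border).astype(np.uint8)
    return img8, mask


def boundary_area(spec: SyntheticSpec | None = None, n_theta: int = 4096) -> float:
    """Analytic area enclosed by the sampled boundary curve, 0.5 * int r^2 dtheta."""
    spec = (spec or SyntheticSpec()).validate()
    rng = np.random.default_rng(spec.seed)
    coeffs, phases = _sample_harmonics(rng, spec)
    theta = np.linspace(0.0, 2.0 * np.pi, n_theta, endpoint=False)
    r = _radius_at(theta, spec, coeffs, phases)
    return float(0.5 * np.sum(r**2) * (2.0 * np.pi / n_theta))


def suite_specs(n: int, base_spec: SyntheticSpec | None = None, master_seed: int = 0):
    """Derive the n per-image specs of a fixture suite from one master seed.

    Centre, radius, irregularity and hair count vary per image within
    PH2-like bounds (centre jitter +-8% of the image size, radius 0.75-1.25x
    the base, irregularity 0.5-1.5x, hair count 0..base); each image gets
    its own derived render seed.
    """
    if n < 1:
        raise ValueError(f"suite size must be >= 1, got {n}")
    base = (base_spec or SyntheticSpec()).validate()
    render_seeds = np.random.SeedSequence(master_seed).generate_state(n)
    specs = []
    for i in range(n):
        meta = np.random.default_rng(np.random.SeedSequence([master_seed, i]))
        cy = (base.height - 1) / 2.0 + meta.uniform(-0.08, 0.08) * base.height
        cx = (base.width - 1) / 2.0 + meta.uniform(-0.08, 0.08) * base.width
        specs.append(
            dataclasses.replace(
                base,
                center=(cy, cx),
                radius=base.radius * meta.uniform(0.75, 1.25),
                irregularity=base.irregularity * meta.uniform(0.5, 1.5),
                hair_count=int(meta.integers(0, base.hair_count + 1)),
                seed=int(render_seeds[i]),
            ).validate()
        )
    return specs


def generate_suite(n: int, base_spec: SyntheticSpec | None = None, master_seed: int = 0):
    """Generate n fixtures: list of (image, mask, identifier) triples."""
    return [
        (*generate_fixture(spec), f"synth_{i:03d}")
        for i, spec in enumerate(suite_specs(n, base_spec, master_seed))
    ]
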