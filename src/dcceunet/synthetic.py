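"""Seeded ultrasound-phantom generator.

Real ultrasound images of hypoechoic lesions are dominated by four
properties that make segmentation hard: multiplicative speckle texture, low
lesion/background contrast, blurred lesion boundaries, and irregular lesion
shapes.  The generator emulates exactly these:

* a smooth seeded background intensity field,
* lesion supports built from rotated ellipses whose radius is perturbed by
  a low-order Fourier series (irregular contours),
* a hypoechoic intensity drop inside the lesion (``contrast`` < 1), with the
  transition softened by a Gaussian of ``boundary_blur_sigma`` pixels,
* fully developed speckle as i.i.d. unit-mean Gamma multipliers
  ``G ~ Gamma(shape, 1/shape)``,
* an optional posterior attenuation band (acoustic shadowing) and additive
  electronic noise.

The binary ground-truth mask is the lesion support *before* boundary
blurring.  Everything is reproducible from the spec's seed.
``generate_dataset`` writes image/mask PNG pairs in the standard
``images/`` + ``masks/`` directory layout with a CSV manifest.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, asdict
from pathlib import Path

import numpy as np
from PIL import Image
from scipy.ndimage import gaussian_filter


@dataclass
class PhantomSpec:
    """Parameters of one synthetic phantom.

    ``lesion_axes`` is the (min, max) range in pixels of the ellipse
    semi-axes; when None it defaults to (0.10, 0.28) of the shorter image
    side.  ``contrast`` is the lesion/background intensity ratio (< 1:
    hypoechoic).  ``speckle_shape`` is the Gamma shape of the multiplicative
    speckle (``inf`` disables it).
    """

    image_size: tuple = (224, 224)
    lesion_count: int = 1
    lesion_axes: tuple | None = None
    boundary_blur_sigma: float = 1.5
    contrast: float = 0.5
    speckle_shape: float = 6.0
    shadow_prob: float = 0.15
    additive_noise_sigma: float = 0.02
    background_level: float = 0.55
    background_variation: float = 0.15
    background_smooth: float = 8.0
    seed: int = 0

    def __post_init__(self):
        self.image_size = tuple(int(s) for s in self.image_size)
        h, w = self.image_size
        if self.lesion_axes is None:
            m = min(h, w)
            self.lesion_axes = (0.10 * m, 0.28 * m)
        self.lesion_axes = tuple(float(a) for a in self.lesion_axes)
        if not (0 < self.contrast < 1):
            raise ValueError("contrast must lie in (0, 1): lesions are hypoechoic")
        if self.lesion_axes[0] <= 0 or self.lesion_axes[0] > self.lesion_axes[1]:
            raise ValueError("lesion_axes must be a positive (min, max) range")
        # the largest perturbed ellipse must fit inside the image
        if 2 * self.lesion_axes[1] * (1 + _MAX_PERTURB) > min(h, w):
            raise ValueError(
                f"lesion axes up to {self.lesion_axes[1]:.1f}px do not fit in {h}x{w}")
        if self.lesion_count < 0 or not (0 <= self.shadow_prob <= 1):
            raise ValueError("invalid lesion_count or shadow_prob")
        if self.boundary_blur_sigma < 0 or self.additive_noise_sigma < 0:
            raise ValueError("noise and blur parameters must be nonnegative")
        if not self.speckle_shape > 0:
            raise ValueError("speckle_shape must be positive")


_MAX_PERTURB = 0.20  # peak relative radius perturbation of the Fourier contour


def _lesion_support(rng, h, w, axes_range):
    """Rasterise one randomly placed, rotated, Fourier-perturbed ellipse."""
    a = rng.uniform(*axes_range)
    b = rng.uniform(*axes_range)
    theta = rng.uniform(0, np.pi)
    margin = max(a, b) * (1 + _MAX_PERTURB) + 1
    cy = rng.uniform(margin, h - margin)
    cx = rng.uniform(margin, w - margin)
    # low-order harmonics -> smooth but irregular contour
    n_harm = 4
    amp = rng.uniform(0, _MAX_PERTURB / n_harm, n_harm)
    phase = rng.uniform(0, 2 * np.pi, n_harm)
    yy, xx = np.mgrid[0:h, 0:w]
    dy, dx = yy - cy, xx - cx
    u = (dx * np.cos(theta) + dy * np.sin(theta)) / a
    v = (-dx * np.sin(theta) + dy * np.cos(theta)) / b
    rho = np.hypot(u, v)
    phi = np.arctan2(v, u)
    r = 1.0 + sum(amp[k] * np.cos((k + 2) * phi + phase[k]) for k in range(n_harm))
    return rho <= r, (cy, cx, a, b)


def generate_phantom(spec: PhantomSpec):
    """Generate one phantom; returns ``(image, mask)``.

    ``image`` is float32 in [0, 1]; ``mask`` is a boolean array marking the
    lesion support before boundary blurring.
    """
    rng = np.random.default_rng(spec.seed)
    h, w = spec.image_size
    # smooth seeded background field
    if spec.background_variation > 0:
        g = gaussian_filter(rng.standard_normal((h, w)), spec.background_smooth)
        s = g.std()
        if s > 0:
            g = g / s
        bg = spec.background_level * (1.0 + spec.background_variation * g)
    else:
        rng.standard_normal((h, w))  # keep the stream aligned across settings
        bg = np.full((h, w), spec.background_level)
    bg = np.clip(bg, 0.05, 0.95)

    mask = np.zeros((h, w), dtype=bool)
    extents = []
    for _ in range(spec.lesion_count):
        support, geom = _lesion_support(rng, h, w, spec.lesion_axes)
        mask |= support
        extents.append(geom)

    soft = mask.astype(np.float64)
    if spec.boundary_blur_sigma > 0:
        soft = gaussian_filter(soft, spec.boundary_blur_sigma)
    img = bg * (1.0 - (1.0 - spec.contrast) * soft)

    if np.isfinite(spec.speckle_shape):
        img = img * rng.gamma(spec.speckle_shape, 1.0 / spec.speckle_shape, (h, w))

    # posterior acoustic shadow: darken a vertical band below the lesion
    for cy, cx, a, b in extents:
        if rng.random() < spec.shadow_prob:
            half = 0.7 * max(a, b)
            x0, x1 = int(max(0, cx - half)), int(min(w, cx + half))
            y0 = int(min(h, cy + min(a, b)))
            img[y0:, x0:x1] *= rng.uniform(0.5, 0.8)

    if spec.additive_noise_sigma > 0:
        img = img + rng.normal(0.0, spec.additive_noise_sigma, (h, w))

    return np.clip(img, 0.0, 1.0).astype(np.float32), mask


def _write_png(path: Path, arr: np.ndarray):
    Image.fromarray(arr.astype(np.uint8), mode="L").save(path, format="PNG")


def generate_dataset(n: int, out_dir, seed: int = 0, image_size=(224, 224),
                     lesion_count: int = 1, lesion_axes=None,
                     contrast_range=(0.35, 0.65), blur_range=(1.0, 2.0),
                     speckle_shape: float = 6.0, shadow_prob: float = 0.15,
                     additive_noise_sigma: float = 0.02):
    """Write ``n`` phantom image/mask PNG pairs plus a CSV manifest.

    Layout: ``out_dir/images/<stem>.png`` and ``out_dir/masks/<stem>.png``
    with matching stems; masks are strictly {0, 255}.  Per-sample seeds and
    per-sample contrast/blur draws derive deterministically from ``seed``,
    so a re-run reproduces the files byte for byte.  Returns the manifest as
    a list of dicts (also written to ``out_dir/manifest.csv``).
    """
    out = Path(out_dir)
    (out / "images").mkdir(parents=True, exist_ok=True)
    (out / "masks").mkdir(parents=True, exist_ok=True)
    master = np.random.default_rng(seed)
    manifest, seen = [], set()
    for i in range(n):
        stem = f"phantom_{i:04d}"
        if stem in seen:
            raise ValueError(f"duplicate stem {stem}")
        seen.add(stem)
        spec = PhantomSpec(
            image_size=image_size, lesion_count=lesion_count,
            lesion_axes=lesion_axes,
            contrast=float(master.uniform(*contrast_range)),
            boundary_blur_sigma=float(master.uniform(*blur_range)),
            speckle_shape=speckle_shape, shadow_prob=shadow_prob,
            additive_noise_sigma=additive_noise_sigma,
            seed=int((seed * 1000003 + i) % 2**31),
        )
        img, mask = generate_phantom(spec)
        _write_png(out / "images" / f"{stem}.png", np.round(img * 255))
        _write_png(out / "masks" / f"{stem}.png", mask * 255)
        manifest.append({
            "stem": stem,
            "lesion_area_px": int(mask.sum()),
            "contrast": round(spec.contrast, 6),
            "boundary_blur_sigma": round(spec.boundary_blur_sigma, 6),
            "seed": spec.seed,
        })
    with open(out / "manifest.csv", "w", newline="") as fh:
        writer = csv.DictWriter(fh, fieldnames=list(manifest[0]))
        writer.writeheader()
        writer.writerows(manifest)
    return manifest
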