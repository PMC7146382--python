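"""Seeded generator of H&E-like images with nest ground truth.

Real training data for this task are whole-slide-image crops of skin stained
with hematoxylin and eosin: pink eosin-stained stroma with scattered
blue-purple hematoxylin-stained nuclei, where "nests" are dense clusters of
dozens of nevus cells.  The generator emulates only the statistical
structure the segmentation pipeline relies on:

* an eosin-pink background with low-frequency multiplicative texture and
  i.i.d. pixel noise,
* hematoxylin-purple cell disks grouped into a few roughly round nests per
  image, with per-cell colour jitter,
* an exact binary ground-truth mask, defined as the morphological closing of
  the union of each nest's cell disks,
* a mixed corpus of labeled (mask present) and unlabeled images of varying
  sizes.

Everything is driven by ``numpy.random.Generator`` seeded explicitly, so a
(params, seed) pair maps to a bit-identical image.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, replace
from pathlib import Path

import numpy as np
from PIL import Image
from scipy import ndimage


class ParameterError(ValueError):
    """Invalid generator parameters."""


@dataclass(frozen=True)
class SynthParams:
    """Knobs of the synthetic H&E slide generator.

    Colour means are RGB in [0, 1].  Defaults approximate eosin-pink stroma
    and hematoxylin-purple nuclei at moderate magnification, with nests big
    enough (tens of pixels across) that a 16x16 latent grid can resolve them.
    """

    image_height: int = 256
    image_width: int = 384
    nest_count_range: tuple[int, int] = (2, 4)
    nest_radius_range: tuple[int, int] = (22, 36)
    cells_per_nest_range: tuple[int, int] = (30, 80)
    cell_radius_range: tuple[int, int] = (4, 8)
    background_rgb_mean: tuple[float, float, float] = (0.91, 0.77, 0.86)
    nucleus_rgb_mean: tuple[float, float, float] = (0.42, 0.28, 0.58)
    color_jitter_sd: float = 0.04
    noise_sd: float = 0.02
    labeled: bool = True

    def validate(self) -> None:
        for name in ("nest_count_range", "nest_radius_range",
                     "cells_per_nest_range", "cell_radius_range"):
            lo, hi = getattr(self, name)
            if lo > hi or lo < 0:
                raise ParameterError(f"{name} must satisfy 0 <= min <= max")
        if self.image_height < 128 or self.image_width < 128:
            raise ParameterError("image dims must be >= 128")
        for name in ("background_rgb_mean", "nucleus_rgb_mean"):
            if not all(0.0 <= v <= 1.0 for v in getattr(self, name)):
                raise ParameterError(f"{name} components must lie in [0, 1]")
        if self.color_jitter_sd < 0 or self.noise_sd < 0:
            raise ParameterError("noise levels must be nonnegative")


@dataclass
class SlideImage:
    """One RGB image with optional binary nest mask; the unit of splitting."""

    image_id: str
    rgb: np.ndarray  # H x W x 3 float in [0, 1]
    mask: np.ndarray | None  # H x W uint8 in {0, 1}, present iff labeled
    labeled: bool

    def __post_init__(self):
        if self.mask is not None:
            if self.mask.shape != self.rgb.shape[:2]:
                raise ParameterError("mask and rgb spatial shapes differ")
        if self.labeled != (self.mask is not None):
            raise ParameterError("labeled flag must match mask presence")

    @property
    def shape(self) -> tuple[int, int]:
        return self.rgb.shape[:2]


@dataclass(frozen=True)
class NestGeometry:
    """Cell-disk geometry of one generated image: (row, col, radius) per cell,
    grouped per nest, plus the closing radius used to fill inter-cell gaps."""

    nests: tuple[tuple[tuple[float, float, float], ...], ...]
    closing_radius: int


def _disk_footprint(radius: int) -> np.ndarray:
    r = int(radius)
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    return (yy * yy + xx * xx) <= r * r


def sample_geometry(params: SynthParams, rng: np.random.Generator,
                    height: int | None = None, width: int | None = None
                    ) -> NestGeometry:
    """Draw nest centers (rejecting heavy overlaps) and per-nest cell disks."""
    h = height if height is not None else params.image_height
    w = width if width is not None else params.image_width
    n_nests = int(rng.integers(params.nest_count_range[0],
                               params.nest_count_range[1] + 1))
    centers: list[tuple[float, float, float]] = []
    nests = []
    for _ in range(n_nests):
        radius = float(rng.uniform(*params.nest_radius_range))
        for _try in range(50):
            cy = float(rng.uniform(radius, h - radius))
            cx = float(rng.uniform(radius, w - radius))
            # reject centers closer than 80% of the radii sum
            if all(np.hypot(cy - oy, cx - ox) >= 0.8 * (radius + orad)
                   for oy, ox, orad in centers):
                break
        centers.append((cy, cx, radius))
        n_cells = int(rng.integers(params.cells_per_nest_range[0],
                                   params.cells_per_nest_range[1] + 1))
        cells = []
        for _ in range(n_cells):
            ang = rng.uniform(0.0, 2.0 * np.pi)
            rad = radius * np.sqrt(rng.uniform(0.0, 1.0))
            cr = float(rng.uniform(*params.cell_radius_range))
            cells.append((cy + rad * np.sin(ang), cx + rad * np.cos(ang), cr))
        nests.append(tuple(cells))
    closing_radius = max(2, int(round(params.cell_radius_range[1])))
    return NestGeometry(tuple(nests), closing_radius)


def rasterize_mask(geometry: NestGeometry, height: int, width: int) -> np.ndarray:
    """Ground truth: morphological closing of the union of all cell disks."""
    union = np.zeros((height, width), bool)
    for cells in geometry.nests:
        for cy, cx, cr in cells:
            r = int(np.ceil(cr))
            y0, y1 = max(0, int(cy) - r), min(height, int(cy) + r + 2)
            x0, x1 = max(0, int(cx) - r), min(width, int(cx) + r + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            union[y0:y1, x0:x1] |= (yy - cy) ** 2 + (xx - cx) ** 2 <= cr * cr
    closed = ndimage.binary_closing(
        union, structure=_disk_footprint(geometry.closing_radius),
        border_value=0
    )
    return closed.astype(np.uint8)


def _render(params: SynthParams, geometry: NestGeometry, rng: np.random.Generator,
            height: int, width: int) -> np.ndarray:
    """Paint background texture, then cell disks with jittered nucleus colour."""
    bg = np.asarray(params.background_rgb_mean, np.float64)
    # low-frequency multiplicative texture: heavily smoothed white noise
    field_ = rng.standard_normal((height, width))
    field_ = ndimage.gaussian_filter(field_, sigma=16.0)
    sd = field_.std()
    if sd > 0:
        field_ = field_ / sd * 0.05
    rgb = bg[None, None, :] * (1.0 + field_[:, :, None])
    nucleus = np.asarray(params.nucleus_rgb_mean, np.float64)
    for cells in geometry.nests:
        for cy, cx, cr in cells:
            colour = nucleus + rng.normal(0.0, params.color_jitter_sd, 3)
            r = int(np.ceil(cr))
            y0, y1 = max(0, int(cy) - r), min(height, int(cy) + r + 2)
            x0, x1 = max(0, int(cx) - r), min(width, int(cx) + r + 2)
            if y0 >= y1 or x0 >= x1:
                continue
            yy, xx = np.mgrid[y0:y1, x0:x1]
            disk = (yy - cy) ** 2 + (xx - cx) ** 2 <= cr * cr
            rgb[y0:y1, x0:x1][disk] = colour
    rgb += rng.normal(0.0, params.noise_sd, rgb.shape)
    return np.clip(rgb, 0.0, 1.0)


def generate_slide(params: SynthParams, seed: int, image_id: str | None = None,
                   height: int | None = None, width: int | None = None
                   ) -> SlideImage:
    """Generate one synthetic H&E-like slide image.

    The mask (present iff ``params.labeled``) is exactly
    ``rasterize_mask(sample_geometry(...))`` for the same seeded geometry.
    """
    params.validate()
    h = height if height is not None else params.image_height
    w = width if width is not None else params.image_width
    rng = np.random.default_rng(seed)
    geometry = sample_geometry(params, rng, h, w)
    rgb = _render(params, geometry, rng, h, w)
    mask = rasterize_mask(geometry, h, w) if params.labeled else None
    return SlideImage(image_id or f"slide_{seed:06d}",
                      rgb.astype(np.float32), mask, params.labeled)


def generate_corpus(n_images: int, labeled_fraction: float, params: SynthParams,
                    seed: int, size_steps: int = 2) -> list[SlideImage]:
    """Generate a mixed labeled/unlabeled corpus.

    Exactly ``round(n_images * labeled_fraction)`` images carry masks; which
    ones is decided by a seeded permutation.  Image heights/widths vary in
    steps of 64 px up to ``size_steps`` steps above the configured base dims.
    """
    params.validate()
    if n_images <= 0:
        raise ParameterError("n_images must be positive")
    if not 0.0 <= labeled_fraction <= 1.0:
        raise ParameterError("labeled_fraction must lie in [0, 1]")
    n_labeled = int(np.floor(n_images * labeled_fraction + 0.5))
    rng = np.random.default_rng(seed)
    labeled_idx = set(rng.permutation(n_images)[:n_labeled].tolist())
    slides = []
    for i in range(n_images):
        h = params.image_height + 64 * int(rng.integers(0, size_steps + 1))
        w = params.image_width + 64 * int(rng.integers(0, size_steps + 1))
        sub_seed = int(rng.integers(0, 2**31 - 1))
        p = replace(params, labeled=(i in labeled_idx))
        slides.append(
            generate_slide(p, sub_seed, image_id=f"img_{i:04d}", height=h, width=w)
        )
    return slides


# -- disk I/O ---------------------------------------------------------------

def write_corpus(slides: list[SlideImage], out_dir) -> Path:
    """Write 8-bit RGB PNGs, {0,255} mask PNGs and a manifest CSV; returns
    the manifest path."""
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    manifest = out / "manifest.csv"
    with open(manifest, "w", newline="") as fh:
        writer = csv.writer(fh)
        writer.writerow(["image_id", "path", "mask_path", "labeled",
                         "height", "width"])
        for s in slides:
            img_path = out / f"{s.image_id}.png"
            Image.fromarray((s.rgb * 255).round().astype(np.uint8)).save(img_path)
            mask_path = ""
            if s.mask is not None:
                mask_path = str(out / f"{s.image_id}_mask.png")
                Image.fromarray((s.mask * 255).astype(np.uint8)).save(mask_path)
            writer.writerow([s.image_id, str(img_path), mask_path,
                             int(s.labeled), *s.shape])
    return manifest


def read_corpus(manifest_path) -> list[SlideImage]:
    """Load a corpus previously written by :func:`write_corpus`."""
    slides = []
    with open(manifest_path, newline="") as fh:
        for row in csv.DictReader(fh):
            rgb = np.asarray(Image.open(row["path"]).convert("RGB"),
                             np.float32) / 255.0
            mask = None
            if row["mask_path"]:
                m = np.asarray(Image.open(row["mask_path"]).convert("L"))
                mask = (m >= 128).astype(np.uint8)
            slides.append(SlideImage(row["image_id"], rgb, mask,
                                     bool(int(row["labeled"]))))
    return slides
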