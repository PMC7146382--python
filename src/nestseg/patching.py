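"""Image-level splitting and 128x128 patch extraction.

The corpus is split into train/validation/test at the *image* level, before
any patch is cut, stratified so each split keeps the corpus's
labeled-to-unlabeled proportion.  Patches are then extracted on a regular
grid with a coarse stride; wherever a grid window touches nest mask, its
3x3 grid neighbourhood is re-scanned with a finer stride so the positive
class is oversampled.  Positive patches are further augmented by rotation
(45-degree steps by default) to balance the classes.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from scipy import ndimage

from .synthdata import SlideImage


class ConfigurationError(ValueError):
    pass


class DataError(ValueError):
    pass


SPLITS = ("train", "validation", "test")


@dataclass(frozen=True)
class SplitAssignment:
    """Map image_id -> split, produced before any patching."""

    assignment: dict[str, str]
    fractions: tuple[float, float, float]
    seed: int

    def ids(self, split: str) -> list[str]:
        return [i for i, s in self.assignment.items() if s == split]


@dataclass(frozen=True)
class PatchConfig:
    """Stride and augmentation rules for patch extraction.

    ``negative_stride`` is the coarse grid step (no overlap at the default
    128); ``positive_stride`` the fine step used around nest-bearing
    windows (50% overlap at the default 64).  A window counts as positive
    when its mask tile has at least ``positive_rule`` nest pixels.
    """

    patch_size: int = 128
    negative_stride: int = 128
    positive_stride: int = 64
    augment_angles: tuple[float, ...] = (45.0, 90.0, 135.0, 180.0)
    positive_rule: int = 1

    def validate(self) -> None:
        if not (1 <= self.positive_stride <= self.negative_stride
                <= self.patch_size):
            raise ConfigurationError(
                "need 1 <= positive_stride <= negative_stride <= patch_size")
        if not self.augment_angles:
            raise ConfigurationError("augment_angles must be nonempty")
        if not all(0.0 < a < 360.0 for a in self.augment_angles):
            raise ConfigurationError("augment angles must lie in (0, 360)")
        if self.positive_rule < 1:
            raise ConfigurationError("positive_rule must be >= 1")


@dataclass
class Patch:
    """One 128x128 network input tile with its provenance."""

    source_id: str
    origin: tuple[int, int]  # 0-based (row, col) of the top-left pixel
    rgb: np.ndarray  # patch_size x patch_size x 3 float32 in [0, 1]
    mask: np.ndarray | None  # patch_size x patch_size uint8, if labeled
    positive: bool
    augmented: bool = False


def _largest_remainder(n: int, fractions) -> list[int]:
    """Apportion n items to fractions, largest fractional remainder first."""
    raw = [n * f for f in fractions]
    counts = [int(math.floor(r)) for r in raw]
    rem = n - sum(counts)
    order = sorted(range(len(fractions)), key=lambda i: raw[i] - counts[i],
                   reverse=True)
    for i in order[:rem]:
        counts[i] += 1
    return counts


def split_corpus(images: list[SlideImage], fractions, seed: int
                 ) -> SplitAssignment:
    """Stratified image-level train/validation/test assignment.

    Labeled and unlabeled images are apportioned independently with
    largest-remainder rounding, so each split's labeled share tracks the
    corpus share; a 70/39-labeled corpus at 0.70/0.143/0.157 lands at
    49/10/11 images overall and 27/6/6 labeled.
    """
    fractions = tuple(float(f) for f in fractions)
    if len(fractions) != 3 or any(f < 0 for f in fractions):
        raise ConfigurationError("need 3 nonnegative fractions")
    if abs(sum(fractions) - 1.0) > 1e-9:
        raise ConfigurationError("fractions must sum to 1")
    n_nonzero = sum(f > 0 for f in fractions)
    if len(images) < n_nonzero:
        raise ConfigurationError("fewer images than nonzero splits")
    rng = np.random.default_rng(seed)
    assignment: dict[str, str] = {}
    for flag in (True, False):
        ids = [s.image_id for s in images if s.labeled == flag]
        if not ids:
            continue
        ids = [ids[i] for i in rng.permutation(len(ids))]
        counts = _largest_remainder(len(ids), fractions)
        pos = 0
        for split, k in zip(SPLITS, counts):
            for image_id in ids[pos : pos + k]:
                assignment[image_id] = split
            pos += k
    return SplitAssignment(assignment, fractions, seed)


def _pad_reflect(arr: np.ndarray, target_h: int, target_w: int) -> np.ndarray:
    """Reflect-pad bottom/right so the full image is covered by the grid."""
    ph, pw = target_h - arr.shape[0], target_w - arr.shape[1]
    if ph == 0 and pw == 0:
        return arr
    widths = ((0, ph), (0, pw)) + ((0, 0),) * (arr.ndim - 2)
    return np.pad(arr, widths, mode="reflect")


def padded_extent(size: int, patch: int, stride: int) -> int:
    """Smallest grid-covering extent >= size: patch + k*stride, k minimal."""
    if size <= patch:
        return patch
    k = math.ceil((size - patch) / stride)
    return patch + k * stride


def grid_origins(size: int, patch: int, stride: int) -> list[int]:
    """Origins of a stride-regular scan over the padded extent."""
    extent = padded_extent(size, patch, stride)
    return list(range(0, extent - patch + 1, stride))


def extract_patches(image: SlideImage, config: PatchConfig | None = None
                    ) -> list[Patch]:
    """Cut a slide into patches under the class-dependent stride rules.

    Unlabeled images yield mask-less patches on the coarse grid only.  For
    labeled images, every coarse grid window whose mask tile is positive
    triggers a fine re-scan of its 3x3 grid-cell neighbourhood; duplicate
    origins are dropped.  Images not covered exactly by the grid are
    reflect-padded on the bottom/right first.
    """
    config = config or PatchConfig()
    config.validate()
    p = config.patch_size
    if image.mask is not None and image.mask.shape != image.rgb.shape[:2]:
        raise DataError("mask/rgb size mismatch")
    h, w = image.shape
    hp = padded_extent(h, p, config.negative_stride)
    wp = padded_extent(w, p, config.negative_stride)
    rgb = _pad_reflect(image.rgb, hp, wp)
    mask = _pad_reflect(image.mask, hp, wp) if image.mask is not None else None

    rows = grid_origins(h, p, config.negative_stride)
    cols = grid_origins(w, p, config.negative_stride)
    origins = {(r, c) for r in rows for c in cols}
    if mask is not None:
        def is_pos(r, c):
            return int(mask[r : r + p, c : c + p].sum()) >= config.positive_rule

        for gi, r in enumerate(rows):
            for gj, c in enumerate(cols):
                if not is_pos(r, c):
                    continue
                r_lo = rows[max(gi - 1, 0)]
                r_hi = rows[min(gi + 1, len(rows) - 1)]
                c_lo = cols[max(gj - 1, 0)]
                c_hi = cols[min(gj + 1, len(cols) - 1)]
                for rr in range(r_lo, r_hi + 1, config.positive_stride):
                    for cc in range(c_lo, c_hi + 1, config.positive_stride):
                        origins.add((rr, cc))
    patches = []
    for r, c in sorted(origins):
        mtile = mask[r : r + p, c : c + p].copy() if mask is not None else None
        positive = (mtile is not None
                    and int(mtile.sum()) >= config.positive_rule)
        patches.append(Patch(image.image_id, (r, c),
                             np.ascontiguousarray(rgb[r : r + p, c : c + p]),
                             mtile, positive))
    return patches


def augment_patch(patch: Patch, angles=None, strict: bool = True) -> list[Patch]:
    """Rotate a positive patch by each angle about its center.

    Right angles are exact pixel permutations (``np.rot90``); other angles
    use bilinear interpolation with reflect padding for the image and
    nearest-neighbour (re-binarized) rotation for the mask.
    """
    angles = tuple(angles) if angles is not None else (45.0, 90.0, 135.0, 180.0)
    if strict and not patch.positive:
        raise DataError("augmentation is applied to positive (nest) patches")
    out = []
    for angle in angles:
        if angle % 90 == 0:
            k = int(angle // 90) % 4
            rgb = np.ascontiguousarray(np.rot90(patch.rgb, k))
            mask = (np.ascontiguousarray(np.rot90(patch.mask, k))
                    if patch.mask is not None else None)
        else:
            rgb = ndimage.rotate(patch.rgb, angle, axes=(0, 1), reshape=False,
                                 order=1, mode="reflect").astype(np.float32)
            np.clip(rgb, 0.0, 1.0, out=rgb)
            mask = None
            if patch.mask is not None:
                m = ndimage.rotate(patch.mask.astype(np.float32), angle,
                                   axes=(0, 1), reshape=False, order=0,
                                   mode="reflect")
                mask = (m >= 0.5).astype(np.uint8)
        positive = patch.positive if mask is None else bool(mask.sum() >= 1)
        out.append(Patch(patch.source_id, patch.origin, rgb, mask,
                         positive, augmented=True))
    return out


@dataclass(frozen=True)
class BalanceReport:
    n_positive: int
    n_negative: int

    @property
    def ratio(self) -> float:
        """positive:negative ratio; inf when no negatives, nan when empty."""
        if self.n_negative == 0:
            return float("inf") if self.n_positive else float("nan")
        return self.n_positive / self.n_negative


def balance_report(patches: list[Patch]) -> BalanceReport:
    n_pos = sum(p.positive for p in patches)
    return BalanceReport(n_pos, len(patches) - n_pos)


def augment_positives(patches: list[Patch], config: PatchConfig | None = None
                      ) -> list[Patch]:
    """Append the rotation-augmented variants of every positive patch."""
    config = config or PatchConfig()
    out = list(patches)
    for patch in patches:
        if patch.positive:
            out.extend(augment_patch(patch, config.augment_angles))
    return out


def write_patch_index(patches: list[Patch], path,
                      split_of: dict[str, str] | None = None) -> None:
    """Patch index CSV: source image, origin, class and augmentation flags."""
    import csv

    with open(path, "w", newline="") as fh:
        w = csv.writer(fh)
        w.writerow(["source_id", "row", "col", "positive", "augmented", "split"])
        for p in patches:
            split = (split_of or {}).get(p.source_id, "")
            w.writerow([p.source_id, p.origin[0], p.origin[1],
                        int(p.positive), int(p.augmented), split])
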