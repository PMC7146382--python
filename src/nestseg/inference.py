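"""Whole-image mask prediction by tiling, batching and stitching.

An arbitrary-size image is reflect-padded on the bottom/right to the
smallest grid-covered extent, cut into 128x128 tiles, pushed through the
segmentation head, and the per-tile probability maps are reassembled.
Overlapping tiles (stride < 128) contribute the mean of their values to each
pixel; the default stride of 128 is non-overlapping, so stitching is then an
exact reassembly.  The binary mask thresholds the stitched probability at
0.5 by default, with ties counted as positive.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import tifffile
from PIL import Image

from .model import CAEModel, ContractError
from .patching import _pad_reflect, grid_origins, padded_extent

PATCH = 128


@dataclass
class ProbabilityMap:
    values: np.ndarray  # H x W float in [0, 1]
    source_id: str

    def save_tiff(self, path) -> None:
        tifffile.imwrite(path, self.values.astype(np.float32))


@dataclass
class BinaryMask:
    values: np.ndarray  # H x W uint8 in {0, 1}
    threshold_used: float

    def save_png(self, path) -> None:
        Image.fromarray((self.values * 255).astype(np.uint8)).save(path)


def tile_image(image, stride: int = PATCH) -> list[tuple[tuple[int, int], np.ndarray]]:
    """Cut an image (or bare H x W [x C] array) into 128x128 tiles covering
    every pixel, reflect-padding the bottom/right edge when needed."""
    if not 1 <= stride <= PATCH:
        raise ContractError("stride must lie in [1, 128]")
    arr = image.rgb if hasattr(image, "rgb") else np.asarray(image)
    h, w = arr.shape[:2]
    hp = padded_extent(h, PATCH, stride)
    wp = padded_extent(w, PATCH, stride)
    padded = _pad_reflect(arr, hp, wp)
    tiles = []
    for r in grid_origins(h, PATCH, stride):
        for c in grid_origins(w, PATCH, stride):
            tiles.append(((r, c),
                          np.ascontiguousarray(padded[r : r + PATCH,
                                                      c : c + PATCH])))
    return tiles


def stitch(tiles, canvas_shape: tuple[int, int], source_id: str = ""
           ) -> ProbabilityMap:
    """Reassemble per-tile probability maps; overlaps average contributions.

    ``canvas_shape`` is the *unpadded* image shape; padding rows/cols beyond
    it are cropped away.  Raises if any canvas pixel is left uncovered.
    """
    h, w = canvas_shape
    hp = max(h, max((r for (r, _), _ in tiles), default=0) + PATCH)
    wp = max(w, max((c for (_, c), _ in tiles), default=0) + PATCH)
    acc = np.zeros((hp, wp), np.float64)
    cnt = np.zeros((hp, wp), np.int64)
    for (r, c), tile in tiles:
        t = np.asarray(tile)
        if t.ndim == 3:
            t = t[:, :, 0]
        acc[r : r + PATCH, c : c + PATCH] += t
        cnt[r : r + PATCH, c : c + PATCH] += 1
    acc, cnt = acc[:h, :w], cnt[:h, :w]
    if (cnt == 0).any():
        raise ContractError("stitch: uncovered canvas pixels")
    return ProbabilityMap(acc / cnt, source_id)


def predict_mask(model: CAEModel, image, stride: int = PATCH,
                 threshold: float = 0.5, batch_size: int = 16
                 ) -> tuple[BinaryMask, ProbabilityMap]:
    """Whole-image nest probability map and thresholded binary mask.

    The comparison at the threshold is ``>=``, so probabilities exactly at
    the threshold are positive.
    """
    if model.spec.variant != "segmentation":
        raise ContractError("predict_mask requires the segmentation variant")
    if not 0.0 < threshold < 1.0:
        raise ContractError("threshold must lie in (0, 1)")
    tiles = tile_image(image, stride)
    origins = [o for o, _ in tiles]
    rgbs = np.stack([t for _, t in tiles]).astype(np.float32)
    probs = []
    for i in range(0, len(rgbs), batch_size):
        out = model.forward(rgbs[i : i + batch_size])
        probs.extend(out[j, :, :, 0].copy() for j in range(out.shape[0]))
    source_id = getattr(image, "image_id", "")
    pmap = stitch(list(zip(origins, probs)),
                  (image.rgb if hasattr(image, "rgb") else image).shape[:2],
                  source_id)
    mask = BinaryMask((pmap.values >= threshold).astype(np.uint8), threshold)
    return mask, pmap
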