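"""Image preparation for distance-transform regression.

Covers the four steps between a raw montage and network-ready tensors:
validity-mask erosion (von Neumann structuring element, with the named presets
used for training vs. inference), distance-transform label construction,
random training crops, and the inference tiling / stitching pair.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
from scipy.ndimage import binary_erosion, generate_binary_structure
from scipy.spatial import cKDTree

from .core import ConeSet, ScalarMap, ValidityMask

#: Named erosion presets: heavy erosion before training crops (border artifacts
#: must not enter the loss), light erosion at inference (keep image content).
EROSION_ITERS_TRAINING = 64
EROSION_ITERS_INFERENCE = 2

#: Distance labels are clipped at this radius (px) by default so the
#: regression target is informative near cones instead of being dominated by
#: large distances in cone-free regions.
DEFAULT_LABEL_CAP_PX = 8.0


@dataclass
class Patch:
    crop: np.ndarray
    label: np.ndarray | None
    offset: tuple[int, int]  # (row, col) of the crop's top-left corner


@dataclass
class PatchSet:
    patches: list[Patch]
    size: int
    padded: bool = False  # True when a too-small image was zero-padded

    def __len__(self) -> int:
        return len(self.patches)

    def __iter__(self):
        return iter(self.patches)


def erode_mask(mask: ValidityMask, iterations: int) -> ValidityMask:
    """Iterated binary erosion with the 4-connected (plus-shaped) element."""
    if iterations < 0:
        raise ValueError("iterations must be >= 0")
    if iterations == 0:
        return ValidityMask(mask.mask.copy())
    struct = generate_binary_structure(2, 1)
    out = binary_erosion(mask.mask, structure=struct, iterations=iterations,
                         border_value=0)
    if not out.any():
        warnings.warn("mask became empty after erosion", stacklevel=2)
    return ValidityMask(out)


def distance_label(cones: ConeSet, shape: tuple[int, int],
                   cap_px: float = DEFAULT_LABEL_CAP_PX) -> ScalarMap:
    """Per-pixel Euclidean distance to the nearest cone center, clipped at cap.

    The distance is measured from pixel centers (integer coordinates) to the
    sub-pixel cone positions, so it is zero only where a cone center rounds
    onto the pixel itself.
    """
    if len(cones) == 0:
        raise ValueError("cannot build a distance label from an empty cone set")
    if cap_px <= 0:
        raise ValueError("cap_px must be positive")
    h, w = shape
    yy, xx = np.mgrid[0:h, 0:w]
    pix = np.column_stack([xx.ravel(), yy.ravel()]).astype(float)
    d, _ = cKDTree(cones.xy).query(pix)
    return ScalarMap(np.minimum(d, cap_px).reshape(h, w))


def random_crops(image: np.ndarray, label: ScalarMap | None, mask: ValidityMask,
                 n: int = 256, size: int = 256, seed: int = 0) -> PatchSet:
    """Randomly placed, overlapping square training crops.

    Crop footprints are constrained to the bounding box of the valid mask so
    eroded borders never enter a training patch. Offsets are uniform over the
    admissible range; identical seeds give identical crops.
    """
    rows = np.flatnonzero(mask.mask.any(axis=1))
    cols = np.flatnonzero(mask.mask.any(axis=0))
    if rows.size == 0:
        raise ValueError("validity mask is empty")
    r0, r1 = int(rows[0]), int(rows[-1]) + 1
    c0, c1 = int(cols[0]), int(cols[-1]) + 1
    if (r1 - r0) < size or (c1 - c0) < size:
        raise ValueError(
            f"valid region {(r1 - r0)}x{(c1 - c0)} is smaller than crop size {size}"
        )
    rng = np.random.default_rng(seed)
    offs_r = rng.integers(r0, r1 - size + 1, size=n)
    offs_c = rng.integers(c0, c1 - size + 1, size=n)
    patches = []
    for r, c in zip(offs_r, offs_c):
        crop = image[r:r + size, c:c + size]
        lab = None if label is None else label.data[r:r + size, c:c + size]
        patches.append(Patch(crop=np.array(crop), label=None if lab is None else np.array(lab),
                             offset=(int(r), int(c))))
    return PatchSet(patches=patches, size=size)


def tile_for_inference(image: np.ndarray, size: int = 256,
                       overlap: int = 32) -> PatchSet:
    """Regular tiling with stride ``size - overlap``; the last row/column is
    shifted inward so tiles never exceed the image. Covers every pixel."""
    if overlap >= size:
        raise ValueError("overlap must be smaller than tile size")
    h, w = image.shape
    if h < size or w < size:
        pad = np.zeros((max(h, size), max(w, size)), dtype=image.dtype)
        pad[:h, :w] = image
        return PatchSet(patches=[Patch(crop=pad, label=None, offset=(0, 0))],
                        size=size, padded=True)
    stride = size - overlap

    def _starts(extent: int) -> list[int]:
        s = list(range(0, extent - size + 1, stride))
        if s[-1] != extent - size:
            s.append(extent - size)
        return s

    patches = [
        Patch(crop=np.array(image[r:r + size, c:c + size]), label=None, offset=(r, c))
        for r in _starts(h) for c in _starts(w)
    ]
    return PatchSet(patches=patches, size=size)


def stitch(predictions: PatchSet, shape: tuple[int, int]) -> ScalarMap:
    """Average overlapping tile predictions back into montage coordinates.

    Pixels covered by no tile are marked invalid.
    """
    h, w = shape
    acc = np.zeros((h, w), dtype=float)
    cnt = np.zeros((h, w), dtype=float)
    for p in predictions:
        r, c = p.offset
        ph, pw = p.crop.shape
        if r < 0 or c < 0 or r + ph > h or c + pw > w:
            if predictions.padded and r == 0 and c == 0:
                acc[:h, :w] += p.crop[:h, :w]
                cnt[:h, :w] += 1
                continue
            raise ValueError(f"tile at offset {(r, c)} falls outside shape {shape}")
        acc[r:r + ph, c:c + pw] += p.crop
        cnt[r:r + ph, c:c + pw] += 1
    covered = cnt > 0
    out = np.zeros((h, w), dtype=float)
    out[covered] = acc[covered] / cnt[covered]
    return ScalarMap(out, valid=covered)
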