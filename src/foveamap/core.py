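"""Shared containers used across the detection / evaluation / topography pipeline.

Coordinate convention (used everywhere in this package): 0-based, ``x`` is the
column index, ``y`` the row index, pixel centers at integer coordinates.
Sub-pixel positions are allowed and expected after peak refinement.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np


@dataclass
class ConeSet:
    """Ordered collection of sub-pixel cone-center coordinates.

    Parameters
    ----------
    xy:
        ``(n, 2)`` float array of ``(x, y)`` positions in pixel units.
    scale_px_per_deg:
        Digital image scale. ``None`` when unknown; topography operations that
        report angular units require it.
    """

    xy: np.ndarray
    scale_px_per_deg: float | None = None

    def __post_init__(self) -> None:
        self.xy = np.asarray(self.xy, dtype=float).reshape(-1, 2)

    def __len__(self) -> int:
        return self.xy.shape[0]

    @property
    def x(self) -> np.ndarray:
        return self.xy[:, 0]

    @property
    def y(self) -> np.ndarray:
        return self.xy[:, 1]

    def min_pairwise_distance(self) -> float:
        """Smallest Euclidean distance between any two cones (exact)."""
        from scipy.spatial import cKDTree

        if len(self) < 2:
            raise ValueError("need at least two cones for a pairwise distance")
        d, _ = cKDTree(self.xy).query(self.xy, k=2)
        return float(d[:, 1].min())


@dataclass
class ScalarMap:
    """A 2D float field registered to image pixel coordinates.

    ``valid`` marks pixels carrying meaningful values (e.g. pixels covered by
    at least one inference tile, or density-map probes with enough bounded
    Voronoi cells).
    """

    data: np.ndarray
    valid: np.ndarray = field(default=None)  # type: ignore[assignment]

    def __post_init__(self) -> None:
        self.data = np.asarray(self.data, dtype=float)
        if self.valid is None:
            self.valid = np.ones(self.data.shape, dtype=bool)
        else:
            self.valid = np.asarray(self.valid, dtype=bool)
        if self.valid.shape != self.data.shape:
            raise ValueError("valid mask shape must match data shape")

    @property
    def shape(self) -> tuple[int, int]:
        return self.data.shape  # type: ignore[return-value]


@dataclass
class ValidityMask:
    """Boolean per-pixel usability mask (True = usable)."""

    mask: np.ndarray

    def __post_init__(self) -> None:
        self.mask = np.asarray(self.mask, dtype=bool)

    @property
    def shape(self) -> tuple[int, int]:
        return self.mask.shape  # type: ignore[return-value]


def bilinear_sample(grid: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Bilinear interpolation of ``grid`` at sub-pixel ``(x, y)`` positions.

    Positions are clamped to the grid domain, so samples at the border are
    well defined.
    """
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    x = np.clip(np.asarray(xy, dtype=float).reshape(-1, 2)[:, 0], 0.0, w - 1.0)
    y = np.clip(np.asarray(xy, dtype=float).reshape(-1, 2)[:, 1], 0.0, h - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2) if w > 1 else np.zeros_like(x, int)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2) if h > 1 else np.zeros_like(y, int)
    fx, fy = x - x0, y - y0
    g00 = grid[y0, x0]
    g01 = grid[y0, np.minimum(x0 + 1, w - 1)]
    g10 = grid[np.minimum(y0 + 1, h - 1), x0]
    g11 = grid[np.minimum(y0 + 1, h - 1), np.minimum(x0 + 1, w - 1)]
    return (g00 * (1 - fx) * (1 - fy) + g01 * fx * (1 - fy)
            + g10 * (1 - fx) * fy + g11 * fx * fy)


def bilinear_gradient(grid: np.ndarray, xy: np.ndarray) -> np.ndarray:
    """Gradient (d/dx, d/dy) of the bilinear interpolant at ``(x, y)``."""
    grid = np.asarray(grid, dtype=float)
    h, w = grid.shape
    pts = np.asarray(xy, dtype=float).reshape(-1, 2)
    x = np.clip(pts[:, 0], 0.0, w - 1.0)
    y = np.clip(pts[:, 1], 0.0, h - 1.0)
    x0 = np.clip(np.floor(x).astype(int), 0, w - 2) if w > 1 else np.zeros_like(x, int)
    y0 = np.clip(np.floor(y).astype(int), 0, h - 2) if h > 1 else np.zeros_like(y, int)
    fx, fy = x - x0, y - y0
    x1 = np.minimum(x0 + 1, w - 1)
    y1 = np.minimum(y0 + 1, h - 1)
    g00, g01, g10, g11 = grid[y0, x0], grid[y0, x1], grid[y1, x0], grid[y1, x1]
    dx = (g01 - g00) * (1 - fy) + (g11 - g10) * fy
    dy = (g10 - g00) * (1 - fx) + (g11 - g01) * fx
    return np.stack([dx, dy], axis=1)
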