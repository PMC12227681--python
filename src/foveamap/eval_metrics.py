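"""Point-matching validation protocol for automatic cone detection.

Predicted cones are matched one-to-one to ground truth (GT): a prediction is
a true positive if it lies within a distance d of an unmatched GT cone, where
d defaults to 0.35 of the minimal pairwise GT distance across all evaluated
images. When several predictions fall within d of one GT cone, only the
nearest is a TP and the rest are FP. Predictions outside the boundary formed
by the GT set (its convex hull) are excluded before matching. From the
partition, TPR = TP/(TP+FN), FDR = FP/(TP+FP) and F1 = 2TP/(2TP+FP+FN); the
Chamfer distance is the mean over GT cones of the distance to the nearest
prediction; the correction-time model converts FP+FN into expert re-labelling
minutes at 3 seconds per fix.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.spatial import Delaunay, QhullError, cKDTree

from .core import ConeSet

__all__ = [
    "MatchConfig", "MatchResult", "matching_threshold", "boundary_filter",
    "match_cones", "scores", "chamfer", "correction_time",
]

SECONDS_PER_FIX = 3.0  # expert time to add a missed cone or remove a false one


@dataclass
class MatchConfig:
    d_fraction: float = 0.35
    d_px: float | str = "auto"   # auto => d_fraction * min pairwise GT distance
    boundary_rule: str = "convex_hull"  # or "none"

    def validate(self) -> None:
        if self.d_px == "auto" and not (0.0 < self.d_fraction < 1.0):
            raise ValueError("d_fraction must be in (0, 1) when d_px is 'auto'")
        if self.boundary_rule not in ("convex_hull", "none"):
            raise ValueError("boundary_rule must be 'convex_hull' or 'none'")


@dataclass
class MatchResult:
    tp_pairs: list[tuple[int, int, float]]  # (pred index, gt index, distance px)
    fp: list[int] = field(default_factory=list)
    fn: list[int] = field(default_factory=list)
    d_used: float = float("nan")

    @property
    def tp(self) -> int:
        return len(self.tp_pairs)

    @property
    def n_fp(self) -> int:
        return len(self.fp)

    @property
    def n_fn(self) -> int:
        return len(self.fn)


def matching_threshold(gt_sets: list[ConeSet], d_fraction: float = 0.35) -> float:
    """d = d_fraction x (minimal pairwise distance over all GT sets)."""
    if not gt_sets:
        raise ValueError("need at least one ground-truth set")
    minima = []
    for s in gt_sets:
        if len(s) < 2:
            raise ValueError("every ground-truth set needs at least two cones")
        minima.append(s.min_pairwise_distance())
    return d_fraction * min(minima)


def boundary_filter(pred: ConeSet, gt: ConeSet,
                    rule: str = "convex_hull") -> tuple[ConeSet, np.ndarray]:
    """Drop predictions outside the convex hull of the GT set.

    Returns the filtered set together with the indices (into ``pred``) that
    were kept, so match partitions can refer back to original indices.
    """
    if rule == "none":
        return pred, np.arange(len(pred))
    if len(gt) < 3:
        raise ValueError("convex-hull boundary needs >= 3 GT cones; use rule='none'")
    try:
        hull = Delaunay(gt.xy)
    except QhullError as err:
        raise ValueError(
            "GT points are degenerate (collinear?); use boundary rule 'none'"
        ) from err
    inside = hull.find_simplex(pred.xy) >= 0
    keep = np.flatnonzero(inside)
    return ConeSet(pred.xy[keep], scale_px_per_deg=pred.scale_px_per_deg), keep


def match_cones(pred: ConeSet, gt: ConeSet,
                cfg: MatchConfig | None = None) -> MatchResult:
    """Greedy one-to-one matching by ascending pair distance.

    All (prediction, GT) pairs closer than d are sorted by distance (ties
    broken lexicographically by indices) and accepted greedily when both
    endpoints are still unmatched — this realizes the nearest-wins duplicate
    rule deterministically. Unmatched predictions become FP, unmatched GT
    cones FN. The boundary filter runs first; FP indices refer to the
    original prediction order.
    """
    cfg = cfg or MatchConfig()
    cfg.validate()
    if len(pred) == 0 or len(gt) == 0:
        raise ValueError("both cone sets must be non-empty")
    d = (matching_threshold([gt], cfg.d_fraction)
         if cfg.d_px == "auto" else float(cfg.d_px))

    pred_f, kept = boundary_filter(pred, gt, cfg.boundary_rule)

    pairs: list[tuple[float, int, int]] = []
    if len(pred_f) > 0:
        tree = cKDTree(gt.xy)
        neighbor_lists = tree.query_ball_point(pred_f.xy, r=d)
        for pi, gl in enumerate(neighbor_lists):
            for gi in gl:
                dist = float(np.hypot(*(pred_f.xy[pi] - gt.xy[gi])))
                pairs.append((dist, pi, gi))
    pairs.sort(key=lambda t: (t[0], t[1], t[2]))

    pred_matched = np.zeros(len(pred_f), dtype=bool)
    gt_matched = np.zeros(len(gt), dtype=bool)
    tp_pairs: list[tuple[int, int, float]] = []
    for dist, pi, gi in pairs:
        if not pred_matched[pi] and not gt_matched[gi]:
            pred_matched[pi] = gt_matched[gi] = True
            tp_pairs.append((int(kept[pi]), gi, dist))
    fp = [int(kept[pi]) for pi in np.flatnonzero(~pred_matched)]
    fn = [int(gi) for gi in np.flatnonzero(~gt_matched)]
    return MatchResult(tp_pairs=tp_pairs, fp=fp, fn=fn, d_used=d)


def scores(m: MatchResult) -> tuple[float, float, float]:
    """(TPR, FDR, F1) = (TP/(TP+FN), FP/(TP+FP), 2TP/(2TP+FP+FN))."""
    tp, fp, fn = m.tp, m.n_fp, m.n_fn
    if tp + fn == 0:
        raise ValueError("TPR undefined: no ground-truth cones in the boundary")
    if tp + fp == 0:
        raise ValueError("FDR undefined: no predictions in the boundary")
    return (tp / (tp + fn), fp / (tp + fp), 2 * tp / (2 * tp + fp + fn))


def chamfer(gt: ConeSet, pred: ConeSet) -> float:
    """Mean over GT cones of the distance to the nearest prediction (px).

    One-directional (GT -> predictions), as defined.
    """
    if len(gt) == 0 or len(pred) == 0:
        raise ValueError("both cone sets must be non-empty")
    d, _ = cKDTree(pred.xy).query(gt.xy)
    return float(d.mean())


def correction_time(m: MatchResult,
                    seconds_per_fix: float = SECONDS_PER_FIX) -> float:
    """Estimated expert re-labelling time in minutes: (FP + FN) x 3 s / 60."""
    return (m.n_fp + m.n_fn) * seconds_per_fix / 60.0
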