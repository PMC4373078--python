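"""Descriptive native/invasive overlap in morphospace.

Quantifies, per group of specimens, the occupied region of the 3-D
ordination (axis-aligned bounding box, convex-hull volume, mean distance to
the group centroid) and, per group pair, the fraction of the smaller hull's
volume shared with the other hull (Monte Carlo estimate).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError

log = logging.getLogger(__name__)


@dataclass
class GroupSummary:
    n: int
    bbox_min: list[float]
    bbox_max: list[float]
    hull_volume: float | None  # None when the hull is degenerate or n < 4
    disparity: float           # mean distance to group centroid


@dataclass
class OverlapReport:
    groups: dict[str, GroupSummary]
    overlap_fraction: dict[tuple[str, str], float | None]
    n_mc_points: int
    seed: int

    def to_jsonable(self) -> dict:
        return {
            "groups": {g: vars(s) for g, s in self.groups.items()},
            "overlap_fraction": {f"{a}|{b}": v
                                 for (a, b), v in self.overlap_fraction.items()},
            "n_mc_points": self.n_mc_points,
            "seed": self.seed,
        }


def _hull(points: np.ndarray) -> ConvexHull | None:
    if points.shape[0] < points.shape[1] + 1:
        return None
    try:
        return ConvexHull(points)
    except QhullError:
        return None


def _sample_in_hull(hull: ConvexHull, n: int, rng: np.random.Generator,
                    ) -> np.ndarray:
    lo = hull.points.min(axis=0)
    hi = hull.points.max(axis=0)
    out = []
    need = n
    a, b = hull.equations[:, :-1], hull.equations[:, -1]
    while need > 0:
        cand = rng.uniform(lo, hi, size=(max(4 * need, 1000), hull.points.shape[1]))
        inside = np.all(cand @ a.T + b <= 1e-12, axis=1)
        got = cand[inside]
        out.append(got[:need])
        need -= len(got[:need])
    return np.vstack(out)


def _contains(hull: ConvexHull, pts: np.ndarray) -> np.ndarray:
    a, b = hull.equations[:, :-1], hull.equations[:, -1]
    return np.all(pts @ a.T + b <= 1e-9, axis=1)


def group_overlap(coordinates: pd.DataFrame,
                  groups: Mapping[str, str],
                  n_mc_points: int = 20000,
                  seed: int = 0) -> OverlapReport:
    """Bounding boxes, hull volumes, disparities, and pairwise hull overlap.

    overlap_fraction[(a, b)] = vol(hull_a intersect hull_b) / min(vol_a, vol_b),
    estimated by uniform Monte Carlo sampling inside each hull.  Groups with
    fewer than 4 members (or a degenerate hull) are summarized without a hull
    and skipped in the pairwise overlaps.
    """
    labels = list(coordinates.index)
    missing = [l for l in labels if l not in groups]
    if missing:
        raise ValueError(f"no group for specimen(s): {missing[:5]}")
    by_group: dict[str, np.ndarray] = {}
    for g in sorted(set(groups[l] for l in labels)):
        pts = coordinates.loc[[l for l in labels if groups[l] == g]].to_numpy(float)
        by_group[g] = pts

    rng = np.random.default_rng(seed)
    summaries: dict[str, GroupSummary] = {}
    hulls: dict[str, ConvexHull | None] = {}
    for g, pts in by_group.items():
        centroid = pts.mean(axis=0)
        disparity = float(np.linalg.norm(pts - centroid, axis=1).mean())
        hull = _hull(pts) if len(pts) >= 4 else None
        if len(pts) < 4:
            log.warning("group %r has %d < 4 points; hull skipped", g, len(pts))
        hulls[g] = hull
        summaries[g] = GroupSummary(
            n=len(pts),
            bbox_min=pts.min(axis=0).tolist(),
            bbox_max=pts.max(axis=0).tolist(),
            hull_volume=float(hull.volume) if hull is not None else None,
            disparity=disparity,
        )

    names = sorted(by_group)
    overlaps: dict[tuple[str, str], float | None] = {}
    for i, a in enumerate(names):
        for b in names[i:]:
            ha, hb = hulls[a], hulls[b]
            if ha is None or hb is None:
                overlaps[(a, b)] = None
                continue
            pa = _sample_in_hull(ha, n_mc_points, rng)
            pb = _sample_in_hull(hb, n_mc_points, rng)
            inter_in_a = _contains(hb, pa).mean() * ha.volume  # vol(A∩B) via A
            inter_in_b = _contains(ha, pb).mean() * hb.volume
            inter = 0.5 * (inter_in_a + inter_in_b)
            overlaps[(a, b)] = float(inter / min(ha.volume, hb.volume))
    return OverlapReport(groups=summaries, overlap_fraction=overlaps,
                         n_mc_points=n_mc_points, seed=seed)
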