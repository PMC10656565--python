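"""Consolidate per-flight plant detections and index them to the sowing grid.

An object detector run independently on each flight date produces one
rectangle per visible plant per date. Boxes belonging to the same plant are
grouped by pairwise overlap and replaced by their envelope, then each merged
box is matched to the nearest point of the sowing grid, subject to the
within-row plant spacing as a distance cut.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import List, Optional, Sequence, Tuple

import numpy as np
from shapely import box as shapely_box
from shapely.strtree import STRtree

from .geo import BoundingBox, GeoTransform

__all__ = [
    "GridPoint",
    "PlantAssignment",
    "pixel_box_to_projected",
    "projected_box_to_pixel",
    "merge_detections",
    "build_grid",
    "assign_boxes_to_grid",
    "detection_accuracy",
]


@dataclass(frozen=True)
class GridPoint:
    """One sowing position: a unique plant index and its projected center."""

    plant_id: int
    x: float
    y: float


@dataclass(frozen=True)
class PlantAssignment:
    """Result of matching one grid point against the merged detections.

    ``box`` and ``spd_m`` (the Euclidean point-to-box-center distance) are
    ``None`` when no detection fell within the distance cut.
    """

    plant_id: int
    box: Optional[BoundingBox]
    spd_m: Optional[float]


def pixel_box_to_projected(
    box_px: Sequence[float], gt: GeoTransform, source_tp=None
) -> BoundingBox:
    """Transform a pixel-space rectangle to projected coordinates.

    ``box_px`` is (col0, row0, col1, row1), 0-based, half-open. The y
    interval is reordered so that ymin < ymax in projected space.
    """
    c0, r0, c1, r1 = box_px
    if not (c0 < c1 and r0 < r1):
        raise ValueError(f"degenerate pixel rectangle: {box_px}")
    x0, y0 = gt.pixel_to_xy(r0, c0)
    x1, y1 = gt.pixel_to_xy(r1, c1)
    return BoundingBox(
        xmin=float(min(x0, x1)),
        ymin=float(min(y0, y1)),
        xmax=float(max(x0, x1)),
        ymax=float(max(y0, y1)),
        source_tp=source_tp,
    )


def projected_box_to_pixel(box: BoundingBox, gt: GeoTransform) -> Tuple[float, float, float, float]:
    """Inverse of :func:`pixel_box_to_projected`: (col0, row0, col1, row1)."""
    r0, c0 = gt.xy_to_pixel(box.xmin, box.ymax)
    r1, c1 = gt.xy_to_pixel(box.xmax, box.ymin)
    return float(c0), float(r0), float(c1), float(r1)


def _overlap_ratio(a: BoundingBox, b: BoundingBox) -> float:
    inter = a.intersection_area(b)
    if inter <= 0:
        return 0.0
    return inter / min(a.area, b.area)


class _DisjointSet:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, i: int) -> int:
        while self.parent[i] != i:
            self.parent[i] = self.parent[self.parent[i]]
            i = self.parent[i]
        return i

    def union(self, i: int, j: int) -> None:
        ri, rj = self.find(i), self.find(j)
        if ri != rj:
            self.parent[rj] = ri


def merge_detections(
    boxes: Sequence[BoundingBox], overlap_threshold: float = 0.40
) -> List[BoundingBox]:
    """Group overlapping detections across flights and merge each group.

    Two boxes are related when their intersection area exceeds
    ``overlap_threshold`` of the *smaller* box's area (scale-robust when
    early-season boxes are much smaller than late-season ones). Groups are
    the connected components (transitive closure) of that relation; each
    group is replaced by its coordinate-wise envelope. Boxes overlapping
    nothing pass through unchanged. Output order follows the first member
    of each group in the input; the result is independent of input order
    as a *set*.
    """
    boxes = list(boxes)
    if not boxes:
        return []
    geoms = [shapely_box(b.xmin, b.ymin, b.xmax, b.ymax) for b in boxes]
    tree = STRtree(geoms)
    dsu = _DisjointSet(len(boxes))
    for i, g in enumerate(geoms):
        for j in tree.query(g, predicate="intersects"):
            j = int(j)
            if j <= i:
                continue
            if _overlap_ratio(boxes[i], boxes[j]) > overlap_threshold:
                dsu.union(i, j)

    groups: dict = {}
    for i in range(len(boxes)):
        groups.setdefault(dsu.find(i), []).append(i)

    merged: List[BoundingBox] = []
    for root in sorted(groups, key=lambda r: min(groups[r])):
        members = groups[root]
        if len(members) == 1:
            merged.append(boxes[members[0]])
            continue
        merged.append(
            BoundingBox(
                xmin=min(boxes[i].xmin for i in members),
                ymin=min(boxes[i].ymin for i in members),
                xmax=max(boxes[i].xmax for i in members),
                ymax=max(boxes[i].ymax for i in members),
                source_tp="merged",
            )
        )
    return merged


def build_grid(
    origin: Tuple[float, float],
    n_rows: int,
    n_cols: int,
    plant_spacing_m: float = 0.45,
    row_spacing_m: float = 0.65,
) -> List[GridPoint]:
    """Sowing grid: plants ``plant_spacing_m`` apart along x within a row,
    rows ``row_spacing_m`` apart along y. Ids are row-major from the origin."""
    if n_rows < 1 or n_cols < 1:
        raise ValueError("grid counts must be >= 1")
    ox, oy = origin
    points = []
    for r in range(n_rows):
        for c in range(n_cols):
            points.append(
                GridPoint(
                    plant_id=r * n_cols + c,
                    x=ox + c * plant_spacing_m,
                    y=oy + r * row_spacing_m,
                )
            )
    return points


def spatial_point_distance(point: GridPoint, box: BoundingBox) -> float:
    """Euclidean distance between a grid point and a box center (SPd)."""
    bx, by = box.center
    return float(np.hypot(point.x - bx, point.y - by))


def assign_boxes_to_grid(
    points: Sequence[GridPoint],
    boxes: Sequence[BoundingBox],
    max_dist_m: float = 0.45,
) -> List[PlantAssignment]:
    """Index each merged box to its sowing-grid point.

    Each point proposes its nearest box center within ``max_dist_m``. A box
    may be claimed by at most one point: when several points propose the same
    box, the globally nearest point wins and the losers are left unassigned
    (they are not re-matched to their second choice).
    """
    if not points:
        return []
    if not boxes:
        return [PlantAssignment(p.plant_id, None, None) for p in points]

    centers = np.array([b.center for b in boxes])
    pxy = np.array([[p.x, p.y] for p in points])
    dists = np.hypot(
        pxy[:, 0:1] - centers[None, :, 0], pxy[:, 1:2] - centers[None, :, 1]
    )
    nearest = np.argmin(dists, axis=1)
    nearest_d = dists[np.arange(len(points)), nearest]

    proposal: dict = {}
    for pi, (bi, d) in enumerate(zip(nearest, nearest_d)):
        if d < max_dist_m:
            proposal.setdefault(int(bi), []).append((float(d), pi))

    winner_of_box = {
        bi: min(cands)[1] for bi, cands in proposal.items()
    }
    assigned = {pi: (bi, dists[pi, bi]) for bi, pi in winner_of_box.items()}

    result = []
    for pi, p in enumerate(points):
        if pi in assigned:
            bi, d = assigned[pi]
            result.append(PlantAssignment(p.plant_id, boxes[int(bi)], float(d)))
        else:
            result.append(PlantAssignment(p.plant_id, None, None))
    return result


def detection_accuracy(
    assignments: Sequence[PlantAssignment], n_total_plants: int
) -> float:
    """Overall detection accuracy: assigned plants / total plants sown."""
    if n_total_plants <= 0:
        raise ValueError("n_total_plants must be positive")
    n_assigned = sum(1 for a in assignments if a.box is not None)
    if n_total_plants < n_assigned:
        raise ValueError("n_total_plants smaller than the number assigned")
    return n_assigned / n_total_plants
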