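"""Individual tree crown (ITC) delineation from a smoothed CHM.

The approach seeds crowns at local height maxima found with a circular
moving window, grows a region around each seed by repeatedly admitting
4-neighbour pixels whose height deficit relative to the seed apex is below
both a fractional and an absolute threshold, extracts the first-return
points of each region (after removing low points), and takes the 2-D convex
hull of those points as the final crown polygon.  Crown height is the 99th
percentile of the first returns inside the region (linear interpolation
between order statistics).

Regions grow in parallel rounds; a pixel claimable by two regions in the
same round goes to the seed with the greater apex (ties to the smaller seed
id), which makes the output deterministic and independent of seed order.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from shapely.geometry import MultiPoint, Polygon

from .chm import ChmParams, rasterize_chm, smooth_chm
from .io_formats import PointCloud, RasterGrid

logger = logging.getLogger(__name__)


@dataclass
class DelineationParams:
    """User-set delineation thresholds.

    window_diameter
        Diameter (m) of the circular local-maxima window.
    min_tree_height
        Small-tree cut-off (m); pixels at or below it cannot seed a crown.
    frac_threshold
        Maximum height deficit as a fraction of the seed apex height.
    abs_threshold
        Maximum absolute height deficit (m).
    low_point_cutoff
        Points at or below this height (m) are removed before hulling.

    Defaults are plausible settings for an Alpine conifer stand; all are
    exposed in configuration.
    """

    window_diameter: float = 2.5
    min_tree_height: float = 2.0
    frac_threshold: float = 0.45
    abs_threshold: float = 6.0
    low_point_cutoff: float = 2.0

    def __post_init__(self) -> None:
        for name in ("window_diameter", "min_tree_height", "frac_threshold",
                     "abs_threshold", "low_point_cutoff"):
            if getattr(self, name) <= 0:
                raise ValueError(f"{name} must be strictly positive")
        if not 0 < self.frac_threshold < 1:
            raise ValueError("frac_threshold must be in (0, 1)")


@dataclass
class TreeTop:
    """A local CHM maximum designated as a tree apex."""

    row: int
    col: int
    x: float
    y: float
    apex_height: float


@dataclass
class ITC:
    """A delineated individual tree crown."""

    id: int
    seed: TreeTop
    polygon: Polygon
    crown_area: float
    height: float
    species: str | None = None
    dbh_cm: float | None = None
    agb_kg: float | None = None
    carbon_kg: float | None = None
    point_indices: np.ndarray = field(default=None, repr=False)  # type: ignore[assignment]


def _window_offsets(chm: RasterGrid, params: DelineationParams) -> list[tuple[int, int]]:
    radius = params.window_diameter / 2.0
    r_px = int(np.floor(radius / chm.resolution))
    if 2 * r_px + 1 < 3:
        raise ValueError(
            f"window_diameter {params.window_diameter} m spans fewer than 3 pixels "
            f"at {chm.resolution} m resolution")
    offs = []
    for dr in range(-r_px, r_px + 1):
        for dc in range(-r_px, r_px + 1):
            if dr == 0 and dc == 0:
                continue
            if (dr * chm.resolution) ** 2 + (dc * chm.resolution) ** 2 <= radius ** 2:
                offs.append((dr, dc))
    return offs


def find_local_maxima(chm: RasterGrid, params: DelineationParams) -> list[TreeTop]:
    """Locate tree tops with a circular moving window.

    A pixel is a tree top iff no pixel in its window is strictly higher,
    at least one is strictly lower (flat plateaus spanning the whole window
    are not seeded), any equal-height pixel in the window follows it in
    (row, col) lexicographic order, and its height exceeds the small-tree
    cut-off.
    """
    offs = _window_offsets(chm, params)
    v = chm.values
    n_rows, n_cols = v.shape
    tops: list[TreeTop] = []
    for r in range(n_rows):
        for c in range(n_cols):
            h = v[r, c]
            if h <= params.min_tree_height:
                continue
            ok = True
            any_lower = False
            for dr, dc in offs:
                rr, cc = r + dr, c + dc
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                other = v[rr, cc]
                if other > h:
                    ok = False
                    break
                if other == h and (rr, cc) < (r, c):
                    ok = False
                    break
                if other < h:
                    any_lower = True
            if ok and any_lower:
                x, y = chm.pixel_center(r, c)
                tops.append(TreeTop(r, c, float(x), float(y), float(h)))
    return tops


def grow_crowns(chm: RasterGrid, seeds: list[TreeTop],
                params: DelineationParams) -> RasterGrid:
    """Grow crown regions around the seeds; returns an integer label map.

    Pixel p joins seed s's region when it is 4-connected to s through pixels
    whose height deficit relative to s's apex is below both thresholds;
    growth proceeds in synchronous rounds until no pixel is added.
    Labels are 1-based in seed order; unclaimed pixels are 0.
    """
    v = chm.values
    n_rows, n_cols = v.shape
    labels = np.zeros((n_rows, n_cols), dtype=int)
    apex = {}
    frontier: list[tuple[int, int]] = []
    for i, s in enumerate(seeds, start=1):
        if s.apex_height < params.min_tree_height:
            logger.warning("seed %d below min_tree_height; skipped", i)
            continue
        if labels[s.row, s.col] == 0:
            labels[s.row, s.col] = i
            apex[i] = s.apex_height
            frontier.append((s.row, s.col))

    def admissible(lab: int, r: int, c: int) -> bool:
        gap = apex[lab] - v[r, c]
        return gap < params.frac_threshold * apex[lab] and gap < params.abs_threshold

    while frontier:
        claims: dict[tuple[int, int], int] = {}
        for r, c in frontier:
            lab = labels[r, c]
            for rr, cc in ((r - 1, c), (r + 1, c), (r, c - 1), (r, c + 1)):
                if not (0 <= rr < n_rows and 0 <= cc < n_cols):
                    continue
                if labels[rr, cc] != 0 or not admissible(lab, rr, cc):
                    continue
                prev = claims.get((rr, cc))
                if prev is None:
                    claims[(rr, cc)] = lab
                elif prev != lab:
                    # conflict within one round: greater apex wins, then smaller id
                    if (apex[lab], -lab) > (apex[prev], -prev):
                        claims[(rr, cc)] = lab
        frontier = []
        for (rr, cc), lab in claims.items():
            labels[rr, cc] = lab
            frontier.append((rr, cc))
    return chm.copy_with(labels.astype(float))


def extract_crown_returns(labels: RasterGrid, cloud: PointCloud,
                          params: DelineationParams) -> dict[int, np.ndarray]:
    """First-return points per region, low points removed.

    Returns a mapping region id -> indices into ``cloud``.  Regions left
    with fewer than 3 points are dropped (cannot be hulled).
    """
    lab = labels.values.astype(int)
    row, col = labels.world_to_pixel(cloud.x, cloud.y)
    inside = (row >= 0) & (row < labels.n_rows) & (col >= 0) & (col < labels.n_cols)
    keep = inside & (cloud.return_number == 1) & (cloud.z > params.low_point_cutoff)
    idx = np.flatnonzero(keep)
    regions: dict[int, list[int]] = {}
    point_labels = lab[row[idx], col[idx]]
    for i, rlab in zip(idx, point_labels):
        if rlab > 0:
            regions.setdefault(int(rlab), []).append(int(i))
    out = {}
    for rid, members in regions.items():
        if len(members) < 3:
            logger.warning("region %d has %d first returns above cutoff; dropped",
                           rid, len(members))
            continue
        out[rid] = np.asarray(members, dtype=int)
    return out


def hull_crowns(regions: dict[int, np.ndarray], cloud: PointCloud,
                seeds_by_id: dict[int, TreeTop]) -> list[ITC]:
    """Convex-hull each region's first returns into final ITC polygons.

    Crown area is the hull polygon area; crown height is the 99th
    percentile of the region's first-return heights.  Degenerate (collinear)
    regions are dropped.
    """
    itcs: list[ITC] = []
    for rid in sorted(regions):
        idx = regions[rid]
        pts = np.column_stack([cloud.x[idx], cloud.y[idx]])
        hull = MultiPoint(pts).convex_hull
        if hull.geom_type != "Polygon" or hull.area <= 0:
            logger.warning("region %d degenerate (collinear points); dropped", rid)
            continue
        height = float(np.percentile(cloud.z[idx], 99))
        itcs.append(ITC(id=rid, seed=seeds_by_id[rid], polygon=hull,
                        crown_area=float(hull.area), height=height,
                        point_indices=idx))
    return itcs


def delineate(cloud: PointCloud, chm_params: ChmParams | None = None,
              delin_params: DelineationParams | None = None) -> list[ITC]:
    """Full delineation: rasterize, smooth, seed, grow, extract, hull."""
    chm_params = chm_params or ChmParams()
    delin_params = delin_params or DelineationParams()
    chm = smooth_chm(rasterize_chm(cloud, chm_params), chm_params)
    seeds = find_local_maxima(chm, delin_params)
    if not seeds:
        return []
    labels = grow_crowns(chm, seeds, delin_params)
    regions = extract_crown_returns(labels, cloud, delin_params)
    seeds_by_id = {i: s for i, s in enumerate(seeds, start=1)}
    return hull_crowns(regions, cloud, seeds_by_id)
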