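"""RI as a function of along-wall geodesic distance from a vessel break.

Distances are geodesic *within* the wall mask (8-connected pixel graph,
unit lateral and √2 diagonal steps), matching the notion of distance along
the vessel wall rather than through space. With multiple break endpoints,
each wall pixel takes the minimum distance over the endpoints reachable in
its own connected component.

The moving window is centered (a convention); the three-region partition is
near (< 50 μm), mid (50–350 μm inclusive at both bounds) and far (> 350 μm).
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import ndimage as ndi
from skimage import morphology
from skimage.graph import MCP_Geometric

REGION_BOUNDS_UM = (50.0, 350.0)
REGION_NAMES = ("near", "mid", "far")

_NEIGHBOR_KERNEL = np.array([[1, 1, 1], [1, 0, 1], [1, 1, 1]])


@dataclass(frozen=True)
class BreakProfile:
    """Per-wall-pixel break-distance profile for one vessel."""

    break_points: list[tuple[int, int]]
    distances: np.ndarray  # μm, per wall pixel (order of np.argwhere(wall))
    ri_values: np.ndarray
    window: float  # μm
    grid: np.ndarray  # μm, distance axis of the moving profile
    moving_mean: np.ndarray
    moving_sd: np.ndarray
    n_samples: np.ndarray
    region_labels: np.ndarray  # strings from REGION_NAMES
    region_bounds: tuple[float, float] = REGION_BOUNDS_UM


def find_break_endpoints(
    wall_mask: np.ndarray, exclude_border: int = 0
) -> list[tuple[int, int]]:
    """Break endpoints: degree-1 nodes of the wall band's skeleton.

    A closed annulus has a cyclic skeleton and returns an empty list. Each
    endpoint is refined by marching outward along the local skeleton
    direction to the band's cut face, so the returned coordinate sits at
    the break itself rather than half a band-width inside it.

    ``exclude_border`` drops endpoints within that many pixels of the image
    edge — walls truncated by the field of view are not breaks (the
    pipeline uses 2; the default keeps the raw contract).
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if not wall_mask.any():
        raise ValueError("wall mask is empty")
    skel = morphology.skeletonize(wall_mask)
    degrees = ndi.convolve(skel.astype(np.uint8), _NEIGHBOR_KERNEL, mode="constant")
    tips = np.argwhere(skel & (degrees == 1))
    halfwidth = float(ndi.distance_transform_edt(wall_mask).max())
    endpoints: list[tuple[int, int]] = []
    skel_pts = np.argwhere(skel).astype(np.float64)
    for tip in tips:
        d = np.hypot(skel_pts[:, 0] - tip[0], skel_pts[:, 1] - tip[1])
        near = skel_pts[(d > 0) & (d <= 5.0)]
        if len(near) == 0:
            endpoints.append((int(tip[0]), int(tip[1])))
            continue
        direction = tip - near.mean(axis=0)
        norm = np.hypot(*direction)
        if norm == 0:
            endpoints.append((int(tip[0]), int(tip[1])))
            continue
        direction /= norm
        p = tip.astype(np.float64)
        last = (int(tip[0]), int(tip[1]))
        for _ in range(4 * max(wall_mask.shape)):
            p = p + 0.5 * direction
            yi, xi = int(round(p[0])), int(round(p[1]))
            if not (
                0 <= yi < wall_mask.shape[0]
                and 0 <= xi < wall_mask.shape[1]
                and wall_mask[yi, xi]
            ):
                break
            last = (yi, xi)
        endpoints.append(last)
    # skeletonization forks at a cut face, yielding one tip per face corner;
    # after refinement those land on the same face — merge endpoints closer
    # than one band width into their (mask-snapped) centroid
    merge_radius = 2.0 * halfwidth + 1.0
    merged: list[tuple[int, int]] = []
    used = [False] * len(endpoints)
    for i, ep in enumerate(endpoints):
        if used[i]:
            continue
        cluster = [ep]
        used[i] = True
        for j in range(i + 1, len(endpoints)):
            if not used[j] and np.hypot(
                endpoints[j][0] - ep[0], endpoints[j][1] - ep[1]
            ) <= merge_radius:
                cluster.append(endpoints[j])
                used[j] = True
        cy, cx = np.mean(cluster, axis=0)
        wall_pts = np.argwhere(wall_mask)
        snap = wall_pts[
            int(np.argmin(np.hypot(wall_pts[:, 0] - cy, wall_pts[:, 1] - cx)))
        ]
        merged.append((int(snap[0]), int(snap[1])))
    endpoints = merged
    if exclude_border > 0:
        ny, nx = wall_mask.shape
        endpoints = [
            (y, x)
            for y, x in endpoints
            if exclude_border <= y < ny - exclude_border
            and exclude_border <= x < nx - exclude_border
        ]
    return endpoints


def wall_distance_from_break(
    wall_mask: np.ndarray,
    break_point: tuple[int, int],
    pixel_size: float,
) -> np.ndarray:
    """Geodesic distance (μm) from the break point to every wall pixel.

    Computed on the 8-connected in-mask pixel graph with unit/√2 step
    weights; unreachable pixels (other connected components) get ``inf``.
    Shape matches ``wall_mask``; off-mask pixels are ``inf``. A break point
    off the mask is snapped to the nearest wall pixel within 2 px.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    by, bx = break_point
    if not (0 <= by < wall_mask.shape[0] and 0 <= bx < wall_mask.shape[1]):
        raise ValueError("break point outside the image")
    if not wall_mask[by, bx]:
        pts = np.argwhere(wall_mask)
        d = np.hypot(pts[:, 0] - by, pts[:, 1] - bx)
        if d.min() > 2.0:
            raise ValueError("break point is not on or adjacent to the wall mask")
        by, bx = pts[int(np.argmin(d))]
    costs = np.where(wall_mask, 1.0, np.inf)
    mcp = MCP_Geometric(costs, fully_connected=True)
    cumulative, _ = mcp.find_costs([(by, bx)])
    dist = np.where(wall_mask, cumulative, np.inf)
    # MCP accumulates (cost_a + cost_b)/2 per step times step length; with
    # unit costs that is exactly 1 or sqrt(2) per move.
    if not np.isfinite(dist[wall_mask]).any():
        raise ValueError("break point disconnected from the wall mask")
    return dist * pixel_size


def moving_profile(
    distances: np.ndarray,
    ri_values: np.ndarray,
    window: float = 20.0,
    grid_step: Optional[float] = None,
    min_samples: int = 3,
) -> tuple[np.ndarray, np.ndarray, np.ndarray, np.ndarray]:
    """Centered moving mean/SD of RI over along-wall distance.

    At each grid distance ``d`` the window collects samples with distance
    in ``[d − window/2, d + window/2]``; windows with fewer than
    ``min_samples`` samples yield NaN (flagged, not an error). Returns
    ``(grid, moving_mean, moving_sd, n_samples)``.
    """
    distances = np.asarray(distances, dtype=np.float64).ravel()
    ri_values = np.asarray(ri_values, dtype=np.float64).ravel()
    if distances.size == 0:
        raise ValueError("need at least one sample")
    if window <= 0:
        raise ValueError("window must be > 0")
    finite = np.isfinite(distances)
    distances, ri_values = distances[finite], ri_values[finite]
    if grid_step is None:
        grid_step = window / 10.0
    grid = np.arange(0.0, distances.max() + grid_step, grid_step)
    order = np.argsort(distances)
    d_sorted = distances[order]
    r_sorted = ri_values[order]
    half = window / 2.0
    lo = np.searchsorted(d_sorted, grid - half, side="left")
    hi = np.searchsorted(d_sorted, grid + half, side="right")
    mean = np.full(grid.shape, np.nan)
    sd = np.full(grid.shape, np.nan)
    n = (hi - lo).astype(int)
    for i, (a, b) in enumerate(zip(lo, hi)):
        if b - a >= min_samples:
            w = r_sorted[a:b]
            if w[0] == w[-1] and np.all(w == w[0]):
                mean[i], sd[i] = w[0], 0.0  # exact for constant windows
            else:
                mean[i] = w.mean()
                sd[i] = w.std(ddof=1)
    return grid, mean, sd, n


def classify_regions(
    distances: np.ndarray,
    ri_values: np.ndarray,
    bounds: tuple[float, float] = REGION_BOUNDS_UM,
) -> tuple[np.ndarray, dict[str, dict[str, float]]]:
    """Label each wall pixel near/mid/far and summarize per region.

    near: d < bounds[0]; mid: bounds[0] ≤ d ≤ bounds[1] (boundary values go
    to mid — convention); far: d > bounds[1]. Empty regions produce NaN
    means/SDs and count 0, never an exception.
    """
    distances = np.asarray(distances, dtype=np.float64).ravel()
    ri_values = np.asarray(ri_values, dtype=np.float64).ravel()
    lo, hi = bounds
    labels = np.where(
        distances < lo, "near", np.where(distances <= hi, "mid", "far")
    )
    summaries: dict[str, dict[str, float]] = {}
    for name in REGION_NAMES:
        sel = labels == name
        vals = ri_values[sel]
        summaries[name] = {
            "mean_ri": float(vals.mean()) if vals.size else float("nan"),
            "sd_ri": float(vals.std(ddof=1)) if vals.size > 1 else float("nan"),
            "n_pixels": int(sel.sum()),
        }
    return labels, summaries


def build_break_profile(
    wall_mask: np.ndarray,
    ri_slice: np.ndarray,
    pixel_size: float,
    break_points: Optional[Sequence[tuple[int, int]]] = None,
    window: float = 20.0,
    bounds: tuple[float, float] = REGION_BOUNDS_UM,
    exclude_border: int = 0,
) -> BreakProfile:
    """Full profile for one vessel slice.

    ``break_points=None`` auto-detects skeleton endpoints (manual
    annotations override detection). Each wall pixel takes the minimum
    distance over all endpoints; pixels unreachable from every endpoint
    (disconnected components with no break of their own) are dropped.
    """
    wall_mask = np.asarray(wall_mask, dtype=bool)
    if break_points is None:
        break_points = find_break_endpoints(wall_mask, exclude_border=exclude_border)
    break_points = [tuple(bp) for bp in break_points]
    if not break_points:
        raise ValueError("no break endpoints found (closed wall?)")
    dist_maps = [
        wall_distance_from_break(wall_mask, bp, pixel_size) for bp in break_points
    ]
    dist = np.min(np.stack(dist_maps), axis=0)
    coords = np.argwhere(wall_mask)
    d = dist[wall_mask]
    ri = np.asarray(ri_slice, dtype=np.float64)[wall_mask]
    reachable = np.isfinite(d)
    d, ri = d[reachable], ri[reachable]
    grid, mean, sd, n = moving_profile(d, ri, window=window, grid_step=pixel_size)
    labels, _ = classify_regions(d, ri, bounds=bounds)
    return BreakProfile(
        break_points=break_points,
        distances=d,
        ri_values=ri,
        window=window,
        grid=grid,
        moving_mean=mean,
        moving_sd=sd,
        n_samples=n,
        region_labels=labels,
        region_bounds=bounds,
    )


def profile_to_frame(profile: BreakProfile) -> pd.DataFrame:
    """Moving profile as a tidy table (distance_um, moving_mean, moving_sd, n)."""
    return pd.DataFrame(
        {
            "distance_um": profile.grid,
            "moving_mean": profile.moving_mean,
            "moving_sd": profile.moving_sd,
            "n_samples": profile.n_samples,
        }
    )
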