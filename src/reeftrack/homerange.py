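"""Home-range boundaries, occupancy maps, and range stability.

The home range is delimited by an alpha-shape boundary around the position
fixes, parameterized by a shrink factor in [0, 1]: 0 returns the convex
hull, 1 the tightest single connected region still containing every point,
and intermediate values interpolate the alpha radius between those two
extremes on a log scale. A kernel (utilization-distribution) estimate is
provided for comparison, along with a dwell-time occupancy grid (5 m bins,
Gaussian-smoothed, log10 display layer), an epoch-overlap stability
statistic, and a sleeping-site summary.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.spatial import Delaunay
from shapely.geometry import MultiPolygon, Polygon
from shapely.ops import unary_union
from skimage import measure


@dataclass
class HomeRangePolygon:
    """A home-range boundary with its area and the shrink factor used."""

    geometry: Polygon | MultiPolygon
    area: float
    shrink_factor: float

    @property
    def vertices(self) -> np.ndarray:
        geom = self.geometry
        if isinstance(geom, MultiPolygon):
            geom = max(geom.geoms, key=lambda g: g.area)
        return np.asarray(geom.exterior.coords)

    def iou(self, other: "HomeRangePolygon") -> float:
        union = self.geometry.union(other.geometry).area
        if union == 0:
            return 0.0
        return self.geometry.intersection(other.geometry).area / union

    def __geo_interface__(self):
        return self.geometry.__geo_interface__


class _UnionFind:
    def __init__(self, n: int):
        self.parent = list(range(n))

    def find(self, a: int) -> int:
        while self.parent[a] != a:
            self.parent[a] = self.parent[self.parent[a]]
            a = self.parent[a]
        return a

    def union(self, a: int, b: int) -> None:
        ra, rb = self.find(a), self.find(b)
        if ra != rb:
            self.parent[rb] = ra


def _circumradii(points: np.ndarray, tri: Delaunay) -> np.ndarray:
    a = points[tri.simplices[:, 0]]
    b = points[tri.simplices[:, 1]]
    c = points[tri.simplices[:, 2]]
    la = np.linalg.norm(b - c, axis=1)
    lb = np.linalg.norm(a - c, axis=1)
    lc = np.linalg.norm(a - b, axis=1)
    area2 = np.abs((b[:, 0] - a[:, 0]) * (c[:, 1] - a[:, 1]) - (c[:, 0] - a[:, 0]) * (b[:, 1] - a[:, 1]))
    with np.errstate(divide="ignore", invalid="ignore"):
        r = la * lb * lc / (2.0 * area2)
    r[area2 == 0] = np.inf
    return r


def _alpha_ok(tri: Delaunay, keep: np.ndarray, n_points: int) -> bool:
    """Kept triangles cover all points and form one edge-connected region."""
    kept = np.nonzero(keep)[0]
    if len(kept) == 0:
        return False
    if len(np.unique(tri.simplices[kept])) != n_points:
        return False
    uf = _UnionFind(len(tri.simplices))
    for s in kept:
        for nb in tri.neighbors[s]:
            if nb != -1 and keep[nb]:
                uf.union(s, nb)
    roots = {uf.find(s) for s in kept}
    return len(roots) == 1


def boundary_polygon(points: np.ndarray, shrink_factor: float = 0.5) -> HomeRangePolygon:
    """Alpha-shape boundary around a point set.

    Triangles of the Delaunay triangulation with circumradius above an alpha
    radius are discarded and the rest unioned. The alpha radius runs on a
    log scale from the largest circumradius (keeps everything: the convex
    hull) at shrink 0 down to the smallest radius that still keeps a single
    connected region containing every point at shrink 1.
    """
    if not 0.0 <= shrink_factor <= 1.0:
        raise ValueError("shrink_factor must lie in [0, 1]")
    pts = np.unique(np.asarray(points, dtype=float), axis=0)
    if len(pts) < 3:
        raise ValueError("at least 3 distinct points are required")
    try:
        tri = Delaunay(pts)
    except Exception as exc:  # collinear input
        raise ValueError("points are collinear; no area to bound") from exc
    if len(tri.simplices) == 0:
        raise ValueError("points are collinear; no area to bound")
    radii = _circumradii(pts, tri)
    finite = radii[np.isfinite(radii)]
    r_max = float(finite.max()) if len(finite) else 1.0

    # smallest circumradius threshold keeping one connected, covering region
    cand = np.unique(finite)
    lo, hi = 0, len(cand) - 1
    if _alpha_ok(tri, radii <= cand[lo], len(pts)):
        r_crit = float(cand[lo])
    else:
        while hi - lo > 1:
            mid = (lo + hi) // 2
            if _alpha_ok(tri, radii <= cand[mid], len(pts)):
                hi = mid
            else:
                lo = mid
        r_crit = float(cand[hi])

    if shrink_factor == 0.0 or r_crit >= r_max:
        r_alpha = r_max
    else:
        r_alpha = float(np.exp((1 - shrink_factor) * np.log(r_max) + shrink_factor * np.log(max(r_crit, 1e-12))))
        r_alpha = max(r_alpha, r_crit)
    keep = radii <= r_alpha + 1e-12
    geom = unary_union([Polygon(pts[s]) for s in tri.simplices[keep]])
    if isinstance(geom, Polygon):
        geom = Polygon(geom.exterior)  # drop slivers/holes from fp noise
    return HomeRangePolygon(geometry=geom, area=float(geom.area), shrink_factor=shrink_factor)


def kde_home_range(
    points: np.ndarray,
    bandwidth: float,
    isopleth: float = 0.95,
    cell: float | None = None,
) -> HomeRangePolygon:
    """Kernel utilization-distribution home range.

    A Gaussian kernel of the given bandwidth (m) is evaluated on a grid; the
    returned polygon is the contour enclosing ``isopleth`` of the
    probability mass (the conventional 95% kernel home range).
    """
    if bandwidth <= 0:
        raise ValueError("bandwidth must be > 0")
    pts = np.asarray(points, dtype=float)
    if len(pts) < 10:
        raise ValueError("at least 10 points are required")
    cell = cell or max(bandwidth / 3.0, 0.25)
    pad = 5.0 * bandwidth
    x0, y0 = pts.min(axis=0) - pad
    x1, y1 = pts.max(axis=0) + pad
    nx = int(np.ceil((x1 - x0) / cell)) + 1
    ny = int(np.ceil((y1 - y0) / cell)) + 1
    hist, _, _ = np.histogram2d(
        pts[:, 0], pts[:, 1], bins=(nx, ny), range=((x0, x0 + nx * cell), (y0, y0 + ny * cell))
    )
    dens = gaussian_filter(hist, sigma=bandwidth / cell, mode="constant", truncate=6.0)
    dens /= dens.sum()
    # density level enclosing the requested mass
    flat = np.sort(dens.ravel())[::-1]
    csum = np.cumsum(flat)
    level = flat[int(np.searchsorted(csum, isopleth))]
    polys = []
    for contour in measure.find_contours(dens, level):
        if len(contour) < 3:
            continue
        xy = np.column_stack([x0 + (contour[:, 0] + 0.5) * cell, y0 + (contour[:, 1] + 0.5) * cell])
        p = Polygon(xy)
        if p.is_valid and p.area > 0:
            polys.append(p)
    if not polys:
        raise ValueError("no contour found at the requested isopleth")
    geom = unary_union(polys)
    return HomeRangePolygon(geometry=geom, area=float(geom.area), shrink_factor=np.nan)


@dataclass
class OccupancyGrid:
    """Dwell time per spatial bin, with smoothed and log10 display layers."""

    origin: tuple[float, float]  # lower-left corner of bin (0, 0)
    bin_size: float  # m
    raw: np.ndarray  # minutes per bin, (nx, ny)
    smoothed: np.ndarray
    log10_display: np.ndarray

    @property
    def total_minutes(self) -> float:
        return float(self.raw.sum())


def occupancy_map(
    xy: np.ndarray,
    bin_size: float = 5.0,
    sigma: float = 2.5,
    log_eps: float = 1e-3,
) -> OccupancyGrid:
    """Dwell-time occupancy grid of a 1-min trajectory.

    Each sample deposits one minute in its bin. Smoothing uses a truncated
    Gaussian (sigma in meters) on a grid padded beyond the kernel support,
    renormalized so total dwell time is conserved exactly; the display layer
    is log10(smoothed + eps).
    """
    pts = np.asarray(xy, dtype=float)
    if len(pts) == 0:
        raise ValueError("trajectory is empty")
    sigma_bins = sigma / bin_size
    pad_bins = int(np.ceil(6.0 * sigma_bins)) + 1
    x0 = np.floor(pts[:, 0].min() / bin_size) * bin_size - pad_bins * bin_size
    y0 = np.floor(pts[:, 1].min() / bin_size) * bin_size - pad_bins * bin_size
    nx = int(np.floor((pts[:, 0].max() - x0) / bin_size)) + 1 + pad_bins
    ny = int(np.floor((pts[:, 1].max() - y0) / bin_size)) + 1 + pad_bins
    ix = ((pts[:, 0] - x0) / bin_size).astype(int)
    iy = ((pts[:, 1] - y0) / bin_size).astype(int)
    raw = np.zeros((nx, ny))
    np.add.at(raw, (ix, iy), 1.0)
    smoothed = gaussian_filter(raw, sigma=sigma_bins, mode="constant", truncate=6.0)
    s = smoothed.sum()
    if s > 0:
        smoothed *= raw.sum() / s
    return OccupancyGrid(
        origin=(float(x0), float(y0)),
        bin_size=float(bin_size),
        raw=raw,
        smoothed=smoothed,
        log10_display=np.log10(smoothed + log_eps),
    )


def range_stability(
    day_points: dict[int, np.ndarray],
    first_k: int = 3,
    last_k: int = 3,
    shrink_factor: float = 0.5,
) -> tuple[HomeRangePolygon, HomeRangePolygon, float]:
    """Boundary polygons of the first and last k tracked days and their IoU."""
    days = sorted(day_points)
    if len(days) < first_k + last_k:
        raise ValueError("not enough days for the requested epochs")
    first = np.vstack([day_points[d] for d in days[:first_k]])
    last = np.vstack([day_points[d] for d in days[-last_k:]])
    p1 = boundary_polygon(first, shrink_factor)
    p2 = boundary_polygon(last, shrink_factor)
    return p1, p2, p1.iou(p2)


def sleeping_site_summary(night_xy: np.ndarray, max_iter: int = 200) -> dict:
    """Geometric median of nighttime fixes and their 95th-percentile radius."""
    pts = np.asarray(night_xy, dtype=float)
    if len(pts) == 0:
        raise ValueError("no nighttime fixes")
    med = pts.mean(axis=0)
    for _ in range(max_iter):  # Weiszfeld iteration
        d = np.linalg.norm(pts - med, axis=1)
        d = np.where(d < 1e-9, 1e-9, d)
        new = (pts / d[:, None]).sum(axis=0) / (1.0 / d).sum()
        if np.linalg.norm(new - med) < 1e-9:
            med = new
            break
        med = new
    radii = np.linalg.norm(pts - med, axis=1)
    return {
        "x_m": float(med[0]),
        "y_m": float(med[1]),
        "r95_m": float(np.percentile(radii, 95)),
        "n_fixes": int(len(pts)),
    }
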