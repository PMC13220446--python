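"""Nanocluster analysis of localization point patterns.

Reproduces the dSTORM cluster pipeline: a manually drawn ROI is cut into a
regular grid of 3000 x 3000 nm sub-regions (keeping only squares entirely
inside the ROI), each sub-region is clustered with DBSCAN (eps 20 nm,
minPts 5, the neighbourhood counting the point itself), per-cluster convex
hull area / radius / density are measured, and Ripley's L-function with
isotropic edge correction is evaluated up to 2200 nm, reporting the signed
maximum deviation of L(r) - r as the clustering-strength statistic.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.spatial import ConvexHull, QhullError
from shapely.geometry import box as _box
from sklearn.cluster import DBSCAN as _SKDBSCAN

from .io import AnalysisConfig, ConfigurationError, LocalizationTable, RoiPolygon

NOISE = -1

#: cap on the isotropic edge-correction weight (numerical guard for points
#: whose correction circle lies almost entirely outside the window)
MAX_EDGE_WEIGHT = 100.0

#: default number of radius-grid points for L(r); 20 nm steps at r_max 2200
DEFAULT_N_R = 110


# ---------------------------------------------------------------------------
# Grid segmentation
# ---------------------------------------------------------------------------

@dataclass
class SubRegion:
    """An axis-aligned square analysis window inside the parent ROI."""

    x0: float
    y0: float
    size: float
    indices: np.ndarray = field(default_factory=lambda: np.empty(0, np.int64))
    xy: np.ndarray = field(default_factory=lambda: np.empty((0, 2)))

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        return (self.x0, self.y0, self.x0 + self.size, self.y0 + self.size)

    @property
    def area(self) -> float:
        return self.size * self.size

    @property
    def n_points(self) -> int:
        return len(self.xy)


def segment_grid(roi: RoiPolygon, locs: LocalizationTable,
                 grid_size: float = 3000.0) -> list[SubRegion]:
    """Cut the ROI into grid squares entirely contained in the polygon.

    The grid is anchored at the minimum corner of the ROI bounding box.  A
    square is kept iff the polygon covers it entirely (exact geometric
    predicate).  Each kept square receives the localizations in its
    half-open extent [x0, x0+size) x [y0, y0+size).
    """
    if grid_size <= 0:
        raise ConfigurationError("grid_size must be > 0")
    xmin, ymin, xmax, ymax = roi.bounds
    poly = roi.shapely
    xy = locs.xy
    out: list[SubRegion] = []
    nx = int(np.floor((xmax - xmin) / grid_size + 1e-9))
    ny = int(np.floor((ymax - ymin) / grid_size + 1e-9))
    for iy in range(ny):
        for ix in range(nx):
            x0 = xmin + ix * grid_size
            y0 = ymin + iy * grid_size
            if not poly.covers(_box(x0, y0, x0 + grid_size, y0 + grid_size)):
                continue
            inside = ((xy[:, 0] >= x0) & (xy[:, 0] < x0 + grid_size) &
                      (xy[:, 1] >= y0) & (xy[:, 1] < y0 + grid_size))
            idx = np.flatnonzero(inside)
            out.append(SubRegion(x0, y0, grid_size, idx, xy[idx]))
    if not out:
        warnings.warn("no grid square fits entirely inside the ROI", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# DBSCAN
# ---------------------------------------------------------------------------

def dbscan(points: np.ndarray, eps: float = 20.0, min_pts: int = 5) -> np.ndarray:
    """Classical DBSCAN labels (-1 = noise, clusters numbered from 0).

    A point is a core point iff its closed eps-neighbourhood, including the
    point itself, holds at least ``min_pts`` points.  Clusters are the
    connected components of core points under eps-reachability; border
    points join the first cluster that reaches them in ascending scan
    order.
    """
    if eps <= 0:
        raise ConfigurationError("eps must be > 0")
    if min_pts < 1:
        raise ConfigurationError("min_pts must be >= 1")
    points = np.asarray(points, float)
    if len(points) == 0:
        return np.empty(0, np.int64)
    return _SKDBSCAN(eps=eps, min_samples=min_pts).fit(points).labels_.astype(np.int64)


# ---------------------------------------------------------------------------
# Convex-hull metrics
# ---------------------------------------------------------------------------

def hull_metrics(points: np.ndarray) -> tuple[float, float, float]:
    """(hull_area nm^2, radius nm, density locs/nm^2) of one cluster.

    Radius is the equivalent-circle radius sqrt(area/pi).  Degenerate
    clusters (< 3 non-collinear points) get area 0, radius 0, density NaN.
    """
    points = np.asarray(points, float)
    if len(points) == 0:
        raise ConfigurationError("hull_metrics needs a non-empty cluster")
    area = 0.0
    if len(points) >= 3:
        try:
            area = float(ConvexHull(points).volume)   # 2-D: volume == area
        except QhullError:
            area = 0.0
    radius = float(np.sqrt(area / np.pi))
    density = len(points) / area if area > 0 else np.nan
    return area, radius, density


# ---------------------------------------------------------------------------
# Ripley's K / L
# ---------------------------------------------------------------------------

def _isotropic_weights(centers: np.ndarray, d: np.ndarray,
                       bounds: tuple[float, float, float, float]) -> np.ndarray:
    """Ripley isotropic edge-correction weight for circles of radius ``d``
    centred at ``centers`` inside a rectangular window.

    The weight is the reciprocal of the fraction of each circle's
    circumference lying inside the rectangle (exact closed form: per-edge
    arc cuts minus per-corner double counts), capped at MAX_EDGE_WEIGHT.
    """
    x0, y0, x1, y1 = bounds
    d = np.asarray(d, float)
    with np.errstate(invalid="ignore", divide="ignore"):
        dl = centers[:, 0] - x0
        dr = x1 - centers[:, 0]
        db = centers[:, 1] - y0
        dt = y1 - centers[:, 1]
        ang = np.zeros_like(d)
        for e in (dl, dr, db, dt):
            ang += 2.0 * np.arccos(np.clip(e / d, -1.0, 1.0)) * (e < d)
        for ex, ey in ((dl, db), (dl, dt), (dr, db), (dr, dt)):
            over = (np.arccos(np.clip(ex / d, -1.0, 1.0)) +
                    np.arccos(np.clip(ey / d, -1.0, 1.0)) - 0.5 * np.pi)
            ang -= np.where((ex * ex + ey * ey < d * d) & (over > 0), over, 0.0)
        frac = 1.0 - ang / (2.0 * np.pi)
        w = np.where(frac > 1.0 / MAX_EDGE_WEIGHT, 1.0 / frac, MAX_EDGE_WEIGHT)
    return w


def ripley_l(points: np.ndarray,
             window,
             r_max: float = 2200.0,
             n_r: int = DEFAULT_N_R,
             correction: str = "isotropic",
             signed: bool = True) -> tuple[np.ndarray, np.ndarray, float]:
    """Ripley's L-function on a square/rectangular window.

    K_hat(r) = A / (n (n-1)) * sum_{i != j} e_ij 1[d_ij <= r] with the
    selected edge correction (``isotropic`` default, ``translation`` or
    ``none``); L(r) = sqrt(K_hat / pi).  Returns (r grid, L(r), max_dev)
    where max_dev is the maximum of L(r) - r over the grid (signed by
    default; absolute with ``signed=False``).  The r grid is ``n_r`` equal
    steps in (0, r_max].
    """
    points = np.asarray(points, float)
    bounds = window.bounds if hasattr(window, "bounds") else tuple(window)
    x0, y0, x1, y1 = bounds
    area = (x1 - x0) * (y1 - y0)
    r = r_max * np.arange(1, n_r + 1) / n_r
    n = len(points)
    if n < 2:
        warnings.warn("Ripley's L needs >= 2 points; returning NaN", stacklevel=2)
        return r, np.full(n_r, np.nan), np.nan
    ii, jj = np.nonzero(~np.eye(n, dtype=bool))
    d = np.linalg.norm(points[ii] - points[jj], axis=1)
    keep = d <= r_max
    ii, d = ii[keep], d[keep]
    if correction == "isotropic":
        w = _isotropic_weights(points[ii], d, bounds)
    elif correction == "translation":
        dx = np.abs(points[ii, 0] - points[jj[keep], 0])
        dy = np.abs(points[ii, 1] - points[jj[keep], 1])
        w = area / ((x1 - x0 - dx) * (y1 - y0 - dy))
    elif correction == "none":
        w = np.ones_like(d)
    else:
        raise ConfigurationError(f"unknown edge correction {correction!r}")
    order = np.argsort(d)
    d_sorted = d[order]
    cum = np.concatenate([[0.0], np.cumsum(w[order])])
    k = area / (n * (n - 1)) * cum[np.searchsorted(d_sorted, r, side="right")]
    el = np.sqrt(k / np.pi)
    dev = el - r
    max_dev = float(np.max(dev) if signed else np.max(np.abs(dev)))
    return r, el, max_dev


# ---------------------------------------------------------------------------
# Full ROI analysis
# ---------------------------------------------------------------------------

@dataclass
class ClusterReport:
    """Aggregated per-point, per-cluster and per-sub-region cluster metrics."""

    points: pd.DataFrame       # subregion, loc_index, label
    clusters: pd.DataFrame     # subregion, cluster, n_locs, hull_area_nm2, radius_nm, density_per_nm2
    subregions: pd.DataFrame   # subregion, x0, y0, size, n_points, n_clusters,
                               # n_noise, clusters_per_um2, mean_locs_per_cluster,
                               # ripley_max_dev_nm
    summary: pd.DataFrame      # one-row overall summary

    def to_frames(self) -> dict[str, pd.DataFrame]:
        return {"points": self.points, "clusters": self.clusters,
                "subregions": self.subregions, "summary": self.summary}


def analyze_roi(locs: LocalizationTable, roi: RoiPolygon,
                config: AnalysisConfig | None = None,
                ripley: bool = True) -> ClusterReport:
    """Run the full cluster pipeline on one ROI.

    Grid-segments the ROI, then per sub-region: DBSCAN, convex-hull metrics
    for every cluster, and the Ripley max-deviation statistic.  Sub-region
    and cluster ordering is deterministic (row-major grid order, ascending
    cluster label).
    """
    cfg = config or AnalysisConfig()
    subs = segment_grid(roi, locs, cfg.grid_size)
    point_rows, cluster_rows, sub_rows = [], [], []
    for s_idx, sub in enumerate(subs):
        labels = dbscan(sub.xy, cfg.eps, cfg.min_pts)
        for li, lab in zip(sub.indices, labels):
            point_rows.append((s_idx, int(li), int(lab)))
        cluster_ids = np.unique(labels[labels != NOISE])
        for cid in cluster_ids:
            pts = sub.xy[labels == cid]
            area, radius, density = hull_metrics(pts)
            cluster_rows.append((s_idx, int(cid), len(pts), area, radius, density))
        n_clusters = len(cluster_ids)
        if ripley and sub.n_points >= 2:
            _, _, max_dev = ripley_l(sub.xy, sub, cfg.ripley_rmax)
        else:
            max_dev = np.nan
        sub_rows.append((
            s_idx, sub.x0, sub.y0, sub.size, sub.n_points, n_clusters,
            int((labels == NOISE).sum()),
            n_clusters / (sub.area / 1e6),
            float(np.mean([r[2] for r in cluster_rows if r[0] == s_idx]))
            if n_clusters else np.nan,
            max_dev,
        ))
    points = pd.DataFrame(point_rows, columns=["subregion", "loc_index", "label"])
    clusters = pd.DataFrame(
        cluster_rows, columns=["subregion", "cluster", "n_locs",
                               "hull_area_nm2", "radius_nm", "density_per_nm2"])
    subregions = pd.DataFrame(
        sub_rows, columns=["subregion", "x0", "y0", "size", "n_points",
                           "n_clusters", "n_noise", "clusters_per_um2",
                           "mean_locs_per_cluster", "ripley_max_dev_nm"])
    summary = pd.DataFrame([{
        "n_subregions": len(subs),
        "n_points": int(subregions["n_points"].sum()) if len(subs) else 0,
        "n_clusters": int(subregions["n_clusters"].sum()) if len(subs) else 0,
        "clusters_per_um2": float(subregions["clusters_per_um2"].mean())
        if len(subs) else np.nan,
        "mean_locs_per_cluster": float(clusters["n_locs"].mean())
        if len(clusters) else np.nan,
        "mean_hull_area_nm2": float(clusters["hull_area_nm2"].mean())
        if len(clusters) else np.nan,
        "mean_ripley_max_dev_nm": float(subregions["ripley_max_dev_nm"].mean())
        if len(subs) else np.nan,
    }])
    return ClusterReport(points, clusters, subregions, summary)
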