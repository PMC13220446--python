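"""Independent brute-force reference implementations used only by tests.

Each oracle recomputes a pipeline quantity by a deliberately different,
slower route (explicit graphs, exhaustive geometry, numeric integration,
per-pixel loops) so that agreement with the package is a genuine
cross-check rather than a tautology.
"""

from __future__ import annotations

import math

import numpy as np


# ---------------------------------------------------------------------------
# DBSCAN: explicit core graph + BFS
# ---------------------------------------------------------------------------

def brute_dbscan(points: np.ndarray, eps: float, min_pts: int) -> np.ndarray:
    """O(n^2) DBSCAN building the eps-graph explicitly.

    Core iff closed neighbourhood (incl. self) has >= min_pts members;
    clusters grow from cores in ascending index order; border points join
    the first (lowest-id) cluster that reaches them.
    """
    pts = np.asarray(points, float)
    n = len(pts)
    labels = np.full(n, -1, np.int64)
    if n == 0:
        return labels
    d = np.sqrt(((pts[:, None, :] - pts[None, :, :]) ** 2).sum(-1))
    nbr = d <= eps
    core = nbr.sum(1) >= min_pts
    cid = -1
    visited = np.zeros(n, bool)
    for i in range(n):
        if visited[i] or not core[i]:
            continue
        cid += 1
        stack = [i]
        visited[i] = True
        while stack:
            p = stack.pop()
            labels[p] = cid
            if not core[p]:
                continue
            for q in np.flatnonzero(nbr[p]):
                if not visited[q]:
                    visited[q] = True
                    stack.append(q)
    return labels


def same_partition(a: np.ndarray, b: np.ndarray) -> bool:
    """True iff two label vectors agree up to cluster renumbering (noise
    must match exactly)."""
    a, b = np.asarray(a), np.asarray(b)
    if a.shape != b.shape:
        return False
    if not np.array_equal(a == -1, b == -1):
        return False
    mapping: dict[int, int] = {}
    back: dict[int, int] = {}
    for x, y in zip(a, b):
        if x == -1:
            continue
        if mapping.setdefault(x, y) != y or back.setdefault(y, x) != x:
            return False
    return True


# ---------------------------------------------------------------------------
# Convex hull: exhaustive edge orientation test
# ---------------------------------------------------------------------------

def exhaustive_hull_area(points: np.ndarray) -> float:
    """Hull area from the O(n^3) edge test: (i, j) is a hull edge iff every
    other point lies on one side; vertices ordered by angle, shoelace."""
    pts = np.asarray(points, float)
    pts = np.unique(pts, axis=0)
    n = len(pts)
    if n < 3:
        return 0.0
    hull_vertices = set()
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            e = pts[j] - pts[i]
            cross = e[0] * (pts[:, 1] - pts[i, 1]) - e[1] * (pts[:, 0] - pts[i, 0])
            others = np.delete(cross, [i, j])
            if np.all(others >= -1e-9) or np.all(others <= 1e-9):
                hull_vertices.add(i)
                hull_vertices.add(j)
    verts = pts[sorted(hull_vertices)]
    if len(verts) < 3:
        return 0.0
    c = verts.mean(0)
    ang = np.arctan2(verts[:, 1] - c[1], verts[:, 0] - c[0])
    verts = verts[np.argsort(ang)]
    x, y = verts[:, 0], verts[:, 1]
    return 0.5 * abs(np.dot(x, np.roll(y, -1)) - np.dot(y, np.roll(x, -1)))


# ---------------------------------------------------------------------------
# Ripley K: numeric arc integration for the isotropic edge weight
# ---------------------------------------------------------------------------

def ripley_k_numeric(points: np.ndarray, bounds, r_grid: np.ndarray,
                     n_angles: int = 4096) -> np.ndarray:
    """K_hat with the isotropic correction, the circumference fraction
    evaluated by brute-force angular sampling instead of closed form."""
    pts = np.asarray(points, float)
    x0, y0, x1, y1 = bounds
    area = (x1 - x0) * (y1 - y0)
    n = len(pts)
    ang = 2 * np.pi * (np.arange(n_angles) + 0.5) / n_angles
    ca, sa = np.cos(ang), np.sin(ang)
    k = np.zeros(len(r_grid))
    for i in range(n):
        for j in range(n):
            if i == j:
                continue
            d = math.hypot(pts[i, 0] - pts[j, 0], pts[i, 1] - pts[j, 1])
            if d > r_grid[-1]:
                continue
            cx = pts[i, 0] + d * ca
            cy = pts[i, 1] + d * sa
            frac = np.mean((cx >= x0) & (cx <= x1) & (cy >= y0) & (cy <= y1))
            w = 1.0 / frac if frac > 0.01 else 100.0
            k[r_grid >= d] += w
    return area / (n * (n - 1)) * k


# ---------------------------------------------------------------------------
# Greedy frame-to-frame linking (pure-python re-implementation)
# ---------------------------------------------------------------------------

def greedy_link_oracle(xy: np.ndarray, frames: np.ndarray,
                       link_radius: float) -> np.ndarray:
    """Track ids from an independent pure-python greedy linker (gap 0):
    per frame pair, all candidate links sorted by (distance, previous row,
    current row) and taken one-to-one."""
    n = len(xy)
    track = np.full(n, -1, np.int64)
    nxt = 0
    for f in sorted(set(int(v) for v in frames)):
        rows = [i for i in range(n) if frames[i] == f]
        prev = [i for i in range(n) if frames[i] == f - 1]
        cands = []
        for r in rows:
            for p in prev:
                d = math.hypot(xy[r, 0] - xy[p, 0], xy[r, 1] - xy[p, 1])
                if d <= link_radius:
                    cands.append((d, p, r))
        used_p, used_r = set(), set()
        for d, p, r in sorted(cands):
            if p in used_p or r in used_r:
                continue
            used_p.add(p)
            used_r.add(r)
            track[r] = track[p]
        for r in rows:
            if track[r] == -1:
                track[r] = nxt
                nxt += 1
    return track


def same_tracks(a: np.ndarray, b: np.ndarray) -> bool:
    """Track partitions equal up to id renumbering."""
    return same_partition(np.asarray(a), np.asarray(b))


# ---------------------------------------------------------------------------
# Radial binning: per-pixel ray casting
# ---------------------------------------------------------------------------

def ray_rho_oracle(centroid, outline: np.ndarray, px_nm: np.ndarray) -> np.ndarray:
    """rho per point by looping rays and segments in pure python; first
    boundary crossing wins."""
    cx, cy = centroid
    out = np.empty(len(px_nm))
    segs = list(zip(outline, np.roll(outline, -1, axis=0)))
    for k, (px, py) in enumerate(px_nm):
        dx, dy = px - cx, py - cy
        dist = math.hypot(dx, dy)
        if dist == 0:
            out[k] = 0.0
            continue
        ux, uy = dx / dist, dy / dist
        tmin = math.inf
        for a, b in segs:
            ex, ey = b[0] - a[0], b[1] - a[1]
            denom = ux * (-ey) - uy * (-ex)
            if denom == 0:
                continue
            ax, ay = a[0] - cx, a[1] - cy
            t = (ax * (-ey) - ay * (-ex)) / denom
            s = (ux * ay - uy * ax) / denom
            if t > 1e-9 and 0.0 <= s < 1.0:
                tmin = min(tmin, t)
        out[k] = min(dist / tmin, 1.0) if math.isfinite(tmin) else 1.0
    return out


def profile_oracle(signal: np.ndarray, bins: np.ndarray, n_bins: int):
    """Per-bin mean intensity by direct per-pixel accumulation."""
    sums = np.zeros(n_bins)
    counts = np.zeros(n_bins, int)
    ny, nx = signal.shape
    for i in range(ny):
        for j in range(nx):
            b = bins[i, j]
            if b >= 0:
                sums[b] += signal[i, j]
                counts[b] += 1
    with np.errstate(invalid="ignore"):
        return np.where(counts > 0, sums / np.maximum(counts, 1), np.nan), counts


# ---------------------------------------------------------------------------
# Kymograph: direct bilinear interpolation
# ---------------------------------------------------------------------------

def bilinear_oracle(frame: np.ndarray, rows: np.ndarray, cols: np.ndarray) -> np.ndarray:
    """Bilinear interpolation at (row, col) index coordinates, pure python."""
    out = np.empty(len(rows))
    ny, nx = frame.shape
    for k, (r, c) in enumerate(zip(rows, cols)):
        i0, j0 = int(math.floor(r)), int(math.floor(c))
        fr, fc = r - i0, c - j0
        i1, j1 = min(i0 + 1, ny - 1), min(j0 + 1, nx - 1)
        out[k] = ((1 - fr) * (1 - fc) * frame[i0, j0] +
                  (1 - fr) * fc * frame[i0, j1] +
                  fr * (1 - fc) * frame[i1, j0] +
                  fr * fc * frame[i1, j1])
    return out


# ---------------------------------------------------------------------------
# FRAP: symbolic three-step normalization on closed-form traces
# ---------------------------------------------------------------------------

def frap_normalized_oracle(time: np.ndarray, trace: np.ndarray,
                           reference: np.ndarray, bleach_time: float) -> np.ndarray:
    """The three-step normalization evaluated directly (reference
    subtraction, zeroing at the first post-bleach sample, scaling by the
    pre-bleach mean), written independently of the package."""
    pre = time < bleach_time
    i0 = int(np.sum(pre))
    f1 = np.asarray(trace, float) - np.asarray(reference, float)
    f2 = f1 - f1[i0]
    return f2 / np.mean(f2[pre])
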