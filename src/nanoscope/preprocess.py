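"""Post-processing of single-molecule localization tables.

Implements the dSTORM post-processing chain: stage-drift estimation by
absolute image correlation of temporal windows, per-frame drift removal,
blink-track assignment by greedy nearest-neighbour linking, track-length /
precision filtering with optional merging of each track into one
localization, and Gaussian rendering onto a regular lattice.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.special import ndtr

from .io import (ConfigurationError, ImageStack, LocalizationTable,
                 NotEnoughDataError)


# ---------------------------------------------------------------------------
# Drift correction
# ---------------------------------------------------------------------------

@dataclass
class DriftTrajectory:
    """Estimated stage drift, per correlation window and per frame.

    The first (reference) window has shift exactly (0, 0); per-frame shifts
    are linear interpolations between window-centre times with constant
    extrapolation before the first and after the last centre.
    """

    window_times: np.ndarray     # s, window centres
    dx: np.ndarray               # nm per window, relative to first window
    dy: np.ndarray
    frames: np.ndarray           # all frames covered
    frame_dx: np.ndarray         # nm per frame
    frame_dy: np.ndarray

    def shift_at(self, frame: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        frame = np.asarray(frame)
        lo, hi = self.frames[0], self.frames[-1]
        if frame.size and (frame.min() < lo or frame.max() > hi):
            raise ValueError(
                f"frame outside drift trajectory span [{lo}, {hi}]")
        idx = frame - lo
        return self.frame_dx[idx], self.frame_dy[idx]

    def negated(self) -> "DriftTrajectory":
        return DriftTrajectory(self.window_times, -self.dx, -self.dy,
                               self.frames, -self.frame_dx, -self.frame_dy)


def _window_histogram(xy: np.ndarray, extent, pixel: float) -> np.ndarray:
    xmin, ymin, xmax, ymax = extent
    nx = max(int(np.ceil((xmax - xmin) / pixel)), 1)
    ny = max(int(np.ceil((ymax - ymin) / pixel)), 1)
    h, _, _ = np.histogram2d(xy[:, 1], xy[:, 0], bins=(ny, nx),
                             range=((ymin, ymin + ny * pixel),
                                    (xmin, xmin + nx * pixel)))
    return h


def _quadratic_peak(c: np.ndarray) -> float:
    """Sub-sample offset of a peak from its 3-point neighbourhood."""
    denom = c[0] - 2.0 * c[1] + c[2]
    if denom == 0:
        return 0.0
    delta = 0.5 * (c[0] - c[2]) / denom
    return float(np.clip(delta, -0.5, 0.5))


def _xcorr_shift(ref: np.ndarray, img: np.ndarray, pixel: float) -> tuple[float, float]:
    """Shift (dx, dy) in nm that maps ``ref`` onto ``img`` (peak of the
    full cross-correlation, refined by per-axis quadratic interpolation)."""
    from scipy.fft import next_fast_len

    ny, nx = ref.shape
    fshape = (next_fast_len(2 * ny - 1), next_fast_len(2 * nx - 1))
    full = np.fft.irfft2(np.fft.rfft2(img, fshape) *
                         np.conj(np.fft.rfft2(ref, fshape)), fshape)
    # reorder circular lags to [-(n-1), ..., n-1] per axis
    corr = np.concatenate([full[-(ny - 1):], full[:ny]], axis=0)
    corr = np.concatenate([corr[:, -(nx - 1):], corr[:, :nx]], axis=1)
    iy, ix = np.unravel_index(np.argmax(corr), corr.shape)
    cy, cx = ny - 1, nx - 1
    dy, dx = float(iy - cy), float(ix - cx)
    if 0 < iy < corr.shape[0] - 1:
        dy += _quadratic_peak(corr[iy - 1:iy + 2, ix])
    if 0 < ix < corr.shape[1] - 1:
        dx += _quadratic_peak(corr[iy, ix - 1:ix + 2])
    return dx * pixel, dy * pixel


def estimate_drift(locs: LocalizationTable,
                   frame_rate: float,
                   pixel: float = 10.0,
                   window: float = 200.0,
                   min_locs_per_window: int = 100) -> DriftTrajectory:
    """Estimate stage drift by absolute image correlation.

    The acquisition is cut into complete windows of ``window`` seconds; the
    2-D localization histogram of each window (bin = ``pixel`` nm) is
    cross-correlated against the first window's histogram, and the
    correlation peak, refined to sub-bin accuracy, gives that window's
    displacement.  Per-frame shifts interpolate linearly between window
    centres (constant at the ends).

    Raises :class:`NotEnoughDataError` with fewer than two complete windows.
    Windows with fewer than ``min_locs_per_window`` localizations are
    skipped with a warning and bridged by the interpolation.
    """
    if pixel <= 0 or window <= 0 or frame_rate <= 0:
        raise ConfigurationError("pixel, window and frame_rate must be > 0")
    if len(locs) == 0:
        raise NotEnoughDataError("empty localization table")
    frames = locs.frames
    n_frames = int(frames.max()) + 1
    wframes = int(round(window * frame_rate))
    n_windows = n_frames // wframes
    # a trailing partial window at least half full still anchors the tail
    # of the trajectory (otherwise it would be constant-extrapolated)
    if n_frames - n_windows * wframes >= wframes // 2:
        n_windows += 1
    if n_windows < 2:
        raise NotEnoughDataError(
            f"need >= 2 {window:g}-s windows, acquisition has {n_windows}")
    xy = locs.xy
    extent = (xy[:, 0].min(), xy[:, 1].min(), xy[:, 0].max(), xy[:, 1].max())

    hists, centers_s, counts = [], [], []
    for w in range(n_windows):
        f0, f1 = w * wframes, min((w + 1) * wframes, n_frames)
        in_w = (frames >= f0) & (frames < f1)
        counts.append(int(in_w.sum()))
        hists.append(_window_histogram(xy[in_w], extent, pixel))
        centers_s.append(0.5 * (f0 + f1) / frame_rate)

    valid = [i for i, c in enumerate(counts) if c >= min_locs_per_window]
    if len(valid) < 2:
        raise NotEnoughDataError(
            "fewer than 2 windows meet the localization minimum "
            f"({min_locs_per_window})")
    skipped = [i for i in range(n_windows) if i not in valid]
    if skipped:
        warnings.warn(f"drift windows {skipped} skipped "
                      f"(< {min_locs_per_window} localizations); interpolating",
                      stacklevel=2)
    ref = hists[valid[0]]
    dx = np.zeros(len(valid))
    dy = np.zeros(len(valid))
    for k, i in enumerate(valid[1:], start=1):
        dx[k], dy[k] = _xcorr_shift(ref, hists[i], pixel)

    wt = np.array([centers_s[i] for i in valid])
    all_frames = np.arange(n_frames)
    t = all_frames / frame_rate
    return DriftTrajectory(window_times=wt, dx=dx, dy=dy, frames=all_frames,
                           frame_dx=np.interp(t, wt, dx),
                           frame_dy=np.interp(t, wt, dy))


def apply_drift(locs: LocalizationTable,
                trajectory: DriftTrajectory) -> LocalizationTable:
    """Subtract the per-frame drift: x' = x - dx(frame), y' = y - dy(frame)."""
    df = locs.df.copy()
    if len(df):
        sx, sy = trajectory.shift_at(locs.frames)
        df["x"] = df["x"].to_numpy() - sx
        df["y"] = df["y"].to_numpy() - sy
    return LocalizationTable(df)


# ---------------------------------------------------------------------------
# Track assignment and merging
# ---------------------------------------------------------------------------

@dataclass
class TrackSet:
    """Partition of a localization table into blink tracks.

    ``track_id`` per localization; ``tracks`` summarises each track's first
    and last frame, length in frames (span) and number of localizations.
    """

    locs: LocalizationTable
    track_id: np.ndarray
    tracks: pd.DataFrame        # track_id, first_frame, last_frame, length, n_locs


def assign_tracks(locs: LocalizationTable, link_radius: float,
                  max_gap: int = 0) -> TrackSet:
    """Greedy nearest-neighbour blink-track linking.

    Localizations in consecutive frames (or across gaps up to ``max_gap``
    frames) within ``link_radius`` nm are linked into one track.  Pairing is
    globally greedy per frame: candidate links are taken in order of
    increasing distance with ties broken by lowest row index, each end
    linked at most once.  Deterministic for a given row order.
    """
    if link_radius <= 0:
        raise ConfigurationError("link_radius must be > 0")
    n = len(locs)
    track_id = np.full(n, -1, np.int64)
    if n == 0:
        return TrackSet(locs, track_id, pd.DataFrame(
            columns=["track_id", "first_frame", "last_frame", "length", "n_locs"]))
    xy = locs.xy
    frames = locs.frames
    order = np.argsort(frames, kind="stable")
    by_frame: dict[int, np.ndarray] = {}
    for f in np.unique(frames):
        by_frame[int(f)] = order[np.searchsorted(frames[order], [f, f + 1])[0]:
                                 np.searchsorted(frames[order], f, side="right")]
    # simpler: rebuild via boolean masks (cheap enough, done once per frame)
    by_frame = {int(f): np.flatnonzero(frames == f) for f in np.unique(frames)}

    next_track = 0
    # track end bookkeeping: row index of the last localization of each open track
    open_ends: dict[int, tuple[int, int]] = {}   # track -> (row, last_frame)
    for f in sorted(by_frame):
        rows = by_frame[f]
        # candidate previous ends within the allowed gap
        prev = [(tid, row) for tid, (row, lf) in open_ends.items()
                if f - 1 - max_gap <= lf <= f - 1]
        if prev:
            prev_rows = np.array([r for _, r in prev])
            d = np.linalg.norm(xy[rows][:, None, :] - xy[prev_rows][None, :, :],
                               axis=2)
            cand = np.argwhere(d <= link_radius)
            # sort by (distance, previous row, current row) for determinism
            keys = sorted(
                ((d[i, j], prev_rows[j], rows[i], i, j) for i, j in cand),
                key=lambda t: (t[0], t[1], t[2]))
            used_cur: set[int] = set()
            used_prev: set[int] = set()
            for _, _, _, i, j in keys:
                if i in used_cur or j in used_prev:
                    continue
                used_cur.add(i)
                used_prev.add(j)
                tid = prev[j][0]
                track_id[rows[i]] = tid
                open_ends[tid] = (int(rows[i]), f)
        for r in rows:
            if track_id[r] == -1:
                track_id[r] = next_track
                open_ends[next_track] = (int(r), f)
                next_track += 1
        # close tracks that can no longer be extended
        open_ends = {tid: (row, lf) for tid, (row, lf) in open_ends.items()
                     if lf >= f - max_gap}

    g = pd.DataFrame({"track_id": track_id, "frame": frames}).groupby("track_id")
    tracks = g["frame"].agg(first_frame="min", last_frame="max",
                            n_locs="size").reset_index()
    tracks["length"] = tracks["last_frame"] - tracks["first_frame"] + 1
    tracks = tracks[["track_id", "first_frame", "last_frame", "length", "n_locs"]]
    return TrackSet(locs, track_id, tracks)


def filter_and_merge(tracks: TrackSet,
                     len_min: int = 1,
                     len_max: int = 5,
                     precision_max: float | None = None,
                     merge: bool = True) -> LocalizationTable:
    """Filter tracks on length (and localizations on precision), then merge.

    Localizations with precision above ``precision_max`` are dropped first;
    tracks whose frame span falls outside ``[len_min, len_max]`` are removed
    entirely.  With ``merge=True`` each surviving track collapses to a
    single localization at the precision-weighted mean position (weights
    1/sigma^2; unweighted mean when precision is unknown), frame = first
    frame, combined precision 1/sqrt(sum 1/sigma_i^2).
    """
    if len_min > len_max:
        raise ConfigurationError("len_min must be <= len_max")
    df = tracks.locs.df.copy()
    df["track_id"] = tracks.track_id
    if precision_max is not None:
        keep = np.isnan(df["precision"]) | (df["precision"] <= precision_max)
        df = df[keep]
    if len(df) == 0:
        return LocalizationTable.empty()
    g = df.groupby("track_id")["frame"]
    span = (g.transform("max") - g.transform("min") + 1)
    df = df[(span >= len_min) & (span <= len_max)]
    if len(df) == 0:
        return LocalizationTable.empty()
    if not merge:
        return LocalizationTable(df.reset_index(drop=True))

    codes, track_ids = pd.factorize(df["track_id"], sort=True)
    n_tracks = len(track_ids)
    prec = df["precision"].to_numpy(float)
    prec_nan = np.isnan(prec)
    had_nan = np.bincount(codes, prec_nan, n_tracks) > 0
    # any-NaN track falls back to the unweighted mean
    w = np.where(prec_nan | had_nan[codes], 1.0, 1.0 / prec ** 2)
    w_sum = np.bincount(codes, w, n_tracks)
    x = np.bincount(codes, w * df["x"].to_numpy(), n_tracks) / w_sum
    y = np.bincount(codes, w * df["y"].to_numpy(), n_tracks) / w_sum
    frame = np.full(n_tracks, np.iinfo(np.int64).max)
    np.minimum.at(frame, codes, df["frame"].to_numpy())
    inten = df["intensity"].to_numpy(float)
    inten_sum = np.bincount(codes, np.nan_to_num(inten), n_tracks)
    inten_any = np.bincount(codes, ~np.isnan(inten), n_tracks) > 0
    merged = pd.DataFrame({
        "x": x, "y": y, "frame": frame,
        "precision": np.where(had_nan, np.nan, 1.0 / np.sqrt(w_sum)),
        "track_id": track_ids,
        "intensity": np.where(inten_any, inten_sum, np.nan),
    })
    return LocalizationTable(merged).sort()


# ---------------------------------------------------------------------------
# Rendering
# ---------------------------------------------------------------------------

def render_gaussian(locs: LocalizationTable,
                    lattice: float = 10.0,
                    sigma: float = 20.0,
                    sigma_mode: str = "fixed",
                    extent: tuple[float, float, float, float] | None = None,
                    truncate: float = 4.0) -> ImageStack:
    """Render each localization as a unit-integral 2-D Gaussian.

    Gaussians are integrated exactly over each lattice pixel (product of
    per-axis normal CDF differences) and truncated at ``truncate`` sigma, so
    the image sums to the localization count to well within 1%.
    ``sigma_mode='per-precision'`` uses each localization's precision as its
    sigma (falling back to ``sigma`` where unknown).
    """
    if lattice <= 0 or sigma <= 0:
        raise ConfigurationError("lattice and sigma must be > 0")
    if sigma_mode not in ("fixed", "per-precision"):
        raise ConfigurationError("sigma_mode must be 'fixed' or 'per-precision'")
    xy = locs.xy
    if extent is None:
        if len(locs) == 0:
            extent = (0.0, 0.0, lattice, lattice)
        else:
            pad = truncate * sigma
            extent = (xy[:, 0].min() - pad, xy[:, 1].min() - pad,
                      xy[:, 0].max() + pad, xy[:, 1].max() + pad)
    xmin, ymin, xmax, ymax = extent
    nx = max(int(np.ceil((xmax - xmin) / lattice)), 1)
    ny = max(int(np.ceil((ymax - ymin) / lattice)), 1)
    img = np.zeros((ny, nx))
    if len(locs) == 0:
        return ImageStack(img, lattice)
    sigmas = np.full(len(locs), float(sigma))
    if sigma_mode == "per-precision":
        prec = locs.precision
        ok = ~np.isnan(prec) & (prec > 0)
        sigmas[ok] = prec[ok]
    for (x, y), s in zip(xy, sigmas):
        r = truncate * s
        j0 = max(int(np.floor((x - r - xmin) / lattice)), 0)
        j1 = min(int(np.ceil((x + r - xmin) / lattice)), nx)
        i0 = max(int(np.floor((y - r - ymin) / lattice)), 0)
        i1 = min(int(np.ceil((y + r - ymin) / lattice)), ny)
        if j0 >= j1 or i0 >= i1:
            continue
        ex = ndtr((xmin + np.arange(j0, j1 + 1) * lattice - x) / s)
        ey = ndtr((ymin + np.arange(i0, i1 + 1) * lattice - y) / s)
        img[i0:i1, j0:j1] += np.outer(np.diff(ey), np.diff(ex))
    return ImageStack(img, lattice)
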