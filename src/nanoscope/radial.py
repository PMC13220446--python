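"""Radial (concentric-ROI) intensity profiling of synapse images.

The cell footprint is segmented from the actin channel; 50 concentric,
outline-following rings are laid from the centroid to the cell periphery;
the mean fluorescence intensity (MFI) of each ring is normalized to the
innermost ring, giving a dimensionless centre-to-edge profile that can be
averaged across cells.  A periphery/centre ratio summarises centralization.

Ring geometry: every pixel gets a normalized radial coordinate
rho = |p - c| / R(theta), where R(theta) is the distance from the centroid
c to the cell outline along the pixel's direction, so iso-rho contours are
shrunken copies of the outline.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy import ndimage
from skimage import measure
from skimage.filters import threshold_otsu

from .io import ConfigurationError, ImageStack, NanoscopeError


class CentroidOutsideError(NanoscopeError):
    """Centroid falls outside the mask; use the distance-transform fallback
    (``radial_bins(..., method='dt')``)."""


# ---------------------------------------------------------------------------
# Segmentation
# ---------------------------------------------------------------------------

@dataclass
class CellMask:
    """A single segmented cell: binary mask + outline polygon + centroid."""

    mask: np.ndarray             # bool, full image frame
    outline: np.ndarray          # (n, 2) nm, (x, y)
    centroid: tuple[float, float]   # nm
    pixel_size: float            # nm
    star_shaped: bool = True     # False if centroid-rays cross the outline twice

    @property
    def area_um2(self) -> float:
        return float(self.mask.sum()) * self.pixel_size ** 2 / 1e6

    @property
    def centroid_inside(self) -> bool:
        cx, cy = self.centroid
        i = int(cy / self.pixel_size)
        j = int(cx / self.pixel_size)
        if not (0 <= i < self.mask.shape[0] and 0 <= j < self.mask.shape[1]):
            return False
        return bool(self.mask[i, j])


def _px_to_nm(rc: np.ndarray, s: float) -> np.ndarray:
    """(row, col) index coordinates -> (x, y) nm at pixel centres."""
    return np.column_stack([(rc[:, 1] + 0.5) * s, (rc[:, 0] + 0.5) * s])


def segment_cell(actin_image: ImageStack,
                 method: str = "otsu",
                 threshold: float | None = None,
                 min_area_um2: float = 10.0) -> list[CellMask]:
    """Segment cell footprints from the actin channel of a 2-D image.

    A global threshold (Otsu by default, or a fixed value) is followed by
    connected-component labelling; components smaller than ``min_area_um2``
    are discarded.  Outlines are sub-pixel marching-squares contours; the
    centroid is the binary centroid of the component.
    """
    img = actin_image.pixels
    if img.ndim != 2:
        raise ConfigurationError("segment_cell expects a single 2-D image")
    if method == "otsu":
        if img.max() == img.min():
            warnings.warn("blank image: no cells found", stacklevel=2)
            return []
        thr = threshold_otsu(img)
    elif method == "fixed":
        if threshold is None:
            raise ConfigurationError("method='fixed' requires a threshold")
        thr = threshold
    else:
        raise ConfigurationError(f"unknown segmentation method {method!r}")
    binary = img > thr
    labels, n = ndimage.label(binary)
    s = actin_image.pixel_size
    min_px = min_area_um2 * 1e6 / s ** 2
    out: list[CellMask] = []
    for lab in range(1, n + 1):
        comp = labels == lab
        if comp.sum() < min_px:
            continue
        # pad so contours of border-touching cells still close
        padded = np.pad(comp, 1)
        contours = measure.find_contours(padded.astype(float), 0.5)
        contour = max(contours, key=len) - 1.0     # undo padding offset
        rows, cols = np.nonzero(comp)
        centroid_nm = ((cols.mean() + 0.5) * s, (rows.mean() + 0.5) * s)
        out.append(CellMask(mask=comp, outline=_px_to_nm(contour, s),
                            centroid=centroid_nm, pixel_size=s))
    if not out:
        warnings.warn("no component passed the size threshold", stacklevel=2)
    return out


# ---------------------------------------------------------------------------
# Outline-following radial binning
# ---------------------------------------------------------------------------

def _ray_outline_distance(centroid: np.ndarray, directions: np.ndarray,
                          outline: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """First-crossing distance from the centroid to the outline along each
    unit direction; also returns whether any ray crossed more than once
    at distinct distances (non-star-shaped outline)."""
    a = outline
    b = np.roll(outline, -1, axis=0)
    e = b - a                                   # (m, 2) segment vectors
    ca = a[None, :, :] - centroid[None, None, :]  # (1, m, 2)
    multi = False
    out = np.full(len(directions), np.nan)
    chunk = 2048
    for lo in range(0, len(directions), chunk):
        u = directions[lo:lo + chunk]           # (k, 2)
        # solve centroid + t*u = a + s*e  per (ray, segment)
        denom = u[:, None, 0] * (-e[None, :, 1]) - u[:, None, 1] * (-e[None, :, 0])
        with np.errstate(divide="ignore", invalid="ignore"):
            t = (ca[:, :, 0] * (-e[None, :, 1]) - ca[:, :, 1] * (-e[None, :, 0])) / denom
            sseg = (u[:, None, 0] * ca[:, :, 1] - u[:, None, 1] * ca[:, :, 0]) / denom
        hit = (t > 1e-9) & (sseg >= 0.0) & (sseg < 1.0)
        t = np.where(hit, t, np.inf)
        tmin = t.min(axis=1)
        n_hits = hit.sum(axis=1)
        if np.any(n_hits > 2):                  # > 2 crossings: concave wrt centroid
            multi = True
        out[lo:lo + chunk] = tmin
    return out, multi


def radial_bins(mask: CellMask, n_bins: int = 50,
                method: str = "ray") -> tuple[np.ndarray, np.ndarray]:
    """Assign every mask pixel to one of ``n_bins`` outline-following rings.

    Returns ``(bin_index, rho)`` as full-frame float/int arrays (-1 / NaN
    outside the mask).  ``method='ray'`` uses the first outline crossing
    along each pixel's direction from the centroid (cells where rays cross
    multiple times are flagged on the mask); ``method='dt'`` is the
    distance-transform fallback rho = 1 - dt/dt_max for cells whose
    centroid lies outside the mask.
    """
    if n_bins < 2:
        raise ConfigurationError("n_bins must be >= 2")
    s = mask.pixel_size
    rows, cols = np.nonzero(mask.mask)
    rho_img = np.full(mask.mask.shape, np.nan)
    if method == "dt":
        dt = ndimage.distance_transform_edt(mask.mask) * s
        rho = 1.0 - dt[rows, cols] / dt.max()
    elif method == "ray":
        if not mask.centroid_inside:
            raise CentroidOutsideError(
                "centroid outside mask; re-run with method='dt'")
        c = np.asarray(mask.centroid)
        p = _px_to_nm(np.column_stack([rows, cols]), s)
        vec = p - c
        dist = np.linalg.norm(vec, axis=1)
        nonzero = dist > 0
        rho = np.zeros(len(p))
        u = vec[nonzero] / dist[nonzero, None]
        r_out, multi = _ray_outline_distance(c, u, mask.outline)
        if multi:
            mask.star_shaped = False
            warnings.warn("outline not star-shaped from centroid; "
                          "first crossing used", stacklevel=2)
        rho[nonzero] = dist[nonzero] / r_out
        rho = np.clip(rho, 0.0, 1.0)
    else:
        raise ConfigurationError(f"unknown radial binning method {method!r}")
    rho_img[rows, cols] = rho
    bins = np.full(mask.mask.shape, -1, np.int64)
    bins[rows, cols] = np.minimum((rho * n_bins).astype(np.int64), n_bins - 1)
    return bins, rho_img


# ---------------------------------------------------------------------------
# Profiles
# ---------------------------------------------------------------------------

@dataclass
class RadialProfile:
    """50-ring normalized MFI profile of one cell (or a cohort average)."""

    n_bins: int
    mfi: np.ndarray            # per-bin mean intensity, AU
    normalized: np.ndarray     # per-bin MFI / innermost-ring MFI
    counts: np.ndarray         # pixels per bin
    sd: np.ndarray | None = None   # cohort profiles only
    n_cells: int = 1
    is_normalized: bool = True

    @property
    def radial_au(self) -> np.ndarray:
        """Ring centres on the 0-100 AU axis (50 rings -> 2 AU per step)."""
        return (np.arange(self.n_bins) + 0.5) * (100.0 / self.n_bins)

    def to_frames(self) -> dict[str, pd.DataFrame]:
        detail = pd.DataFrame({
            "bin": np.arange(self.n_bins), "radial_au": self.radial_au,
            "mfi": self.mfi, "normalized": self.normalized,
            "pixel_count": self.counts,
        })
        if self.sd is not None:
            detail["sd"] = self.sd
        summary = pd.DataFrame([{
            "n_bins": self.n_bins, "n_cells": self.n_cells,
            "periphery_to_center": centralization_summary(self),
        }])
        return {"profile": detail, "summary": summary}


def radial_profile(signal_image: ImageStack, mask: CellMask,
                   bins: np.ndarray, n_bins: int = 50,
                   normalize: str = "inner") -> RadialProfile:
    """Per-ring MFI of ``signal_image`` under the ring partition ``bins``.

    ``normalize='inner'`` divides by the innermost non-empty ring's MFI
    (the convention that pins the profile to 1.0 at the centre);
    ``normalize='adjacent'`` divides each ring by its inward neighbour.
    Empty rings are NaN.  A non-positive innermost MFI flags the profile
    as unnormalized instead of dividing.
    """
    img = signal_image.pixels
    if img.shape != mask.mask.shape:
        raise ConfigurationError("signal image and mask geometry differ")
    inside = bins >= 0
    counts = np.bincount(bins[inside], minlength=n_bins)[:n_bins]
    sums = np.bincount(bins[inside], weights=img[inside].astype(float),
                       minlength=n_bins)[:n_bins]
    with np.errstate(invalid="ignore", divide="ignore"):
        mfi = np.where(counts > 0, sums / np.maximum(counts, 1), np.nan)
    nonempty = np.flatnonzero(counts > 0)
    inner = mfi[nonempty[0]] if len(nonempty) else np.nan
    if normalize == "inner":
        if not inner > 0:
            warnings.warn("innermost-ring MFI <= 0; profile left unnormalized",
                          stacklevel=2)
            return RadialProfile(n_bins, mfi, mfi.copy(), counts,
                                 is_normalized=False)
        norm = mfi / inner
    elif normalize == "adjacent":
        norm = np.empty_like(mfi)
        norm[0] = 1.0
        norm[1:] = mfi[1:] / mfi[:-1]
    else:
        raise ConfigurationError(f"unknown normalization {normalize!r}")
    return RadialProfile(n_bins, mfi, norm, counts)


def profile_average(profiles: list[RadialProfile]) -> RadialProfile:
    """Per-ring mean and sample SD across cells (NaN rings skipped pairwise)."""
    if not profiles:
        raise ConfigurationError("profile_average needs at least one profile")
    n_bins = profiles[0].n_bins
    if any(p.n_bins != n_bins for p in profiles):
        raise ConfigurationError("profiles have differing n_bins")
    stack = np.vstack([p.normalized for p in profiles])
    with warnings.catch_warnings():
        warnings.simplefilter("ignore", RuntimeWarning)
        mean = np.nanmean(stack, axis=0)
        sd = np.nanstd(stack, axis=0, ddof=1) if len(profiles) > 1 \
            else np.full(n_bins, np.nan)
    counts = np.sum(np.vstack([p.counts for p in profiles]), axis=0)
    mfi = np.nanmean(np.vstack([p.mfi for p in profiles]), axis=0)
    return RadialProfile(n_bins, mfi, mean, counts, sd=sd,
                         n_cells=len(profiles))


def centralization_summary(profile: RadialProfile) -> float:
    """Periphery/centre ratio: mean of the outer 10% of rings over the mean
    of the inner 10% (NaN rings excluded)."""
    k = max(1, profile.n_bins // 10)
    inner = profile.normalized[:k]
    outer = profile.normalized[-k:]
    if np.all(np.isnan(inner)) or np.all(np.isnan(outer)):
        raise NanoscopeError("edge rings are all-NaN; ratio undefined")
    return float(np.nanmean(outer) / np.nanmean(inner))
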