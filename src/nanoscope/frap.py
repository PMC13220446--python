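"""FRAP quantification: mobile fractions and the restriction index.

Three ROIs are traced over time: the bleached centre of the cell, the
bleached periphery, and a non-bleached periphery reference that tracks
acquisition photobleaching.  Normalization (per bleached ROI):

1. subtract the reference trace pointwise,
2. subtract the first post-bleach value (so the curve starts at exactly 0),
3. divide by the pre-bleach mean of the result (so pre-bleach is exactly 1).

The mobile fraction (MF) is the normalized value at the recovery endpoint
(900 s by default); the restriction index is RI = MF(periphery)/MF(centre),
with RI < 1 indicating selectively restricted mobility at the centre.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit

from .io import ConfigurationError, NanoscopeError, ParseError


class DegenerateNormalizationError(NanoscopeError):
    """Pre-bleach mean after correction is not positive."""


# ---------------------------------------------------------------------------
# Series container
# ---------------------------------------------------------------------------

@dataclass
class FrapSeries:
    """Raw three-ROI FRAP traces.

    ``time`` is in seconds with the bleach at ``bleach_time``; samples
    before ``bleach_time`` are the pre-bleach phase (default acquisition:
    2 min pre-bleach then one sample every 20 s for 15 min).
    """

    time: np.ndarray
    center: np.ndarray            # bleached centre ROI
    periphery: np.ndarray         # bleached periphery ROI
    reference: np.ndarray         # non-bleached periphery ROI
    bleach_time: float = 0.0

    def __post_init__(self) -> None:
        self.time = np.asarray(self.time, float)
        for name in ("center", "periphery", "reference"):
            arr = np.asarray(getattr(self, name), float)
            if arr.shape != self.time.shape:
                raise ParseError(f"{name} trace length differs from time axis")
            if (arr < 0).any():
                raise ParseError(f"negative intensity in {name} trace")
            setattr(self, name, arr)
        if not np.all(np.diff(self.time) > 0):
            raise ParseError("time axis must be strictly increasing")
        if self.n_prebleach < 1 or len(self.time) - self.n_prebleach < 2:
            raise ParseError("need >= 1 pre-bleach and >= 2 post-bleach samples")

    @property
    def n_prebleach(self) -> int:
        return int(np.searchsorted(self.time, self.bleach_time))

    @property
    def first_post_index(self) -> int:
        return self.n_prebleach


def read_frap_traces(path) -> FrapSeries:
    """Read a ROI-trace CSV with columns time_s, center, periphery,
    reference and an optional bleach_time column (constant)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    needed = ["time_s", "center", "periphery", "reference"]
    missing = [c for c in needed if c not in cols]
    if missing:
        raise ConfigurationError(f"FRAP CSV lacks column(s) {missing}")
    bleach = float(df[cols["bleach_time"]].iloc[0]) if "bleach_time" in cols else 0.0
    return FrapSeries(df[cols["time_s"]].to_numpy(float),
                      df[cols["center"]].to_numpy(float),
                      df[cols["periphery"]].to_numpy(float),
                      df[cols["reference"]].to_numpy(float),
                      bleach_time=bleach)


# ---------------------------------------------------------------------------
# Normalization
# ---------------------------------------------------------------------------

@dataclass
class FrapResult:
    """Normalized recovery curves plus the MF / RI summary."""

    time: np.ndarray
    norm_center: np.ndarray
    norm_periphery: np.ndarray
    bleach_time: float
    first_post_index: int
    endpoint: float = 900.0
    mf_center: float = np.nan
    mf_periphery: float = np.nan
    ri: float = np.nan
    mode: str = "subtractive"

    def to_frames(self) -> dict[str, pd.DataFrame]:
        curves = pd.DataFrame({"time_s": self.time,
                               "norm_center": self.norm_center,
                               "norm_periphery": self.norm_periphery})
        summary = pd.DataFrame([{"mf_center": self.mf_center,
                                 "mf_periphery": self.mf_periphery,
                                 "ri": self.ri,
                                 "endpoint_s": self.endpoint,
                                 "mode": self.mode}])
        return {"curves": curves, "summary": summary}


def _moving_average(x: np.ndarray, win: int) -> np.ndarray:
    """Centered moving average with truncated windows at the edges."""
    if win <= 1:
        return np.asarray(x, float)
    n = len(x)
    half = win // 2
    csum = np.concatenate([[0.0], np.cumsum(x, dtype=float)])
    lo = np.maximum(np.arange(n) - half, 0)
    hi = np.minimum(np.arange(n) + half + 1, n)
    return (csum[hi] - csum[lo]) / (hi - lo)


def _normalize_one(trace: np.ndarray, reference: np.ndarray,
                   pre: slice, i0: int, mode: str) -> np.ndarray:
    if mode == "subtractive":
        f1 = trace - reference
    elif mode == "ratiometric":
        ref_pre = reference[pre].mean()
        if not ref_pre > 0 or (reference <= 0).any():
            raise DegenerateNormalizationError("non-positive reference trace")
        f1 = trace * ref_pre / reference
    else:
        raise ConfigurationError(f"unknown normalization mode {mode!r}")
    f2 = f1 - f1[i0]
    pre_mean = f2[pre].mean()
    if not pre_mean > 0:
        raise DegenerateNormalizationError(
            "corrected pre-bleach mean <= 0; check ROI traces")
    return f2 / pre_mean


def normalize_frap(series: FrapSeries, mode: str = "subtractive",
                   ref_smooth: int = 9) -> FrapResult:
    """Three-step normalization of both bleached ROIs.

    The default reference correction is subtractive; ``mode='ratiometric'``
    divides by the reference (rescaled to its pre-bleach mean) instead,
    which cancels multiplicative acquisition photobleaching exactly where
    the subtractive form leaves a small residual.

    The reference trace measures slow acquisition photobleaching, so it is
    smoothed with a centered ``ref_smooth``-sample moving average before
    being applied (default 9 samples = 3 min at the 20-s cadence); this
    keeps the reference's shot-to-shot noise from being injected into both
    bleached curves.  Pass ``ref_smooth=1`` to use the raw trace.
    """
    i0 = series.first_post_index
    pre = slice(0, series.n_prebleach)
    reference = _moving_average(series.reference, ref_smooth)
    curves = {}
    for name in ("center", "periphery"):
        trace = getattr(series, name)
        depth = 1.0 - trace[i0] / trace[pre].mean() if trace[pre].mean() > 0 else 1.0
        if depth < 0.10:
            warnings.warn(f"weak bleach in {name} ROI "
                          f"(depth {depth:.1%} of pre-bleach)", stacklevel=2)
        curves[name] = _normalize_one(trace, reference, pre, i0, mode)
    return FrapResult(time=series.time, norm_center=curves["center"],
                      norm_periphery=curves["periphery"],
                      bleach_time=series.bleach_time, first_post_index=i0,
                      mode=mode)


# ---------------------------------------------------------------------------
# Mobile fraction / restriction index
# ---------------------------------------------------------------------------

def mobile_fraction(time: np.ndarray, curve: np.ndarray,
                    first_post_index: int, endpoint: float = 900.0,
                    last_k: int = 1) -> float:
    """MF = normalized value at the last sample <= ``endpoint`` (optionally
    the mean of the last ``last_k`` such samples).  No extrapolation."""
    time = np.asarray(time, float)
    post_t = time[first_post_index:]
    eligible = np.flatnonzero(post_t <= endpoint)
    if len(eligible) == 0:
        raise ConfigurationError(
            f"endpoint {endpoint} s precedes the first post-bleach sample")
    last = eligible[-1] + 1
    k = min(last_k, last)
    return float(np.mean(curve[first_post_index:][last - k:last]))


def restriction_index(mf_periphery: float, mf_center: float) -> float:
    """RI = MF(periphery) / MF(centre); requires MF(centre) > 0."""
    if not mf_center > 0:
        raise NanoscopeError("RI undefined: MF(centre) must be > 0")
    return float(mf_periphery) / float(mf_center)


def analyze_frap(series: FrapSeries, endpoint: float = 900.0,
                 mode: str = "subtractive", last_k: int = 1,
                 ref_smooth: int = 9) -> FrapResult:
    """normalize -> MF per ROI -> RI, in one call."""
    res = normalize_frap(series, mode=mode, ref_smooth=ref_smooth)
    res.endpoint = endpoint
    res.mf_center = mobile_fraction(res.time, res.norm_center,
                                    res.first_post_index, endpoint, last_k)
    res.mf_periphery = mobile_fraction(res.time, res.norm_periphery,
                                       res.first_post_index, endpoint, last_k)
    res.ri = restriction_index(res.mf_periphery, res.mf_center)
    return res


# ---------------------------------------------------------------------------
# Recovery-curve fitting (for simulation validation)
# ---------------------------------------------------------------------------

def fit_recovery(time: np.ndarray, curve: np.ndarray,
                 first_post_index: int,
                 residual_threshold: float = 0.1) -> tuple[float, float, float, bool]:
    """Least-squares fit of A (1 - exp(-t/tau)) to the post-bleach samples.

    Times are taken relative to the first post-bleach sample.  Returns
    (A, tau, residual RMS, ok).  ``ok`` is False for a poor model fit:
    either the residual RMS exceeds ``residual_threshold``, or tau runs
    into its upper bound of 10x the post-bleach span (a curve that never
    saturates, e.g. a linear ramp, is not an exponential recovery).
    """
    t = np.asarray(time, float)[first_post_index:]
    y = np.asarray(curve, float)[first_post_index:]
    if len(t) < 5:
        raise ConfigurationError("fit_recovery needs >= 5 post-bleach samples")
    t = t - t[0]
    tau_max = 10.0 * float(t[-1])

    def model(tt, a, tau):
        return a * (1.0 - np.exp(-tt / tau))

    a0 = max(float(y[-1]), 1e-3)
    tau0 = max(float(t[-1]) / 3.0, 1e-3)
    try:
        popt, _ = curve_fit(model, t, y, p0=(a0, tau0),
                            bounds=((1e-12, 1e-12), (np.inf, tau_max)),
                            maxfev=10000)
    except RuntimeError as exc:
        raise NanoscopeError(
            f"recovery fit did not converge (initial guess A={a0:g}, "
            f"tau={tau0:g} s): {exc}") from exc
    rms = float(np.sqrt(np.mean((model(t, *popt) - y) ** 2)))
    ok = rms <= residual_threshold and popt[1] < 0.99 * tau_max
    return float(popt[0]), float(popt[1]), rms, ok
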