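"""Synthetic ground-truth generators for every pipeline input.

Each generator draws from a seeded NumPy Generator and returns both the
simulated input and a ground-truth record sufficient to score the
downstream estimators:

* ``simulate_localizations`` — a Thomas (Poisson-parent, Gaussian-offspring)
  cluster process over uniform background, with per-molecule blink runs of
  1-5 consecutive frames, Gaussian localization error and linear stage
  drift, emulating a dSTORM acquisition of receptor nanoclusters.
* ``simulate_synapse_image`` — a star-shaped cell footprint with a radially
  varying signal (flat / linear / centralized presets, optional central
  cluster and concentric rings) plus an actin channel for segmentation.
* ``simulate_frap`` — three-ROI FRAP traces with known bleach depth, mobile
  fraction, recovery time constant and acquisition photobleaching.
* ``simulate_flow_movie`` — movies of Gaussian features translating along a
  line at known speeds for kymograph velocimetry.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Callable, Sequence

import numpy as np

from .frap import FrapSeries
from .io import ConfigurationError, ImageStack, LocalizationTable, RoiPolygon


def _rng(seed: int) -> np.random.Generator:
    return np.random.default_rng(seed)


# ---------------------------------------------------------------------------
# Thomas-process localizations
# ---------------------------------------------------------------------------

@dataclass
class ThomasSpec:
    """Clustered-localization simulation parameters.

    Rates are per square micron; geometry in nm.  Each molecule emits a
    single blink run of consecutive frames (uniform length on
    [blink_min, blink_max]); every appearance is jittered by the
    localization error, whose sigma is the reported precision.
    """

    window_size: float = 9000.0          # nm, square field
    kappa_per_um2: float = 2.0           # parent (cluster) intensity
    mu: float = 30.0                     # mean offspring per parent
    sigma: float = 15.0                  # nm, offspring spread
    background_per_um2: float = 5.0      # background molecule intensity
    blink_min: int = 1
    blink_max: int = 5
    precision_nm: float = 10.0           # localization error sigma
    drift_nm_per_frame: tuple[float, float] = (0.0, 0.0)
    n_frames: int = 10000
    frame_rate: float = 10.0             # Hz
    seed: int = 0

    def __post_init__(self) -> None:
        if min(self.kappa_per_um2, self.mu, self.background_per_um2) < 0:
            raise ConfigurationError("rates must be >= 0")
        if self.sigma <= 0 or self.precision_nm <= 0:
            raise ConfigurationError("sigma and precision must be > 0")
        if not 1 <= self.blink_min <= self.blink_max <= self.n_frames:
            raise ConfigurationError("require 1 <= blink_min <= blink_max <= n_frames")


def simulate_localizations(spec: ThomasSpec) -> tuple[LocalizationTable, dict]:
    """Draw a blinking Thomas process and return (table, ground truth).

    Ground truth holds parent positions, the molecule table (with parent
    assignment, -1 = background), each localization's molecule id, and the
    injected per-frame drift trajectory.
    """
    rng = _rng(spec.seed)
    area_um2 = (spec.window_size / 1000.0) ** 2
    n_parents = rng.poisson(spec.kappa_per_um2 * area_um2)
    parents = rng.uniform(0, spec.window_size, size=(n_parents, 2))
    mol_xy = []
    mol_parent = []
    for pi in range(n_parents):
        k = rng.poisson(spec.mu)
        if k:
            mol_xy.append(parents[pi] + rng.normal(0, spec.sigma, size=(k, 2)))
            mol_parent.extend([pi] * k)
    n_bg = rng.poisson(spec.background_per_um2 * area_um2)
    if n_bg:
        mol_xy.append(rng.uniform(0, spec.window_size, size=(n_bg, 2)))
        mol_parent.extend([-1] * n_bg)
    mol_xy = np.vstack(mol_xy) if mol_xy else np.empty((0, 2))
    mol_parent = np.asarray(mol_parent, np.int64)
    n_mol = len(mol_xy)

    drift = np.asarray(spec.drift_nm_per_frame, float)
    frame_drift = np.arange(spec.n_frames)[:, None] * drift[None, :]

    xs, ys, frames, mol_ids = [], [], [], []
    if n_mol:
        runs = rng.integers(spec.blink_min, spec.blink_max + 1, size=n_mol)
        starts = rng.integers(0, spec.n_frames - runs + 1)
        for m in range(n_mol):
            fr = np.arange(starts[m], starts[m] + runs[m])
            jitter = rng.normal(0, spec.precision_nm, size=(runs[m], 2))
            pos = mol_xy[m][None, :] + jitter + frame_drift[fr]
            xs.append(pos[:, 0])
            ys.append(pos[:, 1])
            frames.append(fr)
            mol_ids.append(np.full(runs[m], m))
    if xs:
        x = np.concatenate(xs)
        y = np.concatenate(ys)
        fr = np.concatenate(frames)
        mid = np.concatenate(mol_ids)
        order = np.lexsort((x, fr))
        table = LocalizationTable.from_arrays(
            x[order], y[order], fr[order],
            precision=np.full(len(x), spec.precision_nm))
        mid = mid[order]
    else:
        table = LocalizationTable.empty()
        mid = np.empty(0, np.int64)
    truth = {
        "parents": parents,
        "molecules": mol_xy,
        "molecule_parent": mol_parent,
        "loc_molecule": mid,
        "drift_per_frame": frame_drift,
        "kappa_per_um2": spec.kappa_per_um2,
        "mu": spec.mu,
        "window": RoiPolygon(np.array([
            [0.0, 0.0], [spec.window_size, 0.0],
            [spec.window_size, spec.window_size], [0.0, spec.window_size]])),
    }
    return table, truth


# ---------------------------------------------------------------------------
# Synapse images
# ---------------------------------------------------------------------------

@dataclass
class SynapseImageSpec:
    """Star-shaped cell with a radially varying signal channel.

    ``profile`` presets: ``flat`` (g = 1), ``linear``
    (g = 1 - (1-contrast) rho) and ``centralized`` (raised cosine from 1 at
    the centre to ``contrast`` at the edge).  Optional central Gaussian
    cluster and concentric rings (rho fraction, amplitude, width) emulate
    receptor centralization and sarcomeric actin-ring patterns.
    """

    shape: tuple[int, int] = (160, 160)    # pixels (rows, cols)
    pixel_size: float = 100.0              # nm
    mean_radius_um: float = 6.0
    roughness: Sequence[tuple[int, float]] = ((5, 0.06), (8, 0.04))
    profile: str = "flat"
    contrast: float = 0.46                 # periphery / centre
    base_intensity: float = 100.0
    central_cluster: tuple[float, float] | None = None   # (amplitude, sigma/R)
    rings: Sequence[tuple[float, float, float]] = ()     # (rho, amplitude, width)
    noise_sd: float = 2.0
    poisson: bool = False
    seed: int = 0

    def __post_init__(self) -> None:
        if self.base_intensity <= 0:
            raise ConfigurationError("base_intensity must be > 0 (g(0) > 0)")
        if self.profile not in ("flat", "linear", "centralized"):
            raise ConfigurationError(f"unknown profile preset {self.profile!r}")


def _radial_function(spec: SynapseImageSpec) -> Callable[[np.ndarray], np.ndarray]:
    c = spec.contrast
    if spec.profile == "flat":
        return lambda rho: np.ones_like(rho)
    if spec.profile == "linear":
        return lambda rho: 1.0 - (1.0 - c) * rho
    return lambda rho: c + (1.0 - c) * (0.5 + 0.5 * np.cos(np.pi * rho))


def simulate_synapse_image(spec: SynapseImageSpec
                           ) -> tuple[ImageStack, ImageStack, dict]:
    """Render (signal image, actin image, ground truth).

    The outline is R(theta) = R0 (1 + sum_k a_k cos(k theta + phi_k)) with
    random phases; per-pixel rho = r / R(theta) uses the same
    outline-following convention as the radial-profiling stage.  The actin
    channel is a uniform fill with a brighter cortical rim.
    """
    rng = _rng(spec.seed)
    ny, nx = spec.shape
    s = spec.pixel_size
    r0 = spec.mean_radius_um * 1000.0
    phases = rng.uniform(0, 2 * np.pi, size=len(spec.roughness))
    cx, cy = nx * s / 2.0, ny * s / 2.0

    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    x = (jj + 0.5) * s - cx
    y = (ii + 0.5) * s - cy
    r = np.hypot(x, y)
    theta = np.arctan2(y, x)

    def outline_radius(th: np.ndarray) -> np.ndarray:
        out = np.ones_like(th)
        for (k, amp), ph in zip(spec.roughness, phases):
            out = out + amp * np.cos(k * th + ph)
        return r0 * out

    r_out = outline_radius(theta)
    rho = np.where(r_out > 0, r / r_out, np.inf)
    inside = rho <= 1.0

    g = _radial_function(spec)
    signal = np.zeros((ny, nx))
    signal[inside] = spec.base_intensity * g(rho[inside])
    if spec.central_cluster is not None:
        amp, sig_frac = spec.central_cluster
        signal[inside] += amp * np.exp(-r[inside] ** 2 /
                                       (2.0 * (sig_frac * r0) ** 2))
    for ring_rho, amp, width in spec.rings:
        signal[inside] += amp * np.exp(-(rho[inside] - ring_rho) ** 2 /
                                       (2.0 * width ** 2))
    actin = np.zeros((ny, nx))
    actin[inside] = spec.base_intensity
    actin[inside & (rho > 0.88)] = 1.6 * spec.base_intensity   # cortical rim
    if spec.poisson:
        signal = rng.poisson(np.clip(signal, 0, None)).astype(float)
        actin = rng.poisson(np.clip(actin, 0, None)).astype(float)
    if spec.noise_sd > 0:
        signal = signal + rng.normal(0, spec.noise_sd, signal.shape)
        actin = actin + rng.normal(0, spec.noise_sd, actin.shape)
    signal = np.clip(signal, 0, None)
    actin = np.clip(actin, 0, None)

    th_grid = np.linspace(0, 2 * np.pi, 720, endpoint=False)
    outline_poly = np.column_stack([
        cx + outline_radius(th_grid) * np.cos(th_grid),
        cy + outline_radius(th_grid) * np.sin(th_grid)])
    truth = {
        "centroid": (cx, cy),
        "outline": outline_poly,
        "mask": inside,
        "rho": np.where(inside, rho, np.nan),
        "g": g,
        "contrast": spec.contrast,
        "rings": tuple(spec.rings),
    }
    return (ImageStack(signal, s), ImageStack(actin, s), truth)


# ---------------------------------------------------------------------------
# FRAP recovery traces
# ---------------------------------------------------------------------------

@dataclass
class FrapSimSpec:
    """Three-ROI FRAP simulation (defaults follow the acquisition protocol:
    2 min pre-bleach, then one sample every 20 s for 15 min).

    Mobile fractions ``a_center`` / ``a_periphery`` and time constants are
    the ground truth; ``photobleach_per_frame`` applies a multiplicative
    e^(-lambda n) decay to all ROIs per acquired frame, which the
    subtractive reference correction compensates only approximately.
    """

    prebleach: float = 100.0
    reference_level: float = 100.0
    bleach_floor_frac: float = 0.10       # post-bleach floor / pre-bleach
    a_center: float = 0.66
    a_periphery: float = 0.80
    tau_center: float = 120.0             # s
    tau_periphery: float = 120.0
    photobleach_per_frame: float = 0.0    # lambda
    noise_sd_frac: float = 0.02           # of the pre-bleach level
    cadence: float = 20.0                 # s
    duration: float = 900.0               # s post-bleach
    prebleach_duration: float = 120.0     # s
    seed: int = 0

    def __post_init__(self) -> None:
        for a in (self.a_center, self.a_periphery):
            if not 0 <= a <= 1:
                raise ConfigurationError("mobile fractions must lie in [0, 1]")
        if min(self.tau_center, self.tau_periphery) <= 0:
            raise ConfigurationError("time constants must be > 0")
        if self.photobleach_per_frame < 0:
            raise ConfigurationError("photobleaching rate must be >= 0")


def simulate_frap(spec: FrapSimSpec) -> tuple[FrapSeries, dict]:
    """Closed-form recovery curves with noise; bleach at t = 0.

    Post-bleach (t >= 0): F(t) = [floor + A (1 - e^(-t/tau)) (F0 - floor)]
    * e^(-lambda n(t)); the reference decays as F_ref e^(-lambda n(t)).
    Ground truth includes the endpoint mobile fractions
    A (1 - e^(-T/tau)) and their ratio (the expected restriction index).
    """
    rng = _rng(spec.seed)
    t_pre = np.arange(-spec.prebleach_duration, 0, spec.cadence)
    t_post = np.arange(0, spec.duration + spec.cadence / 2, spec.cadence)
    time = np.concatenate([t_pre, t_post])
    n_acq = np.arange(len(time))
    decay = np.exp(-spec.photobleach_per_frame * n_acq)
    floor = spec.bleach_floor_frac * spec.prebleach
    post = time >= 0

    def trace(a: float, tau: float) -> np.ndarray:
        f = np.full_like(time, spec.prebleach)
        f[post] = floor + a * (1.0 - np.exp(-time[post] / tau)) * \
            (spec.prebleach - floor)
        return f * decay

    noise = spec.noise_sd_frac * spec.prebleach
    center = trace(spec.a_center, spec.tau_center)
    periph = trace(spec.a_periphery, spec.tau_periphery)
    ref = spec.reference_level * decay
    if noise > 0:
        center = center + rng.normal(0, noise, center.shape)
        periph = periph + rng.normal(0, noise, periph.shape)
        ref = ref + rng.normal(0, noise, ref.shape)
    series = FrapSeries(time, np.clip(center, 0, None),
                        np.clip(periph, 0, None), np.clip(ref, 0, None),
                        bleach_time=0.0)
    endpoint = t_post[-1]
    mf_c = spec.a_center * (1.0 - np.exp(-endpoint / spec.tau_center))
    mf_p = spec.a_periphery * (1.0 - np.exp(-endpoint / spec.tau_periphery))
    truth = {"mf_center": mf_c, "mf_periphery": mf_p,
             "ri": mf_p / mf_c if mf_c > 0 else np.nan,
             "a_center": spec.a_center, "a_periphery": spec.a_periphery,
             "tau_center": spec.tau_center, "tau_periphery": spec.tau_periphery,
             "endpoint": float(endpoint)}
    return series, truth


# ---------------------------------------------------------------------------
# Flow movies
# ---------------------------------------------------------------------------

@dataclass
class FlowMovieSpec:
    """Movie of Gaussian features translating along a horizontal line.

    Streaks are (origin fraction of the line, retrograde speed nm/s, width
    in pixels, contrast in intensity units); positive speed moves the
    feature toward the line's start (the cell centre).
    """

    shape: tuple[int, int] = (48, 256)     # pixels (rows, cols)
    pixel_size: float = 100.0              # nm
    frame_interval: float = 1.0            # s
    n_frames: int = 300
    streaks: Sequence[tuple[float, float, float, float]] = ((0.5, 10.0, 2.0, 5.0),)
    noise_sd: float = 1.0
    seed: int = 0

    def __post_init__(self) -> None:
        for origin, speed, width, contrast in self.streaks:
            if not np.isfinite(speed):
                raise ConfigurationError("streak speed must be finite")
            if contrast <= 0 or width <= 0:
                raise ConfigurationError("streak contrast and width must be > 0")


def simulate_flow_movie(spec: FlowMovieSpec) -> tuple[ImageStack, dict]:
    """Render the movie plus its kymograph line and streak ground truth.

    The reference line runs along the central row, oriented centre (left)
    to periphery (right); ground truth lists each streak's origin fraction
    and signed retrograde speed.
    """
    rng = _rng(spec.seed)
    ny, nx = spec.shape
    s = spec.pixel_size
    yc = ny // 2
    jj, ii = np.meshgrid(np.arange(nx), np.arange(ny))
    movie = np.zeros((spec.n_frames, ny, nx))
    for origin, speed, width, contrast in spec.streaks:
        x0 = origin * (nx - 1)
        for t in range(spec.n_frames):
            xt = x0 - speed * t * spec.frame_interval / s    # retrograde: -x
            movie[t] += contrast * np.exp(
                -((jj - xt) ** 2 + (ii - yc) ** 2) / (2.0 * width ** 2))
    if spec.noise_sd > 0:
        movie = movie + rng.normal(0, spec.noise_sd, movie.shape)
    line = np.array([[0.5 * s, (yc + 0.5) * s],
                     [(nx - 0.5) * s, (yc + 0.5) * s]])
    truth = {"line": line,
             "streaks": [{"origin_frac": o, "speed_nm_s": v,
                          "width_px": w, "contrast": c}
                         for o, v, w, c in spec.streaks]}
    return ImageStack(movie, s, spec.frame_interval), truth
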