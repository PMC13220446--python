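"""Input/output and core data containers.

All public coordinates are in nanometres, all times in seconds.  The image
coordinate convention is origin at the upper-left corner of the field with y
increasing downward; pixel ``(i, j)`` (row, column) covers the half-open
square ``[j*s, (j+1)*s) x [i*s, (i+1)*s)`` where ``s`` is the pixel size in
nm, so the centre of pixel ``(i, j)`` sits at ``((j+0.5)*s, (i+0.5)*s)``.
"""

from __future__ import annotations

import dataclasses
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import shapely
import tifffile
import yaml
from shapely.geometry import Polygon as _ShapelyPolygon


# ---------------------------------------------------------------------------
# Errors
# ---------------------------------------------------------------------------

class NanoscopeError(Exception):
    """Base class for all pipeline errors."""


class ConfigurationError(NanoscopeError):
    """Invalid parameter, missing column or missing metadata."""


class ParseError(NanoscopeError):
    """Malformed input data; carries the offending row where known."""


class NotEnoughDataError(NanoscopeError):
    """Input too small for the requested analysis."""


class UnsupportedFormatError(NanoscopeError):
    """Input file is readable but not a supported format (e.g. RGB TIFF)."""


# ---------------------------------------------------------------------------
# LocalizationTable
# ---------------------------------------------------------------------------

#: canonical column order of a localization table
LOC_COLUMNS = ("x", "y", "frame", "precision", "track_id", "intensity")

#: case-insensitive aliases used when reading CSV exports of common
#: localization software (thunderSTORM-style bracketed units, plain names).
COLUMN_ALIASES: dict[str, tuple[str, ...]] = {
    "x": ("x", "x [nm]", "x_nm", "x (nm)", "xnm", "x [px]", "x_px", "position_x"),
    "y": ("y", "y [nm]", "y_nm", "y (nm)", "ynm", "y [px]", "y_px", "position_y"),
    "frame": ("frame", "t", "frame_idx", "frame index", "time_frame"),
    "precision": ("precision", "uncertainty [nm]", "uncertainty_xy [nm]",
                  "uncertainty", "sigma [nm]", "loc_precision", "precision [nm]"),
    "track_id": ("track_id", "track", "id", "molecule_id"),
    "intensity": ("intensity", "intensity [photon]", "photons", "amplitude"),
}


@dataclass
class LocalizationTable:
    """Table of single-molecule detections.

    Columns: ``x``/``y`` in nm, ``frame`` (non-negative int), ``precision``
    in nm (NaN if unknown), ``track_id`` (-1 = unassigned) and ``intensity``
    (arbitrary units, NaN if unknown).
    """

    df: pd.DataFrame

    def __post_init__(self) -> None:
        df = self.df
        for col, default in (("precision", np.nan), ("track_id", -1),
                             ("intensity", np.nan)):
            if col not in df.columns:
                df[col] = default
        missing = [c for c in ("x", "y", "frame") if c not in df.columns]
        if missing:
            raise ConfigurationError(f"localization table lacks column(s) {missing}")
        df = df.loc[:, list(LOC_COLUMNS)].reset_index(drop=True)
        df["x"] = df["x"].astype(float)
        df["y"] = df["y"].astype(float)
        df["frame"] = df["frame"].astype(np.int64)
        df["precision"] = df["precision"].astype(float)
        df["track_id"] = df["track_id"].astype(np.int64)
        self.df = df
        self.validate()

    # -- invariants --------------------------------------------------------
    def validate(self) -> None:
        df = self.df
        if len(df) == 0:
            return
        if not (np.isfinite(df["x"]).all() and np.isfinite(df["y"]).all()):
            raise ParseError("non-finite coordinates in localization table")
        if (df["frame"] < 0).any():
            raise ParseError("negative frame index in localization table")
        prec = df["precision"].to_numpy()
        bad = ~np.isnan(prec) & (prec <= 0)
        if bad.any():
            raise ParseError(
                f"non-positive precision at row {int(np.flatnonzero(bad)[0])}")

    # -- convenience accessors --------------------------------------------
    def __len__(self) -> int:
        return len(self.df)

    @property
    def xy(self) -> np.ndarray:
        """(n, 2) array of coordinates in nm."""
        return self.df[["x", "y"]].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return self.df["frame"].to_numpy()

    @property
    def precision(self) -> np.ndarray:
        return self.df["precision"].to_numpy(float)

    @classmethod
    def from_arrays(cls, x, y, frame, precision=None, track_id=None,
                    intensity=None) -> "LocalizationTable":
        n = len(np.atleast_1d(x))
        data = {
            "x": np.asarray(x, float),
            "y": np.asarray(y, float),
            "frame": np.asarray(frame, np.int64),
            "precision": np.full(n, np.nan) if precision is None else np.asarray(precision, float),
            "track_id": np.full(n, -1, np.int64) if track_id is None else np.asarray(track_id, np.int64),
            "intensity": np.full(n, np.nan) if intensity is None else np.asarray(intensity, float),
        }
        return cls(pd.DataFrame(data))

    @classmethod
    def empty(cls) -> "LocalizationTable":
        return cls.from_arrays([], [], [])

    def sort(self) -> "LocalizationTable":
        """Deterministic (frame, x, y) sort; used to canonicalize ordering."""
        df = self.df.sort_values(["frame", "x", "y"], kind="mergesort")
        return LocalizationTable(df.reset_index(drop=True))


def _resolve_columns(header: Sequence[str],
                     column_map: Mapping[str, str] | None) -> dict[str, str]:
    """Map canonical names to actual CSV columns via explicit map or aliases."""
    norm = {str(h).strip().lower(): h for h in header}
    resolved: dict[str, str] = {}
    explicit = {k: v for k, v in (column_map or {}).items()}
    for canon in LOC_COLUMNS:
        if canon in explicit:
            target = explicit[canon]
            if target not in header:
                raise ConfigurationError(
                    f"mapped column {target!r} for {canon!r} not found in header {list(header)}")
            resolved[canon] = target
            continue
        for alias in COLUMN_ALIASES[canon]:
            if alias in norm:
                resolved[canon] = norm[alias]
                break
    for required in ("x", "y", "frame"):
        if required not in resolved:
            raise ConfigurationError(
                f"required column {required!r} not found in header {list(header)}; "
                "pass column_map to name it")
    return resolved


def read_localizations(path: str | Path,
                       column_map: Mapping[str, str] | None = None,
                       units: str = "nm",
                       pixel_size: float | None = None) -> LocalizationTable:
    """Read a localization CSV into a :class:`LocalizationTable`.

    Parameters
    ----------
    column_map
        Optional mapping from canonical names (``x``, ``y``, ``frame``,
        ``precision``, ``track_id``, ``intensity``) to the CSV's column
        names.  Unmapped canonical names fall back to built-in aliases.
    units
        ``"nm"`` (default) or ``"px"``.  Pixel units require ``pixel_size``
        (nm per pixel) and convert coordinates and precision to nm.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    raw = pd.read_csv(path)
    resolved = _resolve_columns(list(raw.columns), column_map)
    data = {}
    for canon, src in resolved.items():
        col = pd.to_numeric(raw[src], errors="coerce")
        bad = col.isna() & raw[src].notna()
        if bad.any():
            raise ParseError(
                f"non-numeric value in column {src!r} at row {int(bad.idxmax())}")
        data[canon] = col
    df = pd.DataFrame(data)
    if units == "px":
        if pixel_size is None or pixel_size <= 0:
            raise ConfigurationError("pixel units require a positive pixel_size")
        for c in ("x", "y", "precision"):
            if c in df:
                df[c] = df[c] * pixel_size
    elif units != "nm":
        raise ConfigurationError(f"unknown units {units!r}; use 'nm' or 'px'")
    if "frame" in df:
        df["frame"] = df["frame"].fillna(0)
    return LocalizationTable(df)


def write_localizations(locs: LocalizationTable, path: str | Path) -> None:
    locs.df.to_csv(path, index=False)


# ---------------------------------------------------------------------------
# ImageStack
# ---------------------------------------------------------------------------

@dataclass
class ImageStack:
    """A 2-D image or 3-D (time, y, x) movie with physical metadata."""

    pixels: np.ndarray
    pixel_size: float            # nm / pixel
    frame_interval: float | None = None   # seconds, movies only

    def __post_init__(self) -> None:
        self.pixels = np.asarray(self.pixels)
        if self.pixels.ndim not in (2, 3):
            raise UnsupportedFormatError(
                f"expected 2-D image or 3-D movie, got ndim={self.pixels.ndim}")
        if not self.pixel_size > 0:
            raise ConfigurationError("pixel_size must be > 0")
        if self.pixels.ndim == 3 and (self.frame_interval is None
                                      or not self.frame_interval > 0):
            raise ConfigurationError("movies require a positive frame_interval")

    @property
    def n_frames(self) -> int:
        return 1 if self.pixels.ndim == 2 else self.pixels.shape[0]

    def frame(self, i: int) -> np.ndarray:
        return self.pixels if self.pixels.ndim == 2 else self.pixels[i]


def read_stack(path: str | Path,
               pixel_size: float | None = None,
               frame_interval: float | None = None) -> ImageStack:
    """Read a grayscale TIFF (bit-exact) into an :class:`ImageStack`.

    Pixel size is taken from ImageJ/TIFF metadata when present, otherwise
    from the ``pixel_size`` argument; lacking both is a configuration error.
    """
    path = Path(path)
    with tifffile.TiffFile(path) as tf:
        page = tf.pages[0]
        if page.photometric in (tifffile.PHOTOMETRIC.RGB,
                                tifffile.PHOTOMETRIC.PALETTE):
            raise UnsupportedFormatError(f"{path.name}: RGB/palette TIFF not supported")
        pixels = tf.asarray()
        meta = tf.imagej_metadata or {}
        res = page.tags.get("XResolution")
        if pixel_size is None:
            if res is not None and meta.get("unit") in ("nm", "nanometer"):
                num, den = res.value
                if num:
                    pixel_size = den / num
            elif res is not None and meta.get("unit") in ("um", "micron", "micrometer", "µm"):
                num, den = res.value
                if num:
                    pixel_size = 1000.0 * den / num
        if frame_interval is None:
            fi = meta.get("finterval")
            frame_interval = float(fi) if fi else None
    if pixels.ndim == 3 and pixels.shape[0] == 1:
        pixels = pixels[0]
    if pixel_size is None:
        raise ConfigurationError(
            f"{path.name}: no pixel size in TIFF metadata; pass pixel_size=")
    if pixels.ndim == 3 and frame_interval is None:
        raise ConfigurationError(
            f"{path.name}: movie lacks frame interval; pass frame_interval=")
    return ImageStack(pixels, pixel_size, frame_interval)


def write_stack(stack: ImageStack, path: str | Path) -> None:
    meta = {"unit": "nm"}
    if stack.frame_interval is not None:
        meta["finterval"] = stack.frame_interval
    tifffile.imwrite(path, stack.pixels, imagej=stack.pixels.dtype != np.float64,
                     resolution=(1.0 / stack.pixel_size, 1.0 / stack.pixel_size),
                     metadata=meta)


# ---------------------------------------------------------------------------
# RoiPolygon
# ---------------------------------------------------------------------------

@dataclass
class RoiPolygon:
    """Closed, simple polygon in nm (vertex order free, not repeated)."""

    vertices: np.ndarray    # (n, 2)

    def __post_init__(self) -> None:
        v = np.asarray(self.vertices, float)
        if v.ndim != 2 or v.shape[1] != 2 or v.shape[0] < 3:
            raise ConfigurationError("ROI polygon needs >= 3 (x, y) vertices")
        # drop an explicit closing vertex
        if np.allclose(v[0], v[-1]):
            v = v[:-1]
        if v.shape[0] < 3:
            raise ConfigurationError("ROI polygon needs >= 3 distinct vertices")
        poly = _ShapelyPolygon(v)
        if not poly.is_simple or not poly.is_valid:
            raise ConfigurationError("ROI polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ConfigurationError("ROI polygon must enclose a positive area")
        self.vertices = v

    @property
    def shapely(self) -> _ShapelyPolygon:
        return _ShapelyPolygon(self.vertices)

    @property
    def area(self) -> float:
        return float(self.shapely.area)

    @property
    def bounds(self) -> tuple[float, float, float, float]:
        """(xmin, ymin, xmax, ymax) in nm."""
        return tuple(self.shapely.bounds)

    def contains_points(self, xy: np.ndarray) -> np.ndarray:
        pts = shapely.points(np.asarray(xy, float))
        return shapely.contains(self.shapely, pts)


def read_roi(path: str | Path) -> RoiPolygon:
    """Read an ROI vertex list CSV with columns x_nm, y_nm (aliases x, y)."""
    df = pd.read_csv(path)
    cols = {c.strip().lower(): c for c in df.columns}
    try:
        xc = cols.get("x_nm", cols.get("x"))
        yc = cols.get("y_nm", cols.get("y"))
        v = df[[xc, yc]].to_numpy(float)
    except (KeyError, ValueError, TypeError) as exc:
        raise ConfigurationError(f"ROI CSV must have x_nm,y_nm columns: {exc}") from exc
    return RoiPolygon(v)


def write_roi(roi: RoiPolygon, path: str | Path) -> None:
    pd.DataFrame(roi.vertices, columns=["x_nm", "y_nm"]).to_csv(path, index=False)


# ---------------------------------------------------------------------------
# AnalysisConfig
# ---------------------------------------------------------------------------

@dataclass
class AnalysisConfig:
    """All analysis parameters in one place.

    Defaults reproduce the dSTORM/TIRF/FRAP processing parameters used for
    the CD40 synapse study: DBSCAN eps 20 nm / minPts 5, 3000 nm grid
    sub-regions, Ripley r_max 2200 nm, 10 nm rendering lattice, drift
    correction on a 10 nm lattice with 200 s windows, track lengths 1-5
    frames, 50 radial bins, 900 s FRAP endpoint.
    """

    eps: float = 20.0              # nm, DBSCAN neighbourhood radius
    min_pts: int = 5               # DBSCAN core threshold (incl. the point)
    grid_size: float = 3000.0      # nm, sub-region edge
    ripley_rmax: float = 2200.0    # nm
    render_lattice: float = 10.0   # nm
    drift_pixel: float = 10.0      # nm, drift-correlation histogram bin
    drift_window: float = 200.0    # s
    track_len_min: int = 1
    track_len_max: int = 5
    radial_bins: int = 50
    frap_endpoint: float = 900.0   # s
    rng_seed: int = 0

    def __post_init__(self) -> None:
        positive = ("eps", "grid_size", "ripley_rmax", "render_lattice",
                    "drift_pixel", "drift_window", "frap_endpoint")
        for name in positive:
            if not getattr(self, name) > 0:
                raise ConfigurationError(f"{name} must be > 0")
        if self.min_pts < 1:
            raise ConfigurationError("min_pts must be >= 1")
        if self.track_len_min < 1 or self.track_len_min > self.track_len_max:
            raise ConfigurationError("require 1 <= track_len_min <= track_len_max")
        if self.radial_bins < 2:
            raise ConfigurationError("radial_bins must be >= 2")

    @classmethod
    def from_yaml(cls, path: str | Path, **overrides) -> "AnalysisConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        if not isinstance(data, dict):
            raise ConfigurationError(f"config file {path} must be a key-value mapping")
        known = {f.name for f in dataclasses.fields(cls)}
        unknown = set(data) - known
        if unknown:
            raise ConfigurationError(
                f"unknown config key(s) {sorted(unknown)}; valid keys: {sorted(known)}")
        data.update({k: v for k, v in overrides.items() if v is not None})
        return cls(**data)

    def to_yaml(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(dataclasses.asdict(self), fh, sort_keys=False)


# ---------------------------------------------------------------------------
# Reports
# ---------------------------------------------------------------------------

def write_report(report, path_prefix: str | Path) -> list[Path]:
    """Write any report object exposing ``to_frames()`` as flat CSV files.

    ``to_frames`` must return ``{name: DataFrame}``; each frame is written
    to ``<prefix>_<name>.csv`` with full float round-trip precision.
    Returns the written paths.
    """
    frames = report.to_frames() if hasattr(report, "to_frames") else dict(report)
    prefix = Path(path_prefix)
    prefix.parent.mkdir(parents=True, exist_ok=True)
    written = []
    for name, frame in frames.items():
        out = prefix.parent / f"{prefix.name}_{name}.csv"
        frame.to_csv(out, index=False)
        written.append(out)
    return written


def read_report(path_prefix: str | Path) -> dict[str, pd.DataFrame]:
    """Read back every ``<prefix>_<name>.csv`` written by :func:`write_report`."""
    prefix = Path(path_prefix)
    out = {}
    for p in sorted(prefix.parent.glob(f"{prefix.name}_*.csv")):
        out[p.stem[len(prefix.name) + 1:]] = pd.read_csv(p)
    if not out:
        raise FileNotFoundError(f"no report CSVs match {prefix}_*.csv")
    return out
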