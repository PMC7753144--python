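"""Localization tables: reading, writing, units, regions of interest, rendering.

The universal input of the pipeline is a table of single-molecule detections
("localizations"), one row per detection, with at least a frame index and a 2D
position.  Everything downstream — blink counting, precision estimation,
tracking — consumes this one container.

Conventions
-----------
* Coordinates are stored in **nanometres**, origin at the top-left corner of
  the field of view, x to the right, y downward.
* Frame indices are 0-based integers.
* Unit conversion (camera pixels to nm) happens once, at the I/O boundary.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace
from pathlib import Path

import numpy as np
import pandas as pd
from shapely import contains_xy
from shapely.geometry import Polygon

from .errors import DataError, FormatError, ParameterError, ParseError

#: Canonical column order on disk.  frame/x/y are mandatory, the rest optional.
CANONICAL_COLUMNS = ("frame", "x", "y", "precision", "intensity", "channel")

#: Header-name maps per dialect: canonical name -> on-disk name.
DIALECTS: dict[str, dict[str, str]] = {
    "generic_csv": {c: c for c in CANONICAL_COLUMNS},
    "thunderstorm_like": {
        "frame": "frame",
        "x": "x [nm]",
        "y": "y [nm]",
        "precision": "uncertainty [nm]",
        "intensity": "intensity [photon]",
        "channel": "channel",
    },
}

DEFAULT_PRECISION_NM = 10.0


@dataclass
class LocalizationTable:
    """Frame-indexed 2D detections plus the unit metadata needed downstream.

    Parameters
    ----------
    data:
        DataFrame with columns ``frame, x, y`` and optionally
        ``precision, intensity, channel``.  Positions in nm.
    pixel_size:
        Camera pixel size in nm (metadata; coordinates are already nm).
    frame_time:
        Acquisition time per frame in seconds.
    fov:
        Field-of-view ``(width, height)`` in nm, or None for unspecified.
    """

    data: pd.DataFrame
    pixel_size: float = 100.0
    frame_time: float = 0.02
    fov: tuple[float, float] | None = None

    def __post_init__(self) -> None:
        for col in ("frame", "x", "y"):
            if col not in self.data.columns:
                raise FormatError(f"localization table lacks mandatory column {col!r}")
        if self.pixel_size is not None and self.pixel_size <= 0:
            raise ParameterError("pixel_size must be > 0")
        if self.frame_time <= 0:
            raise ParameterError("frame_time must be > 0")
        self.data = self.data.reset_index(drop=True)
        frames = self.data["frame"].to_numpy()
        if len(frames) and frames.min() < 0:
            raise ParameterError("frame indices must be >= 0")
        if len(self.data):
            xy = self.data[["x", "y"]].to_numpy(float)
            if not np.isfinite(xy).all():
                raise ParameterError("x/y must be finite")
            if self.fov is not None:
                w, h = self.fov
                if xy[:, 0].max() > w or xy[:, 1].max() > h or xy.min() < 0:
                    raise ParameterError("coordinates outside declared field of view")

    def __len__(self) -> int:
        return len(self.data)

    @property
    def coords(self) -> np.ndarray:
        """(N, 2) array of x, y in nm."""
        return self.data[["x", "y"]].to_numpy(float)

    @property
    def frames(self) -> np.ndarray:
        return self.data["frame"].to_numpy(int)

    @property
    def n_frames(self) -> int:
        return int(self.frames.max()) + 1 if len(self.data) else 0

    def sorted_by_frame(self) -> "LocalizationTable":
        """Return a copy with rows sorted by frame (stable)."""
        return replace(self, data=self.data.sort_values("frame", kind="stable"))

    def select_channel(self, channel: int) -> "LocalizationTable":
        if "channel" not in self.data.columns:
            raise DataError("table has no channel column")
        return replace(self, data=self.data[self.data["channel"] == channel])

    def precisions(self, default: float | None = None) -> np.ndarray:
        """Per-record precision in nm, imputing missing values.

        Missing precisions are filled with `default` (typically a table-level
        NeNA estimate); if `default` is None the package default of
        10 nm is used.
        """
        fill = DEFAULT_PRECISION_NM if default is None else float(default)
        if "precision" in self.data.columns:
            return self.data["precision"].fillna(fill).to_numpy(float)
        return np.full(len(self.data), fill)


def read_localizations(
    path: str | Path,
    dialect: str = "generic_csv",
    units: str = "nm",
    pixel_size: float | None = None,
    frame_time: float = 0.02,
    fov: tuple[float, float] | None = None,
) -> LocalizationTable:
    """Read a localization CSV and return a table in canonical nm units.

    Parameters
    ----------
    dialect:
        ``"generic_csv"`` (columns named ``frame, x, y, ...``) or
        ``"thunderstorm_like"`` (``"x [nm]"``-style headers).
    units:
        ``"nm"`` if positions are already nm, ``"px"`` if in camera pixels
        (then `pixel_size` is mandatory and positions/precisions are scaled).
    """
    path = Path(path)
    if not path.exists():
        raise FormatError(f"no such file: {path}")
    if dialect not in DIALECTS:
        raise ParameterError(f"unknown dialect {dialect!r}; choose from {sorted(DIALECTS)}")
    if units not in ("nm", "px"):
        raise ParameterError("units must be 'nm' or 'px'")
    if units == "px" and (pixel_size is None or pixel_size <= 0):
        raise ParameterError("pixel_size (nm) must be supplied for pixel-unit input")

    raw = pd.read_csv(path, dtype=str)
    colmap = DIALECTS[dialect]
    present = {canon: disk for canon, disk in colmap.items() if disk in raw.columns}
    for mandatory in ("frame", "x", "y"):
        if mandatory not in present:
            raise FormatError(
                f"missing mandatory column {colmap[mandatory]!r} for dialect {dialect!r}"
            )

    data = pd.DataFrame()
    for canon, disk in present.items():
        numeric = pd.to_numeric(raw[disk], errors="coerce")
        bad = numeric.isna() & raw[disk].notna()
        if bad.any():
            row = int(bad.idxmax())
            raise ParseError(
                f"non-numeric value {raw[disk][row]!r} in column {disk!r}, row {row + 2}"
            )
        data[canon] = numeric

    data["frame"] = data["frame"].astype(int)
    scale = float(pixel_size) if units == "px" else 1.0
    for col in ("x", "y", "precision"):
        if col in data.columns:
            data[col] = data[col] * scale
    if "channel" in data.columns:
        data["channel"] = data["channel"].fillna(0).astype(int)

    table = LocalizationTable(
        data=data,
        pixel_size=float(pixel_size) if pixel_size else 100.0,
        frame_time=frame_time,
        fov=fov,
    )
    return table.sorted_by_frame()


def write_localizations(table: LocalizationTable, path: str | Path) -> None:
    """Write a table as generic CSV; round-trips coordinates to < 1e-6 nm."""
    path = Path(path)
    cols = [c for c in CANONICAL_COLUMNS if c in table.data.columns]
    try:
        table.data[cols].to_csv(path, index=False)
    except OSError as exc:  # pragma: no cover - depends on filesystem
        raise PermissionError(f"cannot write {path}: {exc}") from exc


@dataclass
class ROI:
    """A simple (non-self-intersecting) polygon region of interest, in nm."""

    vertices: np.ndarray  # (k, 2), nm
    label: str = ""

    def __post_init__(self) -> None:
        self.vertices = np.asarray(self.vertices, float)
        if self.vertices.ndim != 2 or self.vertices.shape[1] != 2 or len(self.vertices) < 3:
            raise ParameterError("ROI needs >= 3 (x, y) vertices")
        poly = Polygon(self.vertices)
        if not poly.is_valid:
            raise ParameterError("ROI polygon must be simple (non-self-intersecting)")
        if poly.area <= 0:
            raise ParameterError("ROI area must be > 0")

    @property
    def polygon(self) -> Polygon:
        return Polygon(self.vertices)

    @property
    def area_um2(self) -> float:
        """Polygon area in square micrometres."""
        return self.polygon.area / 1e6

    def contains(self, x: np.ndarray, y: np.ndarray) -> np.ndarray:
        """Vectorised point-in-polygon test for nm coordinates."""
        return contains_xy(self.polygon, np.asarray(x, float), np.asarray(y, float))

    @classmethod
    def rectangle(cls, width_nm: float, height_nm: float, label: str = "") -> "ROI":
        v = [(0, 0), (width_nm, 0), (width_nm, height_nm), (0, height_nm)]
        return cls(np.array(v, float), label=label)

    @classmethod
    def from_json(cls, path: str | Path) -> "ROI":
        with open(path) as fh:
            payload = json.load(fh)
        return cls(np.asarray(payload["vertices"], float), label=payload.get("label", ""))

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({"vertices": self.vertices.tolist(), "units": "nm", "label": self.label}, fh)


def render_image(
    table: LocalizationTable,
    bin_nm: float,
    mode: str = "histogram",
    default_precision: float = DEFAULT_PRECISION_NM,
) -> np.ndarray:
    """Render localizations onto a 2D grid.

    ``histogram`` mode counts localizations per bin (grid sum equals the
    number of records exactly).  ``gaussian`` mode spreads each record as a
    discretised 2D Gaussian of its own precision, normalised to unit integral
    over the grid.

    Returns the grid as float64, rows = y (down), cols = x (right).
    """
    if bin_nm <= 0:
        raise ParameterError("bin_nm must be > 0")
    if mode not in ("histogram", "gaussian"):
        raise ParameterError("mode must be 'histogram' or 'gaussian'")
    if table.fov is not None:
        w, h = table.fov
    elif len(table):
        w = float(table.data["x"].max()) + bin_nm
        h = float(table.data["y"].max()) + bin_nm
    else:
        w = h = bin_nm
    nx = max(1, int(np.ceil(w / bin_nm)))
    ny = max(1, int(np.ceil(h / bin_nm)))

    if mode == "histogram":
        if not len(table):
            return np.zeros((ny, nx))
        grid, _, _ = np.histogram2d(
            table.data["y"], table.data["x"],
            bins=(ny, nx), range=((0, ny * bin_nm), (0, nx * bin_nm)),
        )
        return grid

    grid = np.zeros((ny, nx))
    sigmas = table.precisions(default_precision)
    xs = table.data["x"].to_numpy(float)
    ys = table.data["y"].to_numpy(float)
    centers = (np.arange(max(nx, ny)) + 0.5) * bin_nm
    for x0, y0, sig in zip(xs, ys, sigmas):
        half = 4.0 * sig
        i0, i1 = int((y0 - half) // bin_nm), int((y0 + half) // bin_nm) + 1
        j0, j1 = int((x0 - half) // bin_nm), int((x0 + half) // bin_nm) + 1
        i0, i1 = max(i0, 0), min(i1, ny)
        j0, j1 = max(j0, 0), min(j1, nx)
        if i0 >= i1 or j0 >= j1:
            continue
        gy = np.exp(-((centers[i0:i1] - y0) ** 2) / (2 * sig**2))
        gx = np.exp(-((centers[j0:j1] - x0) ** 2) / (2 * sig**2))
        patch = np.outer(gy, gx)
        total = patch.sum()
        if total > 0:
            grid[i0:i1, j0:j1] += patch / total
    return grid


def save_image(grid: np.ndarray, path: str | Path) -> None:
    """Write a rendered grid as a 16-bit grayscale PNG (max scaled to 65535)."""
    import imageio.v3 as iio

    peak = float(grid.max()) if grid.size and grid.max() > 0 else 1.0
    img = np.clip(grid / peak * 65535.0, 0, 65535).astype(np.uint16)
    iio.imwrite(Path(path), img)
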