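"""Core raster data model: grids, multi-date scene stacks, label maps, samples.

All rasters in a run share one north-up, pixel-center, 0-based row/column
grid; the area of a pixel is ``pixel_size**2`` (0.0009 km^2 at 30 m).
Reflectance is stored as float with a boolean validity mask rather than a
numeric nodata sentinel, so index arithmetic never meets magic values.
"""

from __future__ import annotations

import dataclasses
import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd
import tifffile


class AlignmentError(ValueError):
    """Rasters do not share the same grid."""


class FormatError(ValueError):
    """File content violates the expected layout (e.g. band count != 4)."""


class SchemeError(ValueError):
    """A class label is not part of the declared class scheme."""


class CoverageError(ValueError):
    """A zone has no classified map to contribute to the mosaic."""


@dataclass(frozen=True)
class GeoGrid:
    """Regular north-up grid: shape, pixel size (m) and upper-left origin."""

    n_rows: int
    n_cols: int
    pixel_size: float = 30.0
    origin: tuple[float, float] = (0.0, 0.0)  # map x, y of the UL corner
    crs_tag: str = "local"

    def __post_init__(self) -> None:
        if self.n_rows < 1 or self.n_cols < 1:
            raise ValueError("grid must have at least one row and column")
        if self.pixel_size <= 0:
            raise ValueError("pixel_size must be positive")

    @property
    def shape(self) -> tuple[int, int]:
        return (self.n_rows, self.n_cols)

    @property
    def pixel_area_km2(self) -> float:
        return (self.pixel_size / 1000.0) ** 2

    def xy_to_rowcol(self, x: float, y: float) -> tuple[int, int]:
        """Containing-cell lookup (no interpolation); y decreases with row."""
        col = int(np.floor((x - self.origin[0]) / self.pixel_size))
        row = int(np.floor((self.origin[1] - y) / self.pixel_size))
        return row, col

    def contains_rowcol(self, row: int, col: int) -> bool:
        return 0 <= row < self.n_rows and 0 <= col < self.n_cols

    def same_as(self, other: "GeoGrid", tol: float = 1e-6) -> bool:
        return (
            self.shape == other.shape
            and abs(self.pixel_size - other.pixel_size) <= tol
            and abs(self.origin[0] - other.origin[0]) <= tol
            and abs(self.origin[1] - other.origin[1]) <= tol
        )


@dataclass
class SceneStack:
    """Co-registered multi-date 4-band (blue, green, red, NIR) reflectance cube.

    ``data`` has shape (n_dates, 4, n_rows, n_cols); ``mask`` is True where a
    pixel is invalid on a date (shape (n_dates, n_rows, n_cols)); masking a
    pixel masks all four bands of that date.
    """

    grid: GeoGrid
    dates: list[tuple[int, int, int]]
    data: np.ndarray
    mask: np.ndarray

    def __post_init__(self) -> None:
        d = np.asarray(self.data, dtype=np.float64)
        if d.ndim != 4 or d.shape[1] != 4:
            raise FormatError("scene data must be (n_dates, 4, n_rows, n_cols)")
        if d.shape[0] != len(self.dates):
            raise FormatError("date list does not match data planes")
        if d.shape[2:] != self.grid.shape:
            raise AlignmentError("scene data does not match grid shape")
        self.data = d
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.mask.shape != (d.shape[0], *self.grid.shape):
            raise AlignmentError("mask must be (n_dates, n_rows, n_cols)")

    @property
    def n_dates(self) -> int:
        return len(self.dates)

    def date_index(self, date: tuple[int, int, int]) -> int:
        try:
            return self.dates.index(tuple(date))
        except ValueError:
            raise KeyError(f"date {date} not in stack {self.dates}") from None

    def band(self, date: tuple[int, int, int], band: int) -> np.ndarray:
        """Band plane (1-based band number, B1..B4) for one date."""
        if band not in (1, 2, 3, 4):
            raise FormatError("band must be 1..4")
        return self.data[self.date_index(date), band - 1]

    def date_mask(self, date: tuple[int, int, int]) -> np.ndarray:
        return self.mask[self.date_index(date)]


@dataclass
class DEMRaster:
    grid: GeoGrid
    elevation: np.ndarray  # meters

    def __post_init__(self) -> None:
        self.elevation = np.asarray(self.elevation, dtype=np.float64)
        if self.elevation.shape != self.grid.shape:
            raise AlignmentError("DEM does not match grid shape")


@dataclass
class LabelRaster:
    """Per-pixel class codes; ``nodata`` marks unclassified pixels."""

    grid: GeoGrid
    labels: np.ndarray
    nodata: int = 0

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels, dtype=np.int32)
        if self.labels.shape != self.grid.shape:
            raise AlignmentError("labels do not match grid shape")

    def valid(self) -> np.ndarray:
        return self.labels != self.nodata


@dataclass
class ZoneMask:
    grid: GeoGrid
    zones: np.ndarray  # small integer zone ids, 0 = outside all zones

    def __post_init__(self) -> None:
        self.zones = np.asarray(self.zones, dtype=np.int32)
        if self.zones.shape != self.grid.shape:
            raise AlignmentError("zones do not match grid shape")

    def ids(self) -> list[int]:
        return sorted(int(z) for z in np.unique(self.zones) if z != 0)


@dataclass
class SampleSet:
    """Ground points: id, map x/y, class label, role (training|validation)."""

    frame: pd.DataFrame  # columns: id, x, y, label, role, in_extent

    REQUIRED = ("id", "x", "y", "label", "role")

    def __post_init__(self) -> None:
        missing = [c for c in self.REQUIRED if c not in self.frame.columns]
        if missing:
            raise FormatError(f"sample table missing columns: {missing}")
        if "in_extent" not in self.frame.columns:
            self.frame = self.frame.assign(in_extent=True)

    def subset(self, role: str) -> "SampleSet":
        return SampleSet(self.frame[self.frame["role"] == role].reset_index(drop=True))

    def in_extent(self) -> "SampleSet":
        return SampleSet(self.frame[self.frame["in_extent"]].reset_index(drop=True))

    def __len__(self) -> int:
        return len(self.frame)

    def rowcols(self, grid: GeoGrid) -> np.ndarray:
        rc = [grid.xy_to_rowcol(x, y) for x, y in zip(self.frame["x"], self.frame["y"])]
        return np.array(rc, dtype=np.int64).reshape(-1, 2)


# ---------------------------------------------------------------------------
# File I/O.  Rasters travel as plain TIFF with the grid serialized into the
# ImageDescription tag; samples as CSV (id,x,y,class,role).
# ---------------------------------------------------------------------------

def _grid_meta(grid: GeoGrid, extra: dict | None = None) -> str:
    meta = {
        "pixel_size": grid.pixel_size,
        "origin": list(grid.origin),
        "crs_tag": grid.crs_tag,
    }
    if extra:
        meta.update(extra)
    return json.dumps(meta)


def _parse_grid(shape: tuple[int, int], description: str | None) -> tuple[GeoGrid, dict]:
    meta: dict = {}
    if description:
        try:
            meta = json.loads(description)
        except (TypeError, json.JSONDecodeError):
            meta = {}
    grid = GeoGrid(
        n_rows=shape[0],
        n_cols=shape[1],
        pixel_size=float(meta.get("pixel_size", 30.0)),
        origin=tuple(meta.get("origin", (0.0, 0.0))),
        crs_tag=str(meta.get("crs_tag", "local")),
    )
    return grid, meta


def write_bands(path: str | Path, grid: GeoGrid, planes: np.ndarray,
                extra_meta: dict | None = None) -> None:
    """Write a (bands, rows, cols) or (rows, cols) float/int TIFF."""
    arr = np.asarray(planes)
    kwargs = {"photometric": "minisblack"} if arr.ndim == 3 else {}
    tifffile.imwrite(str(path), arr, description=_grid_meta(grid, extra_meta),
                     **kwargs)


def read_bands(path: str | Path) -> tuple[GeoGrid, np.ndarray, dict]:
    with tifffile.TiffFile(str(path)) as tif:
        arr = tif.asarray()
        desc = tif.pages[0].description
    shape = arr.shape[-2:]
    grid, meta = _parse_grid(shape, desc)
    return grid, arr, meta


def read_scene_stack(paths: Sequence[str | Path],
                     dates: Sequence[tuple[int, int, int]],
                     nodata_value: float = -9999.0) -> SceneStack:
    """Load one 4-band file per date into an aligned :class:`SceneStack`.

    Pixels equal to ``nodata_value`` (or non-finite) in any band are masked
    for all four bands of that date.
    """
    if len(paths) != len(dates):
        raise FormatError("one raster file per date required")
    planes = []
    masks = []
    grid0: GeoGrid | None = None
    for p in paths:
        grid, arr, _ = read_bands(p)
        if arr.ndim != 3 or arr.shape[0] != 4:
            raise FormatError(f"{p}: expected 4 bands, got shape {arr.shape}")
        if grid0 is None:
            grid0 = grid
        elif not grid.same_as(grid0):
            raise AlignmentError(f"{p}: grid differs from first raster")
        bad = ~np.isfinite(arr) | (arr == nodata_value)
        date_mask = bad.any(axis=0)
        arr = np.where(date_mask[None], 0.0, arr.astype(np.float64))
        planes.append(arr)
        masks.append(date_mask)
    assert grid0 is not None
    return SceneStack(
        grid=grid0,
        dates=[tuple(d) for d in dates],
        data=np.stack(planes),
        mask=np.stack(masks),
    )


def write_label_raster(path: str | Path, raster: LabelRaster) -> None:
    write_bands(path, raster.grid, raster.labels.astype(np.int32),
                extra_meta={"nodata": raster.nodata})


def read_label_raster(path: str | Path) -> LabelRaster:
    grid, arr, meta = read_bands(path)
    if arr.ndim != 2:
        raise FormatError("label raster must be single-band")
    return LabelRaster(grid=grid, labels=arr.astype(np.int32),
                       nodata=int(meta.get("nodata", 0)))


def load_samples(path: str | Path, grid: GeoGrid | None = None,
                 scheme: dict[str, int] | None = None) -> SampleSet:
    """Read a samples CSV (columns id,x,y,class,role).

    Unknown class labels (against ``scheme``, a name->code map) raise
    :class:`SchemeError`; points outside ``grid`` are flagged out-of-extent,
    never dropped.
    """
    df = pd.read_csv(path)
    cols = {c.lower(): c for c in df.columns}
    for required in ("id", "x", "y", "class", "role"):
        if required not in cols:
            raise FormatError(f"samples file missing column '{required}'")
    out = pd.DataFrame({
        "id": df[cols["id"]],
        "x": df[cols["x"]].astype(float),
        "y": df[cols["y"]].astype(float),
        "label": df[cols["class"]],
        "role": df[cols["role"]].astype(str),
    })
    if scheme is not None:
        unknown = sorted(set(out["label"].astype(str)) - set(scheme))
        if unknown:
            raise SchemeError(f"unknown class labels: {unknown}")
        out["label"] = [scheme[str(v)] for v in out["label"]]
    if grid is not None:
        flags = []
        for x, y in zip(out["x"], out["y"]):
            r, c = grid.xy_to_rowcol(x, y)
            flags.append(grid.contains_rowcol(r, c))
        out["in_extent"] = flags
    else:
        out["in_extent"] = True
    return SampleSet(out)


def write_samples(path: str | Path, samples: SampleSet,
                  scheme_names: dict[int, str] | None = None) -> None:
    df = samples.frame.copy()
    if scheme_names is not None:
        df["label"] = [scheme_names[int(v)] for v in df["label"]]
    df = df.rename(columns={"label": "class"})
    df[["id", "x", "y", "class", "role"]].to_csv(path, index=False)


def mosaic_zone_results(per_zone_maps: dict[int, LabelRaster],
                        zones: ZoneMask, nodata: int = 0) -> LabelRaster:
    """Compose one label map from independently classified zone maps.

    Every pixel takes its label from the map of its zone; pixels in no zone
    get ``nodata``.  A zone present in ``zones`` but missing from
    ``per_zone_maps`` is a :class:`CoverageError`.
    """
    missing = [z for z in zones.ids() if z not in per_zone_maps]
    if missing:
        raise CoverageError(f"no classified map supplied for zones {missing}")
    out = np.full(zones.grid.shape, nodata, dtype=np.int32)
    for zid in zones.ids():
        zmap = per_zone_maps[zid]
        if not zmap.grid.same_as(zones.grid):
            raise AlignmentError(f"zone {zid} map grid differs from master grid")
        sel = zones.zones == zid
        out[sel] = zmap.labels[sel]
    return LabelRaster(grid=zones.grid, labels=out, nodata=nodata)
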