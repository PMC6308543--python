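"""Cross-product map comparison: class remapping, forest-percentage grids,
difference maps and area summaries.

External categorical products are first remapped to a common scheme (binary
forest / non-forest, or forest subtypes), then aggregated to a coarse grid
whose cells hold the percentage of fine forest pixels (default block 50 =
1500 m at 30 m).  Differences between two percentage grids are binned into
10-point classes for frequency comparison.  The coarse grid is anchored at
the fine-grid origin; partial edge blocks keep their own valid-pixel count.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AlignmentError, GeoGrid, LabelRaster, ZoneMask


class RemapError(ValueError):
    """A source code has no entry in the remap table."""


@dataclass
class RemapTable:
    """Total mapping from a product's class codes to target codes."""

    mapping: dict[int, int]
    product: str = ""

    @classmethod
    def from_frame(cls, frame: pd.DataFrame, product: str | None = None) -> "RemapTable":
        """Build from a table with columns product, source_code, target_class."""
        if product is not None:
            frame = frame[frame["product"] == product]
        return cls({int(r.source_code): int(r.target_class) for r in frame.itertuples()},
                   product=product or "")


def remap(raster: LabelRaster, table: RemapTable) -> LabelRaster:
    """Relabel a categorical raster; unmapped codes are an error, not nodata."""
    codes = np.unique(raster.labels)
    unmapped = [int(c) for c in codes
                if c != raster.nodata and int(c) not in table.mapping]
    if unmapped:
        raise RemapError(f"codes without remap entry: {unmapped}")
    lut_size = int(codes.max()) + 1 if codes.size else 1
    lut = np.full(max(lut_size, raster.nodata + 1), raster.nodata, dtype=np.int32)
    for src, dst in table.mapping.items():
        if src < lut.size:
            lut[src] = dst
    out = np.where(raster.labels == raster.nodata, raster.nodata,
                   lut[np.clip(raster.labels, 0, lut.size - 1)])
    return LabelRaster(grid=raster.grid, labels=out, nodata=raster.nodata)


@dataclass
class PercentGrid:
    """Coarse grid of forest percentages (0..100) with valid-pixel counts."""

    block: int  # block size in fine pixels
    percent: np.ndarray  # NaN where a block has no valid pixel
    valid: np.ndarray  # valid fine pixels per block
    fine_grid: GeoGrid | None = None

    @property
    def shape(self) -> tuple[int, int]:
        return self.percent.shape


def aggregate_percentage(binary: LabelRaster, block: int = 50,
                         forest_code: int = 1) -> PercentGrid:
    """Percent of forest pixels per block of a binary forest map.

    Blocks are anchored at the raster origin; edge blocks normalize by
    their own valid-pixel count; blocks with no valid pixel are NaN.
    """
    if block < 1:
        raise ValueError("block must be >= 1")
    lab = binary.labels
    rows, cols = lab.shape
    nr = -(-rows // block)
    nc = -(-cols // block)
    pad_r, pad_c = nr * block - rows, nc * block - cols
    valid = (lab != binary.nodata).astype(np.int64)
    forest = (lab == forest_code).astype(np.int64)
    valid = np.pad(valid, ((0, pad_r), (0, pad_c)))
    forest = np.pad(forest, ((0, pad_r), (0, pad_c)))
    v = valid.reshape(nr, block, nc, block).sum(axis=(1, 3))
    f = forest.reshape(nr, block, nc, block).sum(axis=(1, 3))
    with np.errstate(invalid="ignore", divide="ignore"):
        pct = np.where(v > 0, 100.0 * f / np.maximum(v, 1), np.nan)
    return PercentGrid(block=block, percent=pct, valid=v, fine_grid=binary.grid)


def percent_difference(a: PercentGrid, b: PercentGrid,
                       bin_width: float = 10.0) -> tuple[np.ndarray, pd.DataFrame]:
    """Cellwise difference a - b (range -100..100) plus a bin histogram.

    Only cells valid in both grids count; the histogram covers
    [-100, 100] in ``bin_width`` steps (upper edge inclusive in the last
    bin) and sums to the number of jointly valid cells.
    """
    if a.shape != b.shape or a.block != b.block:
        raise AlignmentError("percentage grids do not share a coarse grid")
    d = a.percent - b.percent
    valid = np.isfinite(d)
    edges = np.arange(-100.0, 100.0 + bin_width, bin_width)
    counts, _ = np.histogram(d[valid], bins=edges)
    hist = pd.DataFrame({
        "low": edges[:-1], "high": edges[1:], "count": counts,
        "fraction": counts / max(valid.sum(), 1),
    })
    return d, hist


def fraction_in_range(diff: np.ndarray, low: float, high: float) -> float:
    """Fraction of valid difference cells with low <= d <= high."""
    valid = np.isfinite(diff)
    if not valid.any():
        return float("nan")
    sel = (diff >= low) & (diff <= high) & valid
    return float(sel.sum() / valid.sum())


def area_summary(label_map: LabelRaster, zones: ZoneMask | None = None,
                 pixel_area_km2: float | None = None) -> pd.DataFrame:
    """Per-zone, per-class areas (km^2) and class shares of total forest.

    Without a zone mask, a single zone 0 covers the map.  Shares are
    relative to the summed area of the forest subtype classes present.
    """
    from .scheme import FOREST_SUBTYPES, is_forest
    px = pixel_area_km2 if pixel_area_km2 is not None else label_map.grid.pixel_area_km2
    if zones is not None:
        if not zones.grid.same_as(label_map.grid):
            raise AlignmentError("zone mask grid differs from label map")
        zarr = zones.zones
    else:
        zarr = np.zeros(label_map.grid.shape, dtype=np.int32)
    rows = []
    for zid in np.unique(zarr):
        sel = zarr == zid
        labs, counts = np.unique(label_map.labels[sel], return_counts=True)
        for lab, cnt in zip(labs, counts):
            if lab == label_map.nodata:
                continue
            rows.append({"zone": int(zid), "class": int(lab),
                         "area_km2": float(cnt * px)})
    df = pd.DataFrame(rows)
    if df.empty:
        return df
    forest_total = df[df["class"].apply(is_forest)]["area_km2"].sum()
    df["share_of_forest"] = np.where(
        df["class"].apply(is_forest), df["area_km2"] / forest_total if forest_total else np.nan,
        np.nan)
    return df


def relative_difference(total_a: float, total_b: float) -> float:
    """Percent by which total_a exceeds total_b: 100 (a - b) / b, 1 dp."""
    if total_b == 0:
        raise ValueError("reference total must be nonzero")
    return round(100.0 * (total_a - total_b) / total_b, 1)
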