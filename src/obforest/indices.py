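"""Per-pixel spectral indices, the LBV transform, and per-object statistics.

Index definitions on the four CCD bands (B1 blue, B2 green, B3 red, B4 NIR):

    NDVI = (B4 - B3) / (B4 + B3)
    NDWI = (B2 - B4) / (B2 + B4)
    RVI  = B4 / B3
    EVI  = 2.5 (B4 - B3) / (B4 + 6 B3 - 7.5 B1 + 1)
    B3B1 = B3 / B1

Zero denominators are masked, never turned into infinities, so downstream
thresholding stays total.

The LBV transform maps the four bands to a radiance level L, a
visible-infrared balance B, and a band-to-band variation magnitude V.  The
original coefficient set is not fixed here; the default realises the same
qualitative decomposition (see :data:`DEFAULT_LBV`) and any 3x4 coefficient
matrix can be supplied instead.  V is reported as the Euclidean norm of the
successive band differences; forest canopies show a smoother band-to-band
profile (lower V) than herbaceous vegetation, which is what the classifier
exploits.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .grids import AlignmentError, DEMRaster, GeoGrid, SceneStack
from .segmentation import SegmentMap

INDEX_NAMES = ("NDVI", "NDWI", "RVI", "EVI", "B3B1", "L", "B", "V")

#: L = band mean; B = NIR minus visible mean (vis-IR balance).
DEFAULT_LBV = {
    "L": np.array([0.25, 0.25, 0.25, 0.25]),
    "B": np.array([-1 / 3, -1 / 3, -1 / 3, 1.0]),
}


@dataclass
class IndexRaster:
    grid: GeoGrid
    values: np.ndarray
    mask: np.ndarray  # True where undefined
    name: str
    date: tuple[int, int, int]

    def __post_init__(self) -> None:
        self.values = np.asarray(self.values, dtype=np.float64)
        self.mask = np.asarray(self.mask, dtype=bool)
        if self.values.shape != self.grid.shape or self.mask.shape != self.grid.shape:
            raise AlignmentError("index plane does not match grid shape")


def _ratio(num: np.ndarray, den: np.ndarray, base_mask: np.ndarray):
    mask = base_mask | (den == 0)
    safe = np.where(den == 0, 1.0, den)
    vals = np.where(mask, np.nan, num / safe)
    return vals, mask


def compute_index(stack: SceneStack, date: tuple[int, int, int], name: str) -> IndexRaster:
    """Compute one spectral index plane for one acquisition date."""
    name = name.upper()
    b1, b2, b3, b4 = (stack.band(date, i) for i in (1, 2, 3, 4))
    m = stack.date_mask(date)
    if name == "NDVI":
        vals, mask = _ratio(b4 - b3, b4 + b3, m)
    elif name == "NDWI":
        vals, mask = _ratio(b2 - b4, b2 + b4, m)
    elif name == "RVI":
        vals, mask = _ratio(b4, b3, m)
    elif name == "EVI":
        vals, mask = _ratio(2.5 * (b4 - b3), b4 + 6.0 * b3 - 7.5 * b1 + 1.0, m)
    elif name == "B3B1":
        vals, mask = _ratio(b3, b1, m)
    elif name in ("L", "B", "V"):
        return lbv_transform(stack, date)[("L", "B", "V").index(name)]
    else:
        raise ValueError(f"unknown index name {name!r}; expected one of {INDEX_NAMES}")
    return IndexRaster(stack.grid, vals, mask, name, tuple(date))


def lbv_transform(stack: SceneStack, date: tuple[int, int, int],
                  coefficients: dict[str, np.ndarray] | None = None,
                  ) -> tuple[IndexRaster, IndexRaster, IndexRaster]:
    """L, B, V planes for one date.

    L and B are linear in the bands with the coefficient rows of
    ``coefficients`` (defaults: :data:`DEFAULT_LBV`).  V is the magnitude of
    the spectral variation vector (B2-B1, B3-B2, B4-B3).
    """
    coefs = coefficients or DEFAULT_LBV
    bands = np.stack([stack.band(date, i) for i in (1, 2, 3, 4)])
    m = stack.date_mask(date)
    L = np.tensordot(np.asarray(coefs["L"], float), bands, axes=1)
    B = np.tensordot(np.asarray(coefs["B"], float), bands, axes=1)
    diffs = bands[1:] - bands[:-1]
    V = np.sqrt((diffs ** 2).sum(axis=0))
    date = tuple(date)
    return (
        IndexRaster(stack.grid, np.where(m, np.nan, L), m.copy(), "L", date),
        IndexRaster(stack.grid, np.where(m, np.nan, B), m.copy(), "B", date),
        IndexRaster(stack.grid, np.where(m, np.nan, V), m.copy(), "V", date),
    )


def object_stats(segments: SegmentMap,
                 rasters: dict[str, IndexRaster | np.ndarray],
                 dem: DEMRaster | None = None,
                 valid_counts: bool = False) -> pd.DataFrame:
    """Mean of each named plane over the unmasked pixels of every object.

    Returns a DataFrame indexed by object id with one column per feature,
    plus ``dem_mean`` (if a DEM is given) and ``n_pixels``.  A feature with
    no unmasked member pixels is NaN (flagged missing, not zero).  With
    ``valid_counts`` a ``<name>_n`` column reports how many unmasked pixels
    entered each mean.
    """
    labels = segments.labels
    ids = segments.object_ids()
    if not ids:
        return pd.DataFrame()
    # map arbitrary object ids to a dense range for bincount
    id_arr = np.asarray(ids, dtype=np.int64)
    dense = np.full(int(labels.max()) + 2, -1, dtype=np.int64)
    dense[id_arr] = np.arange(len(ids))
    inside = labels >= 0
    pos = dense[np.where(inside, labels, 0)]
    out = pd.DataFrame(index=pd.Index(ids, name="object_id"))
    counts = np.bincount(pos[inside], minlength=len(ids))
    out["n_pixels"] = counts
    for name, plane in rasters.items():
        if isinstance(plane, IndexRaster):
            if not plane.grid.same_as(segments.grid):
                raise AlignmentError(f"raster {name} grid differs from segments")
            vals, pmask = plane.values, plane.mask
        else:
            vals = np.asarray(plane, dtype=np.float64)
            if vals.shape != labels.shape:
                raise AlignmentError(f"raster {name} shape differs from segments")
            pmask = ~np.isfinite(vals)
        ok = inside & ~pmask
        n = np.bincount(pos[ok], minlength=len(ids))
        s = np.bincount(pos[ok], weights=vals[ok], minlength=len(ids))
        with np.errstate(invalid="ignore"):
            out[name] = np.where(n > 0, s / np.maximum(n, 1), np.nan)
        if valid_counts:
            out[f"{name}_n"] = n
    if dem is not None:
        if not dem.grid.same_as(segments.grid):
            raise AlignmentError("DEM grid differs from segments")
        s = np.bincount(pos[inside], weights=dem.elevation[inside], minlength=len(ids))
        out["dem_mean"] = np.where(counts > 0, s / np.maximum(counts, 1), np.nan)
    return out
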