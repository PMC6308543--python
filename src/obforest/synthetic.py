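"""Synthetic multi-date scene generation for end-to-end testing.

Emulates 30 m, 4-band surface reflectance over a patchy landscape with
class-specific seasonal trajectories: evergreen canopies keep a high NDVI
year-round, deciduous forest is leaf-off in early spring and peaks in
mid-summer, cropland greens up late and hard (high NIR, hence a large
band-variation V), water stays NDWI-positive, and shrubland shows an
elevated red/blue ratio with a depressed RVI.  Mixed forest and shrubland
patches are placed on low terrain so that the elevation rules of the
classifier are exercised rather than vacuous.

Noise is i.i.d. Gaussian per band, date and pixel, added to the class
monthly mean and clipped to [0, 1]; spatial autocorrelation of the noise is
deliberately absent.  Patches are axis-aligned rectangles stamped onto a
background class, sized to hit configured area fractions up to patch
quantization.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .grids import DEMRaster, GeoGrid, LabelRaster, SampleSet, SceneStack, ZoneMask
from .scheme import LandCover as LC

import pandas as pd


class SamplingError(ValueError):
    """Requested more sample points than a class has pixels."""


@dataclass(frozen=True)
class PhenologyProfile:
    """Monthly mean reflectance (B1..B4) and noise level for one class."""

    label: int
    monthly: dict[int, tuple[float, float, float, float]]
    noise_sd: float = 0.02

    def bands(self, month: int) -> tuple[float, float, float, float]:
        """Band means for a month; nearest defined month if not listed."""
        if month in self.monthly:
            return self.monthly[month]
        nearest = min(self.monthly, key=lambda m: (abs(m - month), m))
        return self.monthly[nearest]

    def ndvi(self, month: int) -> float:
        b1, b2, b3, b4 = self.bands(month)
        return (b4 - b3) / (b4 + b3)

    def ndwi(self, month: int) -> float:
        b1, b2, b3, b4 = self.bands(month)
        return (b2 - b4) / (b2 + b4)


def default_profiles() -> dict[int, PhenologyProfile]:
    """Seasonal band-mean tables for the eleven mapped classes.

    The trajectories realise the contrasts the decision tree relies on:
    early-spring NDVI splits evergreen from deciduous canopies, summer EVI
    orders needleleaf < mixed < broadleaf, forest V stays below herbaceous
    V, and shrubland sits apart on B3/B1 and RVI.
    """
    P = {
        LC.WATER: {m: (0.06, 0.08, 0.05, 0.02) for m in (4, 6, 7, 9)},
        LC.SETTLEMENTS: {m: (0.18, 0.20, 0.22, 0.24) for m in (4, 6, 7, 9)},
        LC.OTHER_LAND: {m: (0.10, 0.14, 0.18, 0.22) for m in (4, 6, 7, 9)},
        LC.CROPLAND: {
            4: (0.09, 0.11, 0.14, 0.17),
            6: (0.05, 0.08, 0.07, 0.30),
            7: (0.04, 0.07, 0.05, 0.50),
            9: (0.08, 0.10, 0.12, 0.20),
        },
        LC.GRASSLAND: {
            4: (0.06, 0.09, 0.09, 0.20),
            6: (0.05, 0.08, 0.07, 0.35),
            7: (0.05, 0.08, 0.06, 0.42),
            9: (0.06, 0.09, 0.09, 0.25),
        },
        LC.WETLAND: {
            4: (0.05, 0.10, 0.06, 0.12),
            6: (0.05, 0.09, 0.07, 0.30),
            7: (0.05, 0.09, 0.06, 0.44),
            9: (0.06, 0.10, 0.08, 0.22),
        },
        LC.EVERGREEN_NEEDLELEAF: {m: (0.03, 0.05, 0.04, 0.25) for m in (4, 6, 7, 9)},
        LC.DECIDUOUS_NEEDLELEAF: {
            4: (0.06, 0.08, 0.09, 0.12),
            6: (0.03, 0.06, 0.05, 0.26),
            7: (0.03, 0.06, 0.045, 0.29),
            9: (0.05, 0.07, 0.07, 0.20),
        },
        LC.DECIDUOUS_BROADLEAF: {
            4: (0.06, 0.08, 0.08, 0.11),
            6: (0.03, 0.07, 0.05, 0.32),
            7: (0.03, 0.07, 0.04, 0.36),
            9: (0.05, 0.08, 0.08, 0.24),
        },
        LC.MIXED_FOREST: {
            4: (0.045, 0.065, 0.06, 0.17),
            6: (0.04, 0.06, 0.05, 0.29),
            7: (0.04, 0.06, 0.05, 0.32),
            9: (0.05, 0.07, 0.07, 0.22),
        },
        LC.SHRUBLAND: {
            4: (0.07, 0.09, 0.12, 0.14),
            6: (0.04, 0.07, 0.08, 0.34),
            7: (0.04, 0.07, 0.08, 0.40),
            9: (0.05, 0.08, 0.09, 0.22),
        },
    }
    return {int(k): PhenologyProfile(int(k), v) for k, v in P.items()}


#: default per-class area fractions of the generated landscape
DEFAULT_FRACTIONS = {
    int(LC.WATER): 0.05,
    int(LC.SETTLEMENTS): 0.04,
    int(LC.OTHER_LAND): 0.04,
    int(LC.CROPLAND): 0.15,
    int(LC.GRASSLAND): 0.08,
    int(LC.WETLAND): 0.06,
    int(LC.EVERGREEN_NEEDLELEAF): 0.06,
    int(LC.DECIDUOUS_NEEDLELEAF): 0.12,
    int(LC.DECIDUOUS_BROADLEAF): 0.30,  # background class
    int(LC.MIXED_FOREST): 0.06,
    int(LC.SHRUBLAND): 0.04,
}

#: classes whose patches are constrained to low terrain (meters); the
#: elevation-limit rules of the classifier only bite if this structure exists
DEM_PLACEMENT_LIMITS = {
    int(LC.MIXED_FOREST): 650.0,
    int(LC.SHRUBLAND): 450.0,
}

DEFAULT_DATES = [(2010, 4, 15), (2010, 6, 15), (2010, 7, 15), (2010, 9, 15)]


@dataclass
class SceneConfig:
    """Geometry, dates, class mix, terrain and noise of a synthetic scene."""

    n_rows: int = 256
    n_cols: int = 256
    pixel_size: float = 30.0
    dates: list[tuple[int, int, int]] = field(default_factory=lambda: list(DEFAULT_DATES))
    class_fractions: dict[int, float] = field(default_factory=lambda: dict(DEFAULT_FRACTIONS))
    background_class: int = int(LC.DECIDUOUS_BROADLEAF)
    patch_range: tuple[int, int] = (16, 44)  # rectangle side lengths, pixels
    dem_base: float = 200.0
    dem_relief: float = 900.0  # east-west gradient amplitude
    dem_ripple: float = 60.0
    noise_sd: float = 0.02
    n_zones: int = 2
    seed: int = 0
    dem_placement_limits: dict[int, float] | None = None  # None -> module default

    def __post_init__(self) -> None:
        total = sum(self.class_fractions.values())
        if abs(total - 1.0) > 1e-6:
            raise ValueError(f"class fractions sum to {total}, expected 1")
        if len(self.dates) < 3:
            raise ValueError("at least three dates (spring to fall) required")
        if self.noise_sd < 0:
            raise ValueError("noise_sd must be nonnegative")


def _make_dem(cfg: SceneConfig) -> np.ndarray:
    r = np.arange(cfg.n_rows)[:, None]
    c = np.arange(cfg.n_cols)[None, :]
    elev = cfg.dem_base + cfg.dem_relief * (c / max(cfg.n_cols - 1, 1))
    elev = elev + cfg.dem_ripple * np.sin(2 * np.pi * r / max(cfg.n_rows, 1)) \
                * np.cos(2 * np.pi * c / max(cfg.n_cols, 1))
    return elev.astype(np.float64)


def _place_patches(cfg: SceneConfig, dem: np.ndarray,
                   rng: np.random.Generator) -> np.ndarray:
    rows, cols = cfg.n_rows, cfg.n_cols
    labels = np.full((rows, cols), cfg.background_class, dtype=np.int32)
    total = rows * cols
    lo, hi = cfg.patch_range
    limits = (cfg.dem_placement_limits if cfg.dem_placement_limits is not None
              else DEM_PLACEMENT_LIMITS)
    # terrain-constrained classes stamp first, while low ground is still free
    ordered = sorted(cfg.class_fractions.items(),
                     key=lambda kv: kv[0] not in limits)
    for cls, frac in ordered:
        if cls == cfg.background_class:
            continue
        target = int(round(frac * total))
        placed = 0
        limit = limits.get(cls)
        attempts = 0
        streak = 0  # rejections since the last successful stamp
        eff_hi = hi  # patch ceiling shrinks for good as the canvas crowds
        while placed < target and attempts < 50_000:
            attempts += 1
            if streak >= 150:
                eff_hi = max(4, eff_hi // 2)
                streak = 0
            eff_lo = min(lo, eff_hi)
            deficit = target - placed
            side = int(np.clip(np.sqrt(deficit), eff_lo, eff_hi))
            h = int(rng.integers(max(2, side // 2), side + 1))
            w = int(np.clip(deficit // max(h, 1), 2, eff_hi))
            if h > rows or w > cols:
                streak += 1
                continue
            r0 = int(rng.integers(0, rows - h + 1))
            c0 = int(rng.integers(0, cols - w + 1))
            block = labels[r0:r0 + h, c0:c0 + w]
            if not (block == cfg.background_class).all():
                streak += 1
                continue
            if limit is not None and dem[r0:r0 + h, c0:c0 + w].mean() >= limit:
                streak += 1
                continue
            block[:] = cls
            placed += h * w
            streak = 0
    return labels


def generate_scene(config: SceneConfig,
                   profiles: dict[int, PhenologyProfile] | None = None,
                   ) -> tuple[SceneStack, DEMRaster, LabelRaster, ZoneMask]:
    """Build a multi-date scene, DEM, truth labels and zone mask.

    Per-pixel reflectance is the class monthly mean plus Gaussian noise of
    ``config.noise_sd``, clipped to [0, 1].  The same seed reproduces the
    scene bit-for-bit.
    """
    profiles = profiles or default_profiles()
    rng = np.random.default_rng(config.seed)
    grid = GeoGrid(config.n_rows, config.n_cols, pixel_size=config.pixel_size)
    dem = _make_dem(config)
    labels = _place_patches(config, dem, rng)

    n_dates = len(config.dates)
    data = np.zeros((n_dates, 4, config.n_rows, config.n_cols))
    for d, date in enumerate(config.dates):
        month = date[1]
        for cls in np.unique(labels):
            prof = profiles[int(cls)]
            sel = labels == cls
            for b, mean in enumerate(prof.bands(month)):
                data[d, b][sel] = mean
    if config.noise_sd > 0:
        data = data + rng.normal(0.0, config.noise_sd, size=data.shape)
    data = np.clip(data, 0.0, 1.0)
    mask = np.zeros((n_dates, config.n_rows, config.n_cols), dtype=bool)

    stack = SceneStack(grid=grid, dates=list(config.dates), data=data, mask=mask)
    zones = np.ones((config.n_rows, config.n_cols), dtype=np.int32)
    if config.n_zones > 1:
        edges = np.linspace(0, config.n_cols, config.n_zones + 1).astype(int)
        for z in range(config.n_zones):
            zones[:, edges[z]:edges[z + 1]] = z + 1
    return (
        stack,
        DEMRaster(grid=grid, elevation=dem),
        LabelRaster(grid=grid, labels=labels, nodata=0),
        ZoneMask(grid=grid, zones=zones),
    )


def sample_points(truth: LabelRaster, n_per_class: dict[int, int], seed: int = 0,
                  train_fraction: float = 0.5) -> SampleSet:
    """Draw labelled points uniformly without replacement from truth pixels.

    Points sit at pixel centers; each class's draw is split into training
    and validation roles by ``train_fraction``.
    """
    rng = np.random.default_rng(seed)
    grid = truth.grid
    records = []
    pid = 0
    for cls, n in sorted(n_per_class.items()):
        pix = np.flatnonzero(truth.labels.ravel() == cls)
        if len(pix) < n:
            raise SamplingError(
                f"class {cls} has {len(pix)} pixels, cannot draw {n} points")
        chosen = rng.choice(pix, size=n, replace=False)
        n_train = int(round(n * train_fraction))
        for j, flat in enumerate(chosen):
            r, c = divmod(int(flat), grid.n_cols)
            x = grid.origin[0] + (c + 0.5) * grid.pixel_size
            y = grid.origin[1] - (r + 0.5) * grid.pixel_size
            records.append({
                "id": pid, "x": x, "y": y, "label": int(cls),
                "role": "training" if j < n_train else "validation",
                "in_extent": True,
            })
            pid += 1
    return SampleSet(pd.DataFrame.from_records(records))
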