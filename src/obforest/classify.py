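"""Hierarchical object-based decision-tree classification.

Level 1 (coarse objects): water by NDWI of an intermediate season; the rest
split into vegetation / non-vegetation by growing-season NDVI; vegetation
split into forest candidates (low band-variation V *and* high NDVI, as a
conjunction) versus the cropland/grassland/wetland pool; non-vegetation
split into settlements / other land with a 1-nearest-neighbour classifier
on standardized band means.

Level 2 (fine objects within the forest mask): early-spring NDVI separates
evergreen from deciduous canopies; summer EVI orders deciduous needleleaf <
mixed < broadleaf, with mixed forest additionally capped by a per-zone
elevation limit; shrubland is finally pulled out of the deciduous
broadleaf / mixed pool where the red/blue band ratio is high, RVI low and
the terrain low.

All thresholds are calibrated from training samples by exhaustive midpoint
search (`calibrate_threshold`) unless pinned in the configuration; every
calibrated value and rule firing count is reported.
"""

from __future__ import annotations

from dataclasses import dataclass, field, fields as dc_fields

import numpy as np
import pandas as pd

from .grids import (DEMRaster, LabelRaster, SampleSet, SceneStack, ZoneMask,
                    mosaic_zone_results)
from .indices import compute_index, lbv_transform, object_stats
from .scheme import (FOREST_SUBTYPES, NON_FOREST_VEGETATION, NON_VEGETATION,
                     LandCover as LC)
from .segmentation import (LEVEL1_PARAMS, LEVEL2_PARAMS, SegParams, segment,
                           segment_within_mask)

#: pool codes used between level-1 and the finer splits
POOL_NON_VEGETATION = -2
POOL_NON_FOREST_VEG = -3


class FeatureError(ValueError):
    """An object lacks a feature a rule needs."""


class TrainingError(ValueError):
    """A class required by a supervised split has no training records."""


class CalibrationError(ValueError):
    """Threshold calibration received an empty group."""


class ConfigError(ValueError):
    """Pipeline configuration is incomplete (e.g. no elevation limit for a zone)."""


# ---------------------------------------------------------------------------
# Threshold calibration
# ---------------------------------------------------------------------------

@dataclass(frozen=True)
class Calibration:
    """A calibrated scalar cut: value, direction and training error."""

    threshold: float
    direction: str  # ">=" classifies positive at or above the cut, "<" below
    error_rate: float
    margin: float
    degenerate: bool = False


def calibrate_threshold(positive, negative, direction: str | None = None) -> Calibration:
    """Best single cut separating two scalar training groups.

    Candidate cuts are the midpoints between adjacent distinct sorted
    values; the cut minimizing training misclassification wins, ties broken
    toward the larger margin (half the gap at the cut), then the lower cut.
    With ``direction`` fixed only that orientation is searched; otherwise
    both are tried and the better recorded.
    """
    pos = np.asarray(list(positive), dtype=float)
    neg = np.asarray(list(negative), dtype=float)
    if pos.size == 0 or neg.size == 0:
        raise CalibrationError("both calibration groups must be nonempty")
    allv = np.unique(np.concatenate([pos, neg]))
    total = pos.size + neg.size
    if allv.size == 1:
        return Calibration(float(allv[0]), direction or ">=", 0.5, 0.0, degenerate=True)
    cuts = (allv[:-1] + allv[1:]) / 2.0
    gaps = (allv[1:] - allv[:-1]) / 2.0
    directions = (direction,) if direction else (">=", "<")
    best: tuple | None = None
    for d in directions:
        for t, g in zip(cuts, gaps):
            if d == ">=":
                err = (np.count_nonzero(pos < t) + np.count_nonzero(neg >= t)) / total
            else:
                err = (np.count_nonzero(pos >= t) + np.count_nonzero(neg < t)) / total
            key = (err, -g, t)
            if best is None or key < best[0]:
                best = (key, t, d, err, g)
    _, t, d, err, g = best
    return Calibration(float(t), d, float(err), float(g))


def _passes(values: np.ndarray, cal_or_value, default_direction: str = ">="):
    if isinstance(cal_or_value, Calibration):
        t, d = cal_or_value.threshold, cal_or_value.direction
    else:
        t, d = float(cal_or_value), default_direction
    return values >= t if d == ">=" else values < t


# ---------------------------------------------------------------------------
# Rule set
# ---------------------------------------------------------------------------

@dataclass
class RuleSet:
    """Decision-tree thresholds (tree nodes a..l) and date roles.

    a ndwi_water, b ndvi_vegetation, c v_forest, d ndvi_forest,
    e spring_ndvi_evergreen, f summer_evi_needleleaf,
    g (summer_evi_mixed_low, summer_evi_mixed_high), h dem_mixed_limit per
    zone (m), i b3b1_shrub, j rvi_shrub, k dem_shrub_limit (m),
    l nn_max_distance (spare; accepted for completeness, not enforced).
    Thresholds may be plain floats (fixed) or :class:`Calibration` results.
    """

    ndwi_water: float | Calibration = 0.0
    ndvi_vegetation: float | Calibration = 0.3
    v_forest: float | Calibration = 0.35
    ndvi_forest: float | Calibration = 0.4
    spring_ndvi_evergreen: float | Calibration = 0.5
    summer_evi_needleleaf: float | Calibration = 0.48
    summer_evi_mixed: tuple[float, float] = (0.48, 0.55)
    dem_mixed_limit: dict[int, float] = field(default_factory=dict)
    b3b1_shrub: float | Calibration = 1.8
    rvi_shrub: float | Calibration = 6.0
    dem_shrub_limit: float | Calibration = 500.0
    nn_max_distance: float | None = None
    evergreen_broadleaf_enabled: bool = False

    def mixed_limit(self, zone: int) -> float:
        if zone not in self.dem_mixed_limit:
            raise ConfigError(f"no mixed-forest elevation limit configured for zone {zone}")
        return float(self.dem_mixed_limit[zone])


#: elevation limits of mixed forest in the three mountain systems (m)
MOUNTAIN_DEM_LIMITS = {"changbai": 1000.0, "zhangguangcai": 900.0, "xiaoxingan": 700.0}


def _require(objects: pd.DataFrame, columns: list[str]) -> None:
    for col in columns:
        if col not in objects.columns:
            raise FeatureError(f"objects table lacks feature '{col}'")
        bad = objects.index[objects[col].isna()]
        if len(bad):
            raise FeatureError(f"object {bad[0]} missing feature '{col}'")


# ---------------------------------------------------------------------------
# Level-1 split
# ---------------------------------------------------------------------------

def classify_level1(objects: pd.DataFrame, rules: RuleSet) -> pd.Series:
    """Water / non-vegetation pool / forest candidate / non-forest-veg pool.

    Expects columns ndwi_intermediate, ndvi_growing, v_growing.  Rule order
    matters: water wins outright, then the vegetation split, then the
    forest conjunction (V below cut *and* NDVI above cut).
    """
    _require(objects, ["ndwi_intermediate", "ndvi_growing", "v_growing"])
    ndwi = objects["ndwi_intermediate"].to_numpy()
    ndvi = objects["ndvi_growing"].to_numpy()
    v = objects["v_growing"].to_numpy()
    out = np.full(len(objects), POOL_NON_FOREST_VEG, dtype=np.int64)
    water = _passes(ndwi, rules.ndwi_water, ">=")
    nonveg = ~water & ~_passes(ndvi, rules.ndvi_vegetation, ">=")
    forest = (~water & ~nonveg
              & _passes(v, rules.v_forest, "<")
              & _passes(ndvi, rules.ndvi_forest, ">="))
    out[water] = int(LC.WATER)
    out[nonveg] = POOL_NON_VEGETATION
    out[forest] = int(LC.FOREST)
    return pd.Series(out, index=objects.index, name="level1")


def nn_classify(objects: pd.DataFrame, training: pd.DataFrame,
                feature_columns: list[str], label_column: str = "label") -> pd.Series:
    """1-nearest-neighbour on z-standardized features.

    Standardization is fit on the training records (zero-variance features
    pass through unscaled); exact distance ties resolve to the smaller
    class code.  Every class named in training must have >= 1 record.
    """
    if training.empty:
        raise TrainingError("no training records for nearest-neighbour split")
    _require(objects, feature_columns)
    _require(training, feature_columns)
    X = training[feature_columns].to_numpy(float)
    y = training[label_column].to_numpy()
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Xs = (X - mu) / sd
    Q = (objects[feature_columns].to_numpy(float) - mu) / sd
    d2 = ((Q[:, None, :] - Xs[None, :, :]) ** 2).sum(axis=2)
    out = np.empty(len(objects), dtype=np.int64)
    for i in range(len(objects)):
        dmin = d2[i].min()
        out[i] = int(min(y[np.isclose(d2[i], dmin, rtol=0, atol=1e-12)]))
    return pd.Series(out, index=objects.index, name="nn_class")


# ---------------------------------------------------------------------------
# Level-2 forest subtypes
# ---------------------------------------------------------------------------

def classify_forest_types(objects: pd.DataFrame, rules: RuleSet,
                          zone: int) -> pd.Series:
    """Forest subtype per fine-level object within one mapping zone.

    Expects columns spring_ndvi, summer_evi, dem_mean.  Evergreen wins on
    early-spring NDVI; the deciduous pool splits on summer EVI with the
    mixed-forest branch additionally capped at the zone's elevation limit.
    """
    _require(objects, ["spring_ndvi", "summer_evi", "dem_mean"])
    h = rules.mixed_limit(zone)
    spring = objects["spring_ndvi"].to_numpy()
    evi = objects["summer_evi"].to_numpy()
    dem = objects["dem_mean"].to_numpy()
    g_low, g_high = _mixed_band(rules)
    evergreen_code = (int(LC.EVERGREEN_BROADLEAF) if rules.evergreen_broadleaf_enabled
                      else int(LC.EVERGREEN_NEEDLELEAF))
    out = np.full(len(objects), int(LC.DECIDUOUS_BROADLEAF), dtype=np.int64)
    evergreen = _passes(spring, rules.spring_ndvi_evergreen, ">=")
    needle = ~evergreen & _passes(evi, rules.summer_evi_needleleaf, "<")
    mixed = (~evergreen & ~needle
             & (evi >= g_low) & (evi <= g_high) & (dem < h))
    out[evergreen] = evergreen_code
    out[needle] = int(LC.DECIDUOUS_NEEDLELEAF)
    out[mixed] = int(LC.MIXED_FOREST)
    return pd.Series(out, index=objects.index, name="forest_type")


def _mixed_band(rules: RuleSet) -> tuple[float, float]:
    lo, hi = rules.summer_evi_mixed
    lo = lo.threshold if isinstance(lo, Calibration) else float(lo)
    hi = hi.threshold if isinstance(hi, Calibration) else float(hi)
    return lo, hi


def extract_shrubland(objects: pd.DataFrame, labels: pd.Series,
                      rules: RuleSet) -> pd.Series:
    """Reassign deciduous-broadleaf / mixed objects to shrubland.

    An object moves iff its red/blue ratio is at or above the shrub cut,
    its RVI below the shrub cut and its mean elevation below the shrub
    elevation limit; everything else is untouched.
    """
    candidates = labels.isin([int(LC.DECIDUOUS_BROADLEAF), int(LC.MIXED_FOREST)])
    if not candidates.any():
        return labels.copy()
    sub = objects.loc[labels.index[candidates]]
    _require(sub, ["b3b1_summer", "rvi_summer", "dem_mean"])
    hit = (
        _passes(sub["b3b1_summer"].to_numpy(), rules.b3b1_shrub, ">=")
        & _passes(sub["rvi_summer"].to_numpy(), rules.rvi_shrub, "<")
        & _passes(sub["dem_mean"].to_numpy(), rules.dem_shrub_limit, "<")
    )
    out = labels.copy()
    out.loc[sub.index[hit]] = int(LC.SHRUBLAND)
    return out


# ---------------------------------------------------------------------------
# Full pipeline
# ---------------------------------------------------------------------------

@dataclass
class PipelineConfig:
    """Date roles, segmentation parameters and threshold overrides.

    ``plane_scale`` multiplies reflectance before segmentation so that the
    color heterogeneity is commensurate with the published scale thresholds
    (which assume DN-like units); 100 maps reflectance [0, 1] to [0, 100].
    Date roles are indices into the stack's date list.
    """

    early_spring_date: int = 0
    intermediate_date: int = 1
    summer_date: int = 2
    growing_date: int = 2
    level1: SegParams = field(default_factory=lambda: LEVEL1_PARAMS)
    level2: SegParams = field(default_factory=lambda: LEVEL2_PARAMS)
    plane_scale: float = 100.0
    segmentation_dates: tuple[int, ...] | None = None  # None -> all dates
    dem_mixed_limit: dict[int, float] = field(default_factory=dict)
    fixed_thresholds: dict[str, float] = field(default_factory=dict)
    seed: int = 0


def _date(stack: SceneStack, idx: int) -> tuple[int, int, int]:
    if not 0 <= idx < stack.n_dates:
        raise ConfigError(f"date role index {idx} outside stack of {stack.n_dates} dates")
    return stack.dates[idx]


def _object_of_points(level_labels: np.ndarray, samples: SampleSet,
                      grid) -> pd.DataFrame:
    """Map sample points to the object id containing them (-1 = background)."""
    rc = samples.rowcols(grid)
    frame = samples.frame.copy()
    frame["object_id"] = [
        int(level_labels[r, c]) if 0 <= r < grid.n_rows and 0 <= c < grid.n_cols else -1
        for r, c in rc
    ]
    return frame


def _training_features(point_frame: pd.DataFrame, objects: pd.DataFrame) -> pd.DataFrame:
    ok = point_frame["object_id"].isin(objects.index)
    merged = point_frame[ok].join(objects, on="object_id")
    return merged


def _calibrate(name: str, cfg: PipelineConfig, pos, neg, direction: str,
               report: dict) -> float | Calibration:
    if name in cfg.fixed_thresholds:
        report["thresholds"][name] = {"value": cfg.fixed_thresholds[name], "fixed": True}
        return cfg.fixed_thresholds[name]
    pos = np.asarray(pos, float)
    neg = np.asarray(neg, float)
    pos = pos[np.isfinite(pos)]
    neg = neg[np.isfinite(neg)]
    cal = calibrate_threshold(pos, neg, direction=direction)
    report["thresholds"][name] = {
        "value": cal.threshold, "direction": cal.direction,
        "training_error": cal.error_rate, "margin": cal.margin,
        "degenerate": cal.degenerate, "n_pos": int(pos.size), "n_neg": int(neg.size),
    }
    return cal


def run_pipeline(stack: SceneStack, dem: DEMRaster, zones: ZoneMask,
                 samples: SampleSet, config: PipelineConfig | None = None,
                 ) -> tuple[LabelRaster, dict]:
    """Segment, calibrate, classify and mosaic a full multi-zone scene.

    Thresholds are calibrated once from the pooled training samples of all
    zones; segmentation and classification then run per zone and the zone
    maps are mosaicked.  Returns the final label raster and a run report
    (calibrated thresholds, object counts, class areas in km^2).
    """
    cfg = config or PipelineConfig()
    report: dict = {"thresholds": {}, "zones": {}, "class_area_km2": {}}
    grid = stack.grid
    training = samples.subset("training").in_extent()
    if training.frame.empty:
        raise TrainingError("no in-extent training samples")

    d_spring = _date(stack, cfg.early_spring_date)
    d_inter = _date(stack, cfg.intermediate_date)
    d_summer = _date(stack, cfg.summer_date)
    d_grow = _date(stack, cfg.growing_date)

    # segmentation planes: bands of the configured dates, DN-like scale
    seg_dates = cfg.segmentation_dates or tuple(range(stack.n_dates))
    planes = np.concatenate([
        np.stack([stack.band(_date(stack, di), b) for b in (1, 2, 3, 4)])
        for di in dict.fromkeys(seg_dates)
    ]) * cfg.plane_scale
    nodata = stack.date_mask(d_grow)
    idx_planes: dict[str, np.ndarray] = {
        "ndwi_intermediate": compute_index(stack, d_inter, "NDWI").values,
        "ndvi_growing": compute_index(stack, d_grow, "NDVI").values,
        "v_growing": lbv_transform(stack, d_grow)[2].values,
        "spring_ndvi": compute_index(stack, d_spring, "NDVI").values,
        "summer_evi": compute_index(stack, d_summer, "EVI").values,
    }
    for di, date in enumerate(stack.dates):
        idx_planes[f"ndvi_d{di}"] = compute_index(stack, date, "NDVI").values
        idx_planes[f"ndwi_d{di}"] = compute_index(stack, date, "NDWI").values
        for b in (1, 2, 3, 4):
            idx_planes[f"b{b}_d{di}"] = stack.band(date, b)

    def add_ratio_features(f: pd.DataFrame) -> pd.DataFrame:
        # band ratios from object mean reflectance (stable where a pixel
        # reciprocal would explode near zero)
        if f.empty:
            return f
        si = cfg.summer_date
        b1 = f[f"b1_d{si}"].replace(0, np.nan)
        b3 = f[f"b3_d{si}"].replace(0, np.nan)
        f = f.copy()
        f["rvi_summer"] = f[f"b4_d{si}"] / b3
        f["b3b1_summer"] = f[f"b3_d{si}"] / b1
        return f

    band_cols = [f"b{b}_d{di}" for di in range(stack.n_dates) for b in (1, 2, 3, 4)]
    veg_cols = [f"ndvi_d{di}" for di in range(stack.n_dates)] + \
               [f"ndwi_d{di}" for di in range(stack.n_dates)]

    # --- per-zone level-1 segmentation and object features ---------------
    zone_ids = zones.ids()
    seg1: dict[int, object] = {}
    feats1: dict[int, pd.DataFrame] = {}
    train_frames = []
    for zid in zone_ids:
        zmask = (zones.zones == zid) & ~nodata
        sm = segment(planes, cfg.level1, seed=cfg.seed + zid, grid=grid, mask=zmask)
        seg1[zid] = sm
        f = add_ratio_features(object_stats(sm, idx_planes, dem))
        feats1[zid] = f
        pts = _object_of_points(sm.labels, training, grid)
        tf = _training_features(pts, f)
        tf["zone"] = zid
        train_frames.append(tf)
        report["zones"][zid] = {"level1_objects": sm.n_objects}
    train1 = pd.concat(train_frames, ignore_index=True)
    if train1.empty:
        raise TrainingError("no training sample falls inside a segmented object")

    lbl = train1["label"].astype(int)
    forest_set = {int(c) for c in FOREST_SUBTYPES} | {int(LC.FOREST)}
    veg_set = forest_set | {int(c) for c in NON_FOREST_VEGETATION}
    is_water = lbl == int(LC.WATER)
    is_nonveg = lbl.isin([int(c) for c in NON_VEGETATION])
    is_forest = lbl.isin(sorted(forest_set))
    is_nfveg = lbl.isin([int(c) for c in NON_FOREST_VEGETATION])

    rules = RuleSet(dem_mixed_limit=dict(cfg.dem_mixed_limit))
    if not rules.dem_mixed_limit:
        defaults = list(MOUNTAIN_DEM_LIMITS.values())
        rules.dem_mixed_limit = {z: defaults[i % len(defaults)]
                                 for i, z in enumerate(zone_ids)}

    def col(mask, name):
        return train1.loc[mask, name].to_numpy(float)

    if not is_water.any():
        raise TrainingError("no water training samples for NDWI calibration")
    rules.ndwi_water = _calibrate(
        "ndwi_water", cfg, col(is_water, "ndwi_intermediate"),
        col(~is_water, "ndwi_intermediate"), ">=", report)
    veg_mask = lbl.isin(sorted(veg_set))
    rules.ndvi_vegetation = _calibrate(
        "ndvi_vegetation", cfg, col(veg_mask, "ndvi_growing"),
        col(is_nonveg, "ndvi_growing"), ">=", report)
    rules.v_forest = _calibrate(
        "v_forest", cfg, col(is_forest, "v_growing"),
        col(is_nfveg, "v_growing"), "<", report)
    rules.ndvi_forest = _calibrate(
        "ndvi_forest", cfg, col(is_forest, "ndvi_growing"),
        col(is_nonveg, "ndvi_growing"), ">=", report)

    # --- level-1 classification per zone ---------------------------------
    level1_maps: dict[int, pd.Series] = {}
    forest_masks: dict[int, np.ndarray] = {}
    nn_nonveg_train = train1[is_nonveg.to_numpy()]
    nn_veg_train = train1[is_nfveg.to_numpy()]
    for zid in zone_ids:
        f = feats1[zid]
        if f.empty:
            level1_maps[zid] = pd.Series(dtype=np.int64)
            forest_masks[zid] = np.zeros(grid.shape, dtype=bool)
            continue
        lv1 = classify_level1(f, rules)
        # non-vegetation -> settlements | other land
        nv = lv1.index[lv1 == POOL_NON_VEGETATION]
        if len(nv):
            lv1.loc[nv] = nn_classify(f.loc[nv], nn_nonveg_train, band_cols).to_numpy()
        # cropland/grassland/wetland pool via seasonal index trajectories
        nf = lv1.index[lv1 == POOL_NON_FOREST_VEG]
        if len(nf):
            lv1.loc[nf] = nn_classify(f.loc[nf], nn_veg_train, veg_cols).to_numpy()
        level1_maps[zid] = lv1
        sm = seg1[zid]
        forest_ids = set(lv1.index[lv1 == int(LC.FOREST)])
        fm = np.isin(sm.labels, sorted(forest_ids))
        forest_masks[zid] = fm
        report["zones"][zid]["forest_candidate_pixels"] = int(fm.sum())

    # --- level-2 segmentation within forest candidates --------------------
    seg2: dict[int, object] = {}
    feats2: dict[int, pd.DataFrame] = {}
    train2_frames = []
    forest_training = training.frame["label"].astype(int).isin(sorted(forest_set))
    training_forest = SampleSet(training.frame[forest_training].reset_index(drop=True))
    for zid in zone_ids:
        fm = forest_masks[zid]
        if not fm.any():
            feats2[zid] = pd.DataFrame()
            continue
        sm2 = segment_within_mask(planes, fm, cfg.level2, seed=cfg.seed + 100 + zid,
                                  grid=grid)
        seg2[zid] = sm2
        f2 = add_ratio_features(object_stats(sm2, idx_planes, dem))
        feats2[zid] = f2
        pts = _object_of_points(sm2.labels, training_forest, grid)
        tf = _training_features(pts, f2)
        train2_frames.append(tf)
        report["zones"][zid]["level2_objects"] = sm2.n_objects
    train2 = (pd.concat(train2_frames, ignore_index=True)
              if train2_frames else pd.DataFrame())

    if not train2.empty:
        l2 = train2["label"].astype(int)
        evergreen = l2.isin([int(LC.EVERGREEN_NEEDLELEAF), int(LC.EVERGREEN_BROADLEAF)])
        deciduous = ~evergreen
        dnf = l2 == int(LC.DECIDUOUS_NEEDLELEAF)
        dbf = l2 == int(LC.DECIDUOUS_BROADLEAF)
        mf = l2 == int(LC.MIXED_FOREST)
        srf = l2 == int(LC.SHRUBLAND)

        def col2(mask, name):
            return train2.loc[mask, name].to_numpy(float)

        if evergreen.any() and deciduous.any():
            rules.spring_ndvi_evergreen = _calibrate(
                "spring_ndvi_evergreen", cfg, col2(evergreen, "spring_ndvi"),
                col2(deciduous, "spring_ndvi"), ">=", report)
        broad_pool = dbf | mf | srf
        if dnf.any() and broad_pool.any():
            rules.summer_evi_needleleaf = _calibrate(
                "summer_evi_needleleaf", cfg, col2(dnf, "summer_evi"),
                col2(broad_pool, "summer_evi"), "<", report)
        if mf.any() and dbf.any():
            g_high = _calibrate("summer_evi_mixed_high", cfg,
                                col2(mf, "summer_evi"), col2(dbf, "summer_evi"),
                                "<", report)
            g_low = rules.summer_evi_needleleaf
            g_low_v = g_low.threshold if isinstance(g_low, Calibration) else float(g_low)
            g_high_v = g_high.threshold if isinstance(g_high, Calibration) else float(g_high)
            rules.summer_evi_mixed = (g_low_v, g_high_v)
        if srf.any() and (dbf | mf).any():
            rules.b3b1_shrub = _calibrate(
                "b3b1_shrub", cfg, col2(srf, "b3b1_summer"),
                col2(dbf | mf, "b3b1_summer"), ">=", report)
            rules.rvi_shrub = _calibrate(
                "rvi_shrub", cfg, col2(srf, "rvi_summer"),
                col2(dbf | mf, "rvi_summer"), "<", report)
    # the shrub elevation cap is knowledge-based like the mixed-forest
    # limits, not calibrated: broadleaf forest occupies low terrain too, so
    # a trained cut would sit flush against the shrub range with no margin
    if "dem_shrub_limit" in cfg.fixed_thresholds:
        rules.dem_shrub_limit = cfg.fixed_thresholds["dem_shrub_limit"]
    report["thresholds"]["dem_shrub_limit"] = {
        "value": rules.dem_shrub_limit, "fixed": True}

    # --- paint zone maps ---------------------------------------------------
    per_zone: dict[int, LabelRaster] = {}
    for zid in zone_ids:
        out = np.zeros(grid.shape, dtype=np.int32)
        sm = seg1[zid]
        lv1 = level1_maps[zid]
        lut_size = int(sm.labels.max()) + 2 if sm.labels.size else 1
        lut = np.zeros(max(lut_size, 1), dtype=np.int32)
        for oid, cls in lv1.items():
            lut[oid] = cls if cls != int(LC.FOREST) else 0
        inside = sm.labels >= 0
        out[inside] = lut[sm.labels[inside]]
        f2 = feats2[zid]
        if not f2.empty:
            sm2 = seg2[zid]
            sub = classify_forest_types(f2, rules, zid)
            sub = extract_shrubland(f2, sub, rules)
            lut2 = np.zeros(int(sm2.labels.max()) + 2, dtype=np.int32)
            for oid, cls in sub.items():
                lut2[oid] = cls
            in2 = sm2.labels >= 0
            out[in2] = lut2[sm2.labels[in2]]
        per_zone[zid] = LabelRaster(grid=grid, labels=out, nodata=0)

    final = mosaic_zone_results(per_zone, zones, nodata=0)
    areas = {}
    px = grid.pixel_area_km2
    for cls in np.unique(final.labels):
        if cls == 0:
            continue
        areas[int(cls)] = float(np.count_nonzero(final.labels == cls) * px)
    report["class_area_km2"] = areas
    report["rules"] = {}
    for fobj in dc_fields(rules):
        if fobj.name == "dem_mixed_limit":
            continue
        v = getattr(rules, fobj.name)
        if isinstance(v, Calibration):
            v = v.threshold
        elif isinstance(v, tuple):
            v = [x.threshold if isinstance(x, Calibration) else x for x in v]
        report["rules"][fobj.name] = v
    report["dem_mixed_limit"] = rules.dem_mixed_limit
    return final, report
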