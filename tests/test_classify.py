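import itertools

import numpy as np
import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from obforest.classify import (Calibration, CalibrationError, ConfigError,
                               FeatureError, POOL_NON_FOREST_VEG,
                               POOL_NON_VEGETATION, RuleSet,
                               calibrate_threshold, classify_forest_types,
                               classify_level1, extract_shrubland, nn_classify)
from obforest.scheme import LandCover as LC


# exhaustive reference: try every midpoint cut and both directions
def exhaustive_best_cut(pos, neg):
    allv = np.unique(np.concatenate([pos, neg]))
    if allv.size == 1:
        return float(allv[0]), None, 0.5
    best = None
    total = len(pos) + len(neg)
    for t, g in zip((allv[:-1] + allv[1:]) / 2, (allv[1:] - allv[:-1]) / 2):
        for d in (">=", "<"):
            if d == ">=":
                err = (sum(p < t for p in pos) + sum(n >= t for n in neg)) / total
            else:
                err = (sum(p >= t for p in pos) + sum(n < t for n in neg)) / total
            key = (err, -g, t)
            if best is None or key < best[0]:
                best = (key, t, d, err)
    return best[1], best[2], best[3]


class TestCalibrateThreshold:
    def test_clean_separation(self):
        cal = calibrate_threshold([0.8, 0.9], [0.1, 0.2])
        assert cal.threshold == pytest.approx(0.5)
        assert cal.direction == ">="
        assert cal.error_rate == 0.0

    def test_identical_values_degenerate(self):
        cal = calibrate_threshold([0.5], [0.5])
        assert cal.degenerate
        assert cal.threshold == 0.5
        assert cal.error_rate == 0.5

    def test_interleaved_best_error(self):
        cal = calibrate_threshold([0.3, 0.7], [0.5])
        assert cal.error_rate == pytest.approx(1 / 3)

    def test_empty_group_is_error(self):
        with pytest.raises(CalibrationError):
            calibrate_threshold([], [0.5])

    @settings(max_examples=100, deadline=None)
    @given(st.lists(st.integers(0, 20), min_size=1, max_size=30),
           st.lists(st.integers(0, 20), min_size=1, max_size=30))
    def test_matches_exhaustive_search(self, pos, neg):
        pos = np.array(pos, float) / 10
        neg = np.array(neg, float) / 10
        cal = calibrate_threshold(pos, neg)
        t, d, err = exhaustive_best_cut(pos, neg)
        assert cal.error_rate == pytest.approx(err)
        if not cal.degenerate:
            assert cal.threshold == pytest.approx(t)


def _objects(**cols):
    return pd.DataFrame(cols)


class TestLevel1:
    RULES = RuleSet(ndwi_water=0.1, ndvi_vegetation=0.3, v_forest=0.35,
                    ndvi_forest=0.4)

    def test_water_wins_regardless_of_other_features(self):
        obj = _objects(ndwi_intermediate=[0.2], ndvi_growing=[0.9], v_growing=[0.1])
        out = classify_level1(obj, self.RULES)
        assert out.iloc[0] == int(LC.WATER)

    def test_forest_candidate_requires_conjunction(self):
        obj = _objects(ndwi_intermediate=[-0.5, -0.5, -0.5],
                       ndvi_growing=[0.8, 0.8, 0.8],
                       v_growing=[0.2, 0.5, 0.2])
        out = classify_level1(obj, self.RULES)
        assert out.iloc[0] == int(LC.FOREST)
        assert out.iloc[1] == POOL_NON_FOREST_VEG  # V too high
        assert out.iloc[2] == int(LC.FOREST)

    def test_low_ndvi_routes_to_non_vegetation(self):
        obj = _objects(ndwi_intermediate=[-0.5], ndvi_growing=[0.1], v_growing=[0.2])
        out = classify_level1(obj, self.RULES)
        assert out.iloc[0] == POOL_NON_VEGETATION

    def test_missing_feature_is_error(self):
        obj = _objects(ndwi_intermediate=[-0.5], ndvi_growing=[0.8],
                       v_growing=[np.nan])
        with pytest.raises(FeatureError, match="v_growing"):
            classify_level1(obj, self.RULES)


class TestNearestNeighbour:
    def _train(self):
        return pd.DataFrame({
            "f1": [0.0, 1.0], "f2": [0.0, 1.0],
            "label": [int(LC.SETTLEMENTS), int(LC.OTHER_LAND)],
        })

    def test_exact_match_wins(self):
        out = nn_classify(_objects(f1=[1.0], f2=[1.0]), self._train(), ["f1", "f2"])
        assert out.iloc[0] == int(LC.OTHER_LAND)

    def test_tie_breaks_to_smaller_class_code(self):
        out = nn_classify(_objects(f1=[0.5], f2=[0.5]), self._train(), ["f1", "f2"])
        assert out.iloc[0] == int(LC.SETTLEMENTS)

    def test_matches_brute_force_distances(self):
        rng = np.random.default_rng(0)
        train = pd.DataFrame({"f1": rng.normal(size=9), "f2": rng.normal(size=9),
                              "label": rng.integers(2, 5, 9)})
        q = _objects(f1=rng.normal(size=5), f2=rng.normal(size=5))
        out = nn_classify(q, train, ["f1", "f2"])
        mu = train[["f1", "f2"]].mean()
        sd = train[["f1", "f2"]].std(ddof=0)
        for i in range(5):
            d = (((train[["f1", "f2"]] - mu) / sd
                  - ((q.iloc[i][["f1", "f2"]] - mu) / sd)) ** 2).sum(axis=1)
            assert out.iloc[i] == train["label"].iloc[int(np.argmin(d.to_numpy()))]


class TestForestTypes:
    RULES = RuleSet(spring_ndvi_evergreen=0.5, summer_evi_needleleaf=0.45,
                    summer_evi_mixed=(0.45, 0.55),
                    dem_mixed_limit={6: 1000.0, 3: 700.0})

    def test_evergreen_wins_on_spring_ndvi(self):
        obj = _objects(spring_ndvi=[0.7], summer_evi=[0.5], dem_mean=[500.0])
        out = classify_forest_types(obj, self.RULES, zone=6)
        assert out.iloc[0] == int(LC.EVERGREEN_NEEDLELEAF)

    def test_low_summer_evi_is_deciduous_needleleaf(self):
        obj = _objects(spring_ndvi=[0.2], summer_evi=[0.40], dem_mean=[500.0])
        out = classify_forest_types(obj, self.RULES, zone=6)
        assert out.iloc[0] == int(LC.DECIDUOUS_NEEDLELEAF)

    def test_mixed_band_above_elevation_limit_is_broadleaf(self):
        # mid EVI at 1200 m in a zone limited to 1000 m: mixed excluded
        obj = _objects(spring_ndvi=[0.2, 0.2], summer_evi=[0.5, 0.5],
                       dem_mean=[1200.0, 800.0])
        out = classify_forest_types(obj, self.RULES, zone=6)
        assert out.iloc[0] == int(LC.DECIDUOUS_BROADLEAF)
        assert out.iloc[1] == int(LC.MIXED_FOREST)

    def test_zone_limits_differ(self):
        # the same 800 m object is mixed in the 1000 m zone, broadleaf in the 700 m zone
        obj = _objects(spring_ndvi=[0.2], summer_evi=[0.5], dem_mean=[800.0])
        assert classify_forest_types(obj, self.RULES, zone=6).iloc[0] == int(LC.MIXED_FOREST)
        assert classify_forest_types(obj, self.RULES, zone=3).iloc[0] == int(LC.DECIDUOUS_BROADLEAF)

    def test_unconfigured_zone_is_config_error(self):
        obj = _objects(spring_ndvi=[0.2], summer_evi=[0.5], dem_mean=[500.0])
        with pytest.raises(ConfigError, match="zone 99"):
            classify_forest_types(obj, self.RULES, zone=99)


class TestShrubland:
    RULES = RuleSet(b3b1_shrub=1.8, rvi_shrub=6.0, dem_shrub_limit=500.0)

    def _labels(self, n):
        return pd.Series([int(LC.DECIDUOUS_BROADLEAF)] * n)

    def test_all_conditions_met_reassigns(self):
        obj = _objects(b3b1_summer=[2.0], rvi_summer=[4.0], dem_mean=[300.0])
        out = extract_shrubland(obj, self._labels(1), self.RULES)
        assert out.iloc[0] == int(LC.SHRUBLAND)

    @pytest.mark.parametrize("b3b1,rvi,dem", [
        (1.5, 4.0, 300.0),   # ratio too low
        (2.0, 7.0, 300.0),   # RVI too high
        (2.0, 4.0, 800.0),   # terrain too high
    ])
    def test_single_failed_condition_leaves_label(self, b3b1, rvi, dem):
        obj = _objects(b3b1_summer=[b3b1], rvi_summer=[rvi], dem_mean=[dem])
        out = extract_shrubland(obj, self._labels(1), self.RULES)
        assert out.iloc[0] == int(LC.DECIDUOUS_BROADLEAF)

    def test_empty_candidate_set_is_noop(self):
        obj = _objects(b3b1_summer=[2.0], rvi_summer=[4.0], dem_mean=[300.0])
        labels = pd.Series([int(LC.EVERGREEN_NEEDLELEAF)])
        out = extract_shrubland(obj, labels, self.RULES)
        assert out.iloc[0] == int(LC.EVERGREEN_NEEDLELEAF)


class TestRuleMonotonicity:
    def test_raising_water_cut_never_grows_water(self):
        rng = np.random.default_rng(2)
        obj = _objects(ndwi_intermediate=rng.uniform(-1, 1, 50),
                       ndvi_growing=rng.uniform(0, 1, 50),
                       v_growing=rng.uniform(0, 1, 50))
        waters = []
        for a in np.linspace(-0.5, 0.5, 7):
            rules = RuleSet(ndwi_water=float(a))
            out = classify_level1(obj, rules)
            waters.append(int((out == int(LC.WATER)).sum()))
        assert waters == sorted(waters, reverse=True)

    def test_every_object_gets_exactly_one_class(self):
        rng = np.random.default_rng(3)
        obj = _objects(ndwi_intermediate=rng.uniform(-1, 1, 40),
                       ndvi_growing=rng.uniform(-0.2, 1, 40),
                       v_growing=rng.uniform(0, 0.6, 40))
        out = classify_level1(obj, RuleSet())
        assert len(out) == 40
        assert out.isin([int(LC.WATER), int(LC.FOREST),
                         POOL_NON_VEGETATION, POOL_NON_FOREST_VEG]).all()
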