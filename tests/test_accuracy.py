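import numpy as np
import pandas as pd
import pytest

from obforest.accuracy import (ConfusionMatrix, EmptyMatrixError, VarianceError,
                               area_weighted_accuracies, build_confusion,
                               simple_accuracies)
from obforest.grids import GeoGrid, LabelRaster, SampleSet


def _samples(points):
    return SampleSet(pd.DataFrame(
        [{"id": i, "x": x, "y": y, "label": lab, "role": "validation",
          "in_extent": True} for i, (x, y, lab) in enumerate(points)]))


class TestBuildConfusion:
    def _map(self):
        grid = GeoGrid(4, 4)
        labels = np.ones(grid.shape, dtype=np.int32)  # all water (code 1)
        return LabelRaster(grid, labels, nodata=0)

    def test_correct_points_fill_diagonal(self):
        pred = self._map()
        cm = build_confusion(pred, _samples([(15, -15, 1), (45, -15, 1), (75, -45, 1)]))
        assert cm.counts.loc[1, 1] == 3
        assert cm.total == 3

    def test_disagreement_goes_off_diagonal(self):
        pred = self._map()
        cm = build_confusion(pred, _samples([(15, -15, 10)]))  # forest point mapped water
        assert cm.counts.loc[1, 10] == 1
        assert cm.counts.loc[10, 10] == 0

    def test_out_of_extent_excluded_and_counted(self):
        pred = self._map()
        ss = _samples([(15, -15, 1), (1000.0, -15, 1)])
        ss.frame.loc[1, "in_extent"] = False
        cm = build_confusion(pred, ss)
        assert cm.total == 1
        assert cm.excluded == 1

    def test_all_excluded_is_error(self):
        pred = self._map()
        ss = _samples([(15, -15, 1)])
        ss.frame["in_extent"] = False
        with pytest.raises(EmptyMatrixError):
            build_confusion(pred, ss)


class TestSimpleAccuracies:
    def test_published_style_matrix(self):
        counts = [[84, 5, 12, 3, 1],
                  [8, 100, 10, 6, 4],
                  [12, 10, 213, 10, 8],
                  [5, 13, 16, 82, 6],
                  [1, 5, 3, 17, 31]]
        cm = ConfusionMatrix.from_counts(counts, ["ENF", "DNF", "DBF", "MF", "SRF"])
        rep = simple_accuracies(cm)
        assert rep.users["DBF"] == pytest.approx(213 / 253)
        assert rep.producers["SRF"] == pytest.approx(31 / 50)
        assert rep.producers["MF"] == pytest.approx(82 / 118)

    def test_identity_matrix_is_perfect(self):
        cm = ConfusionMatrix.from_counts(np.eye(3, dtype=int) * 7, list("xyz"))
        rep = simple_accuracies(cm)
        assert rep.overall == 1.0
        assert (rep.users == 1.0).all()
        assert (rep.producers == 1.0).all()

    def test_empty_row_flagged_undefined(self):
        cm = ConfusionMatrix.from_counts([[0, 0], [3, 5]], ["a", "b"])
        rep = simple_accuracies(cm)
        assert np.isnan(rep.users["a"])


class TestAreaWeighted:
    def test_forest_producers_accuracy_with_weights(self):
        cm = ConfusionMatrix.from_counts([[520, 127], [1008, 2318]],
                                         ["forest", "non-forest"])
        rep = area_weighted_accuracies(cm, {"forest": 0.34, "non-forest": 0.66})
        p11 = 0.34 * 520 / 647
        p21 = 0.66 * 1008 / 3326
        assert rep.producers["forest"] == pytest.approx(p11 / (p11 + p21))
        assert round(rep.producers["forest"], 2) == 0.58

    def test_users_accuracy_and_ci_match_closed_form(self):
        cm = ConfusionMatrix.from_counts([[1169, 142], [359, 2303]],
                                         ["forest", "non-forest"])
        rep = area_weighted_accuracies(cm, {"forest": 0.40, "non-forest": 0.60})
        ua = 1169 / 1311
        assert rep.users["forest"] == pytest.approx(ua)
        assert rep.ci_users()["forest"] == pytest.approx(
            1.96 * np.sqrt(ua * (1 - ua) / 1310))
        assert round(rep.users["forest"], 2) == 0.89
        assert round(rep.ci_users()["forest"], 2) == 0.02

    def test_degenerate_single_stratum_weight(self):
        cm = ConfusionMatrix.from_counts([[8, 2], [3, 7]], ["a", "b"])
        rep = area_weighted_accuracies(cm, {"a": 1.0, "b": 0.0})
        assert rep.overall == pytest.approx(rep.users["a"])

    def test_cell_proportions_sum_to_one(self):
        cm = ConfusionMatrix.from_counts([[50, 5, 2], [7, 80, 3], [1, 4, 60]],
                                         list("abc"))
        w = {"a": 0.2, "b": 0.5, "c": 0.3}
        rep = area_weighted_accuracies(cm, w)
        q = cm.counts.to_numpy() / cm.counts.to_numpy().sum(axis=1, keepdims=True)
        p = np.array([0.2, 0.5, 0.3])[:, None] * q
        assert p.sum() == pytest.approx(1.0, abs=1e-12)
        assert rep.overall == pytest.approx(np.diag(p).sum())

    def test_weights_proportional_to_rows_equals_simple(self):
        cm = ConfusionMatrix.from_counts([[50, 5, 2], [7, 80, 3], [1, 4, 60]],
                                         list("abc"))
        rows = cm.row_totals.to_numpy()
        w = dict(zip(cm.labels, rows / rows.sum()))
        weighted = area_weighted_accuracies(cm, w)
        simple = simple_accuracies(cm)
        assert weighted.overall == pytest.approx(simple.overall)
        assert np.allclose(weighted.producers, simple.producers)

    def test_weight_sum_must_be_near_one(self):
        cm = ConfusionMatrix.from_counts([[5, 2], [3, 7]], ["a", "b"])
        with pytest.raises(ValueError, match="sum"):
            area_weighted_accuracies(cm, {"a": 0.7, "b": 0.7})

    def test_singleton_stratum_is_variance_error(self):
        cm = ConfusionMatrix.from_counts([[1, 0], [3, 7]], ["a", "b"])
        with pytest.raises(VarianceError):
            area_weighted_accuracies(cm, {"a": 0.5, "b": 0.5})

    def test_analytic_se_matches_stratified_bootstrap(self):
        cm = ConfusionMatrix.from_counts([[40, 10], [12, 60]], ["f", "n"])
        w = {"f": 0.45, "n": 0.55}
        rep = area_weighted_accuracies(cm, w)
        rng = np.random.default_rng(0)
        n = cm.counts.to_numpy()
        rows = n.sum(axis=1)
        oas, uas, pas = [], [], []
        for _ in range(10_000):
            q = np.stack([rng.multinomial(rows[i], n[i] / rows[i]) / rows[i]
                          for i in range(2)])
            p = np.array([0.45, 0.55])[:, None] * q
            oas.append(p[0, 0] + p[1, 1])
            uas.append(q[0, 0])
            pas.append(p[0, 0] / (p[0, 0] + p[1, 0]))
        assert rep.se_overall == pytest.approx(np.std(oas), rel=0.15)
        assert rep.se_users["f"] == pytest.approx(np.std(uas), rel=0.15)
        assert rep.se_producers["f"] == pytest.approx(np.std(pas), rel=0.15)
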