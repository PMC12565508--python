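"""Metrics, paired tests, detection utilities, comparison-report contracts."""

import itertools

import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st
from scipy.stats import wilcoxon as scipy_wilcoxon

from fruitvol.evaluation import (
    BoxMatchCounts,
    geometric_baseline,
    iou,
    map50,
    precision_recall,
    regression_metrics,
    residual_summary,
    wilcoxon_compare,
)


class TestRegressionMetrics:
    def test_perfect_fit(self):
        m = regression_metrics([10, 20, 30], [10, 20, 30])
        assert (m.mae, m.mse, m.r2) == (0.0, 0.0, 1.0)

    def test_hand_worked(self):
        m = regression_metrics([10, 20, 30], [12, 22, 32])
        assert m.mae == pytest.approx(2.0)
        assert m.mse == pytest.approx(4.0)
        assert m.r2 == pytest.approx(1 - 12 / 200)

    def test_mean_predictor_zero_r2(self):
        truth = np.array([5.0, 10.0, 15.0, 20.0])
        m = regression_metrics(truth, np.full(4, truth.mean()))
        assert m.r2 == pytest.approx(0.0, abs=1e-12)

    def test_constant_truth_undefined_r2(self):
        m = regression_metrics([3.0, 3.0, 3.0], [3.1, 2.9, 3.0])
        assert m.r2 is None

    @given(
        st.lists(st.floats(1, 500), min_size=3, max_size=40),
        st.integers(0, 10**6),
    )
    def test_metric_identities(self, truth, seed):
        truth = np.asarray(truth)
        pred = truth + np.random.default_rng(seed).normal(size=len(truth))
        m = regression_metrics(truth, pred)
        assert m.rmse**2 == pytest.approx(m.mse, rel=1e-12)
        assert m.mae <= m.rmse + 1e-12
        sst = np.sum((truth - truth.mean()) ** 2)
        if sst > 0:
            assert m.r2 == pytest.approx(1 - m.mse * m.n / sst, rel=1e-9)


class TestGeometricBaseline:
    def test_exact_on_ideal_population(self, ideal_dataset):
        reports, best = geometric_baseline(
            ideal_dataset.features, ideal_dataset.target.values
        )
        assert best == "v_ellip_sh"
        assert reports[best].mse <= 1e-9

    def test_sphere_population_proxies_coincide(self):
        import pandas as pd
        from fruitvol.features import featurize_table

        dims = pd.DataFrame(
            {
                "fruit_id": ["a", "b"],
                "w_top_mm": [60.0, 70.0],
                "h_top_mm": [60.0, 70.0],
                "w_side_mm": [60.0, 70.0],
                "h_side_mm": [60.0, 70.0],
            }
        )
        feats = featurize_table(dims)
        truth = feats["v_sphere"].values
        reports, _ = geometric_baseline(feats, truth)
        for rep in reports.values():
            assert rep.mse == pytest.approx(0.0, abs=1e-18)


def brute_force_signed_rank_p(d):
    """Full 2^n enumeration oracle for the two-sided signed-rank p-value."""
    d = np.asarray(d, dtype=float)
    d = d[d != 0]
    n = len(d)
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    pos = np.arange(1, n + 1, dtype=float)
    i = 0
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = pos[i : j + 1].mean()
        i = j + 1
    w_obs = ranks[d > 0].sum()
    ws = [
        sum(r for r, s in zip(ranks, signs) if s)
        for signs in itertools.product([0, 1], repeat=n)
    ]
    ws = np.asarray(ws)
    lo = np.mean(ws <= w_obs + 1e-9)
    hi = np.mean(ws >= w_obs - 1e-9)
    return min(1.0, 2 * min(lo, hi))


class TestWilcoxon:
    def test_identical_vectors_degenerate(self):
        res = wilcoxon_compare([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res["degenerate"] and res["p_value"] == 1.0

    def test_five_positive_differences(self):
        res = wilcoxon_compare([2, 3, 4, 5, 6], [1, 2, 3, 4, 5])
        assert res["p_value"] == pytest.approx(2 / 32)

    def test_antisymmetry(self):
        rng = np.random.default_rng(2)
        a, b = rng.normal(size=12), rng.normal(size=12)
        r1, r2 = wilcoxon_compare(a, b), wilcoxon_compare(b, a)
        assert r1["statistic"] == -r2["statistic"]
        assert r1["p_value"] == pytest.approx(r2["p_value"], rel=1e-12)

    def test_matches_enumeration_small_n(self):
        rng = np.random.default_rng(5)
        for trial in range(30):
            n = int(rng.integers(3, 11))
            d = np.round(rng.normal(size=n), 1)  # rounding creates ties
            a = d
            b = np.zeros(n)
            if np.all(d == 0):
                continue
            ours = wilcoxon_compare(a, b)["p_value"]
            assert ours == pytest.approx(brute_force_signed_rank_p(d), rel=1e-9)

    def test_matches_scipy_exact_tie_free(self):
        rng = np.random.default_rng(9)
        d = rng.normal(size=14)
        ours = wilcoxon_compare(d, np.zeros(14))["p_value"]
        ref = scipy_wilcoxon(d, mode="exact").pvalue
        assert ours == pytest.approx(ref, rel=1e-9)

    def test_large_n_normal_approximation_reasonable(self):
        rng = np.random.default_rng(3)
        d = rng.normal(0.4, 1.0, size=60)
        res = wilcoxon_compare(d, np.zeros(60))
        ref = scipy_wilcoxon(d, correction=False, mode="approx").pvalue
        assert res["p_value"] == pytest.approx(ref, rel=1e-6)


class TestResiduals:
    def test_zero_residuals(self):
        s = residual_summary([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert s["mean"] == 0.0 and s["sd"] == 0.0

    def test_constant_shift(self):
        s = residual_summary([10.0, 20.0, 30.0], [8.0, 18.0, 28.0])
        assert s["mean"] == pytest.approx(2.0)
        assert s["median"] == pytest.approx(2.0)


class TestDetectionMetrics:
    def test_iou_identical(self):
        assert iou((0, 0, 2, 2), (0, 0, 2, 2)) == 1.0

    def test_iou_disjoint(self):
        assert iou((0, 0, 1, 1), (5, 5, 6, 6)) == 0.0

    def test_iou_hand_value(self):
        assert iou((0, 0, 2, 2), (1, 1, 3, 3)) == pytest.approx(1 / 7)

    def test_iou_degenerate_box(self):
        with pytest.warns(UserWarning):
            assert iou((0, 0, 0, 5), (0, 0, 2, 2)) == 0.0

    def test_precision_recall(self):
        assert precision_recall(BoxMatchCounts(10, 0, 0)) == (1.0, 1.0)
        assert precision_recall(BoxMatchCounts(3, 1, 2)) == (0.75, 0.6)
        p, r = precision_recall(BoxMatchCounts(0, 0, 4))
        assert p is None and r == 0.0

    def test_map_all_correct(self):
        gt = [{"box": (0, 0, 10, 10), "label": "fruit", "image_id": 0}]
        det = [{"box": (0, 0, 10, 10), "label": "fruit", "score": 0.9, "image_id": 0}]
        assert map50(det, gt)["map"] == 1.0

    def test_map_no_detections(self):
        gt = [{"box": (0, 0, 10, 10), "label": "fruit", "image_id": 0}]
        assert map50([], gt)["map"] == 0.0

    def test_map_interleaved_matches_brute_force(self):
        # 2 correct + 1 false detection, interleaved by score:
        # PR points: (r=1/2, p=1), (r=1/2, p=1/2), (r=1, p=2/3) -> AP = 0.5*1 + 0.5*2/3
        gt = [
            {"box": (0, 0, 10, 10), "label": "fruit", "image_id": 0},
            {"box": (20, 20, 30, 30), "label": "fruit", "image_id": 0},
        ]
        det = [
            {"box": (0, 0, 10, 10), "label": "fruit", "score": 0.9, "image_id": 0},
            {"box": (50, 50, 60, 60), "label": "fruit", "score": 0.8, "image_id": 0},
            {"box": (20, 20, 30, 30), "label": "fruit", "score": 0.7, "image_id": 0},
        ]
        assert map50(det, gt)["map"] == pytest.approx(0.5 + 0.5 * 2 / 3)

    def test_map_monotone_in_added_correct_detection(self):
        gt = [
            {"box": (0, 0, 10, 10), "label": "fruit", "image_id": 0},
            {"box": (20, 20, 30, 30), "label": "fruit", "image_id": 0},
        ]
        det = [
            {"box": (0, 0, 10, 10), "label": "fruit", "score": 0.9, "image_id": 0},
            {"box": (50, 50, 60, 60), "label": "fruit", "score": 0.8, "image_id": 0},
        ]
        before = map50(det, gt)["map"]
        det.append({"box": (20, 20, 30, 30), "label": "fruit", "score": 0.1, "image_id": 0})
        assert map50(det, gt)["map"] >= before

    def test_map_class_without_ground_truth_excluded(self):
        gt = [{"box": (0, 0, 10, 10), "label": "fruit", "image_id": 0}]
        det = [
            {"box": (0, 0, 10, 10), "label": "fruit", "score": 0.9, "image_id": 0},
            {"box": (0, 0, 10, 10), "label": "marker", "score": 0.9, "image_id": 0},
        ]
        with pytest.warns(UserWarning):
            res = map50(det, gt)
        assert list(res["ap_per_class"]) == ["fruit"]


class TestComparisonReport:
    def test_schema_and_shared_folds(self, ideal_report):
        frame = ideal_report.to_frame()
        assert len(frame) == 6
        assert set(frame.columns) == {"model", "mae", "mse", "rmse", "r2"}
        assert ideal_report.fold_hash
        assert ideal_report.predictions.shape[0] == 150

    def test_qualitative_ordering_majority(self, study_reports):
        """Proxy >= linear >= best single >= stack by MSE in most seeds."""
        bases = [
            "classic_gbrt",
            "regularised_depthwise_gbrt",
            "histogram_leafwise_gbrt",
        ]
        holds = 0
        for rep in study_reports.values():
            mse = {m: rep.metrics[m].mse for m in rep.metrics}
            best_single = min(bases, key=lambda m: mse[m])
            holds += (
                mse["best_proxy"] >= mse["linear"] >= mse[best_single] >= mse["stack"]
            )
        assert holds > len(study_reports) / 2
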