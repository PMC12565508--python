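"""Original-scale metrics, model comparison, paired tests, detection metrics.

All regression metrics are computed on the original mL scale after the
inverse target transform: MAE, MSE, RMSE = sqrt(MSE) and the coefficient of
determination R^2.  The model-comparison study evaluates a geometric-proxy
baseline, an ordinary least-squares baseline, the three boosted base
learners and the stacked ensemble on identical stratified folds, with
per-sample out-of-fold absolute errors feeding a Wilcoxon signed-rank test.

The detection utilities (IoU, precision/recall, mAP@50) evaluate the
bounding-box stage of a two-view measurement rig; they are exact
re-implementations of the standard definitions with greedy score-ordered
matching and all-points precision-recall interpolation.
"""

from __future__ import annotations

import hashlib
import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.stats import norm, skew
from sklearn.linear_model import LinearRegression

from .features import FEATURE_NAMES
from .modeling import (
    PipelineConfig,
    _transform_features,
    fit_pipeline,
    predict_single_base,
    predict_volume,
)
from .preprocessing import stratified_folds, transform_target, inverse_transform_target

__all__ = [
    "MetricReport",
    "ComparisonReport",
    "BoxMatchCounts",
    "regression_metrics",
    "geometric_baseline",
    "compare_models",
    "wilcoxon_compare",
    "residual_summary",
    "iou",
    "precision_recall",
    "map50",
]

PROXY_COLUMNS = ["v_ellip_avg", "v_ellip_sw", "v_ellip_sh", "v_sphere"]
BASE_FAMILIES = ["classic_gbrt", "regularised_depthwise_gbrt", "histogram_leafwise_gbrt"]


@dataclass(frozen=True)
class MetricReport:
    """MAE / MSE / RMSE / R^2 on the mL scale; r2 is None when undefined."""

    mae: float
    mse: float
    rmse: float
    r2: float | None
    n: int
    per_fold: tuple = ()


@dataclass(frozen=True)
class BoxMatchCounts:
    tp: int
    fp: int
    fn: int

    def __post_init__(self):
        if min(self.tp, self.fp, self.fn) < 0:
            raise ValueError("counts must be non-negative")


@dataclass
class ComparisonReport:
    """Multi-model comparison on shared folds."""

    metrics: dict  # model name -> MetricReport
    predictions: pd.DataFrame  # out-of-fold predictions per model (mL)
    abs_errors: pd.DataFrame  # per-sample absolute errors per model (mL)
    proxy_metrics: dict  # proxy column -> MetricReport
    best_proxy: str
    pairwise_tests: dict  # (model_a, model_b) -> wilcoxon result dict
    fold_hash: str
    seed: int

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for name, m in self.metrics.items():
            rows.append(
                {"model": name, "mae": m.mae, "mse": m.mse, "rmse": m.rmse, "r2": m.r2}
            )
        return pd.DataFrame(rows)


def regression_metrics(truth, pred, fold_index=None) -> MetricReport:
    """MAE, MSE, RMSE = sqrt(MSE), R^2 = 1 - SSE/SST on the original scale."""
    v = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    if v.shape != p.shape or v.ndim != 1:
        raise ValueError("truth and prediction must be equal-length vectors")
    if len(v) < 2:
        raise ValueError("need at least 2 samples")
    resid = p - v
    mae = float(np.mean(np.abs(resid)))
    mse = float(np.mean(resid**2))
    sst = float(np.sum((v - v.mean()) ** 2))
    r2 = None if sst == 0 else float(1.0 - np.sum(resid**2) / sst)
    per_fold = ()
    if fold_index is not None:
        fold_index = np.asarray(fold_index)
        per_fold = tuple(
            {
                "fold": int(f),
                "mae": float(np.mean(np.abs(resid[fold_index == f]))),
                "mse": float(np.mean(resid[fold_index == f] ** 2)),
                "n": int(np.sum(fold_index == f)),
            }
            for f in np.unique(fold_index)
        )
    return MetricReport(mae=mae, mse=mse, rmse=float(np.sqrt(mse)), r2=r2, n=len(v), per_fold=per_fold)


def geometric_baseline(features: pd.DataFrame, truth) -> tuple[dict, str]:
    """Evaluate the four closed-form volume proxies; best = lowest MSE.

    The proxies are direct geometric formulas on the measured dimensions
    (three ellipsoid variants and the mean-diameter sphere), so they need
    no fitting; their "prediction" is the feature value itself.
    """
    reports = {
        c: regression_metrics(truth, features[c].values) for c in PROXY_COLUMNS
    }
    best = min(reports, key=lambda c: reports[c].mse)
    return reports, best


def _fold_hash(fold_index) -> str:
    return hashlib.sha256(np.asarray(fold_index, dtype=np.int64).tobytes()).hexdigest()[:16]


def compare_models(
    dataset,
    seed: int = 0,
    k: int = 5,
    grids: str = "fast",
    config: PipelineConfig | None = None,
) -> ComparisonReport:
    """Run the shared-fold comparison study on a synthetic dataset.

    For each outer fold the entire pipeline (capping, log transforms,
    embedded selection, grid tuning, stacking) is refit on the training
    portion only; the geometric proxies and an OLS baseline on the same
    selected, transformed features are evaluated on the identical folds.
    """
    X = dataset.features[list(FEATURE_NAMES)].reset_index(drop=True)
    y = np.asarray(dataset.target, dtype=float)
    folds = stratified_folds(y, k=k, bins=5, seed=seed)
    cfg = config or PipelineConfig(grids=grids, seed=seed)

    model_names = ["linear"] + BASE_FAMILIES + ["stack"]
    preds = {m: np.full(len(y), np.nan) for m in model_names}

    for f in range(folds.k):
        tr, te = folds.train_indices(f), folds.test_indices(f)
        pipe = fit_pipeline(X.iloc[tr], y[tr], cfg)
        X_te = X.iloc[te]
        preds["stack"][te] = predict_volume(pipe, X_te)
        for fam in BASE_FAMILIES:
            preds[fam][te] = predict_single_base(pipe, X_te, fam)
        # OLS on the same selected, transformed features and log target
        Xt_tr = _transform_features(X.iloc[tr], pipe.feature_caps, pipe.log_columns)
        Xt_te = _transform_features(X_te, pipe.feature_caps, pipe.log_columns)
        sel = list(pipe.selected_names)
        ols = LinearRegression().fit(Xt_tr[sel], transform_target(y[tr]))
        preds["linear"][te] = np.maximum(
            inverse_transform_target(ols.predict(Xt_te[sel])), 0.0
        )

    proxy_metrics, best_proxy = geometric_baseline(dataset.features, y)
    preds["best_proxy"] = dataset.features[best_proxy].values.astype(float)

    order = ["best_proxy"] + model_names
    fi = np.asarray(folds.fold_index)
    metrics = {m: regression_metrics(y, preds[m], fi) for m in order}
    pred_df = pd.DataFrame(preds, columns=order)
    err_df = (pred_df.sub(pd.Series(y), axis=0)).abs()

    best_single = min(BASE_FAMILIES, key=lambda m: metrics[m].mse)
    tests = {
        ("stack", best_single): wilcoxon_compare(
            err_df["stack"].values, err_df[best_single].values
        ),
        ("stack", "best_proxy"): wilcoxon_compare(
            err_df["stack"].values, err_df["best_proxy"].values
        ),
    }
    return ComparisonReport(
        metrics=metrics,
        predictions=pred_df,
        abs_errors=err_df,
        proxy_metrics=proxy_metrics,
        best_proxy=best_proxy,
        pairwise_tests=tests,
        fold_hash=_fold_hash(folds.fold_index),
        seed=seed,
    )


def _signed_rank_exact_p(ranks2: np.ndarray, w2: float) -> float:
    """Two-sided exact p for the signed-rank sum via DP over doubled ranks."""
    total = int(ranks2.sum())
    dist = np.zeros(total + 1)
    dist[0] = 1.0
    for r in ranks2:
        r = int(r)
        nxt = dist.copy()
        nxt[r:] += dist[: total + 1 - r]
        dist = nxt
    dist /= dist.sum()
    w2 = int(round(w2))
    lo = float(dist[: w2 + 1].sum())
    hi = float(dist[w2:].sum())
    return min(1.0, 2.0 * min(lo, hi))


def wilcoxon_compare(errors_a, errors_b, exact_limit: int = 25) -> dict:
    """Two-sided Wilcoxon signed-rank test on paired error vectors.

    Zero differences are dropped.  The null distribution is exact (full
    enumeration over sign assignments, tied ranks handled) for n <= 25 and
    a normal approximation with tie correction above.  The statistic is
    W+ - W-, which changes sign when the arguments swap while the p-value
    is unchanged.
    """
    a = np.asarray(errors_a, dtype=float)
    b = np.asarray(errors_b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("paired vectors must have equal length")
    d = a - b
    d = d[d != 0]
    n = len(d)
    if n == 0:
        return {"statistic": 0.0, "p_value": 1.0, "n": 0, "degenerate": True}
    absd = np.abs(d)
    order = np.argsort(absd, kind="stable")
    ranks = np.empty(n)
    sorted_abs = absd[order]
    # average ranks over ties
    i = 0
    pos = np.arange(1, n + 1, dtype=float)
    while i < n:
        j = i
        while j + 1 < n and sorted_abs[j + 1] == sorted_abs[i]:
            j += 1
        ranks[order[i : j + 1]] = pos[i : j + 1].mean()
        i = j + 1
    w_plus = float(ranks[d > 0].sum())
    w_minus = float(ranks[d < 0].sum())
    statistic = w_plus - w_minus
    if n <= exact_limit:
        p = _signed_rank_exact_p(np.round(2 * ranks).astype(int), 2 * w_plus)
    else:
        mu = n * (n + 1) / 4.0
        var = n * (n + 1) * (2 * n + 1) / 24.0
        _, counts = np.unique(absd, return_counts=True)
        var -= float(np.sum(counts**3 - counts)) / 48.0
        z = (w_plus - mu) / np.sqrt(var)
        p = float(2.0 * norm.sf(abs(z)))
    return {"statistic": statistic, "p_value": float(p), "n": n, "degenerate": False}


def residual_summary(truth, pred) -> dict:
    """Residuals (truth - pred) summary on the mL scale + box-plot data."""
    v = np.asarray(truth, dtype=float)
    p = np.asarray(pred, dtype=float)
    r = v - p
    q1, med, q3 = np.quantile(r, [0.25, 0.5, 0.75])
    iqr = q3 - q1
    return {
        "n": len(r),
        "mean": float(r.mean()),
        "sd": float(r.std(ddof=1)) if len(r) > 1 else 0.0,
        "q1": float(q1),
        "median": float(med),
        "q3": float(q3),
        "skew": float(skew(r)) if len(r) > 2 and np.ptp(r) > 0 else 0.0,
        "whisker_low": float(q1 - 1.5 * iqr),
        "whisker_high": float(q3 + 1.5 * iqr),
        "min": float(r.min()),
        "max": float(r.max()),
    }


def iou(box_a, box_b) -> float:
    """Intersection over union of two axis-aligned boxes (xmin, ymin, xmax, ymax)."""
    ax0, ay0, ax1, ay1 = box_a
    bx0, by0, bx1, by1 = box_b
    if ax1 < ax0 or ay1 < ay0 or bx1 < bx0 or by1 < by0:
        raise ValueError("boxes must satisfy min <= max per axis")
    area_a = (ax1 - ax0) * (ay1 - ay0)
    area_b = (bx1 - bx0) * (by1 - by0)
    if area_a == 0 or area_b == 0:
        warnings.warn("degenerate zero-area box in IoU")
        return 0.0
    iw = min(ax1, bx1) - max(ax0, bx0)
    ih = min(ay1, by1) - max(ay0, by0)
    if iw <= 0 or ih <= 0:
        return 0.0
    inter = iw * ih
    return float(inter / (area_a + area_b - inter))


def precision_recall(counts: BoxMatchCounts) -> tuple[float | None, float | None]:
    """Precision = TP/(TP+FP), Recall = TP/(TP+FN); None when undefined."""
    precision = None if counts.tp + counts.fp == 0 else counts.tp / (counts.tp + counts.fp)
    recall = None if counts.tp + counts.fn == 0 else counts.tp / (counts.tp + counts.fn)
    return precision, recall


def _average_precision(records: list[tuple[float, bool]], n_truth: int) -> float:
    """All-points interpolated AP from (score, is_match) records."""
    if n_truth == 0:
        raise ValueError("no ground truth")
    if not records:
        return 0.0
    records = sorted(records, key=lambda r: -r[0])
    tp = np.cumsum([r[1] for r in records])
    fp = np.cumsum([not r[1] for r in records])
    recall = tp / n_truth
    precision = tp / (tp + fp)
    # precision envelope (monotone non-increasing from the right)
    prec_env = np.maximum.accumulate(precision[::-1])[::-1]
    ap, prev_r = 0.0, 0.0
    for r, p in zip(recall, prec_env):
        if r > prev_r:
            ap += (r - prev_r) * p
            prev_r = r
    return float(ap)


def map50(detections, ground_truth, iou_threshold: float = 0.50) -> dict:
    """mAP at a fixed IoU threshold with greedy score-ordered matching.

    ``detections``: iterable of dicts with keys ``box``, ``score``,
    ``label`` and optional ``image_id``; ``ground_truth``: dicts with
    ``box``, ``label``, optional ``image_id``.  Each truth box is matched
    at most once.  Classes with no ground truth are excluded (warning).
    Returns ``{"map": value, "ap_per_class": {label: ap}}``.
    """
    labels = sorted({g["label"] for g in ground_truth})
    det_labels = {d["label"] for d in detections}
    for lab in sorted(det_labels - set(labels)):
        warnings.warn(f"class {lab!r} has detections but no ground truth; excluded")
    if not labels:
        return {"map": 0.0, "ap_per_class": {}}
    ap_per_class = {}
    for lab in labels:
        gts = [g for g in ground_truth if g["label"] == lab]
        dets = sorted(
            (d for d in detections if d["label"] == lab), key=lambda d: -d["score"]
        )
        matched = [False] * len(gts)
        records = []
        for det in dets:
            best_i, best_iou = -1, 0.0
            for i, g in enumerate(gts):
                if matched[i] or g.get("image_id") != det.get("image_id"):
                    continue
                v = iou(det["box"], g["box"])
                if v >= iou_threshold and v > best_iou:
                    best_i, best_iou = i, v
            if best_i >= 0:
                matched[best_i] = True
                records.append((det["score"], True))
            else:
                records.append((det["score"], False))
        ap_per_class[lab] = _average_precision(records, len(gts))
    return {
        "map": float(np.mean(list(ap_per_class.values()))),
        "ap_per_class": ap_per_class,
    }
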