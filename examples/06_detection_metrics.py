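"""Evaluate a two-class fruit/marker detector with IoU, P/R and mAP@50.

These utilities score the bounding-box stage of a measurement rig: greedy
score-ordered matching at IoU >= 0.5, per-class average precision by
all-points interpolation, and the unweighted class mean.
"""

from fruitvol.evaluation import BoxMatchCounts, iou, map50, precision_recall

print(f"IoU of (0,0,2,2) vs (1,1,3,3): {iou((0, 0, 2, 2), (1, 1, 3, 3)):.4f}")

p, r = precision_recall(BoxMatchCounts(tp=3, fp=1, fn=2))
print(f"precision {p:.2f}, recall {r:.2f} for TP=3 FP=1 FN=2")

ground_truth = [
    {"box": (10, 10, 60, 60), "label": "fruit", "image_id": 0},
    {"box": (70, 70, 90, 90), "label": "marker", "image_id": 0},
]
detections = [
    {"box": (12, 11, 59, 61), "label": "fruit", "score": 0.95, "image_id": 0},
    {"box": (71, 70, 89, 91), "label": "marker", "score": 0.90, "image_id": 0},
    {"box": (0, 0, 15, 15), "label": "fruit", "score": 0.30, "image_id": 0},
]
res = map50(detections, ground_truth)
print(f"AP per class: { {k: round(v, 3) for k, v in res['ap_per_class'].items()} }")
print(f"mAP@50 = {res['map']:.3f}")
# Both true objects are matched at high score; the low-score false fruit
# detection costs nothing at the tail of the PR curve, so mAP@50 = 1.0.
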