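"""Detection and classification metrics: confusion rates, ROC-AUC,
region-level FROC, accuracy-weighted two-model ensembling, k-fold splits.

FROC (free-response ROC) evaluates lesion-level detection: for each
score threshold, the fraction of ground-truth regions hit (a detection
centroid falling inside the region) is plotted against the average
number of unmatched detections per image.  A detection can claim at
most one ground-truth region, greedily by score.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Sequence

import numpy as np
from scipy.stats import rankdata


@dataclass
class MetricsReport:
    tp: int
    fp: int
    tn: int
    fn: int
    accuracy: float
    precision: float | None
    recall: float | None
    auc: float | None = None


def confusion_and_rates(predictions: Sequence[int],
                        labels: Sequence[int]) -> MetricsReport:
    """Binary confusion counts and derived rates.

    Precision/recall are ``None`` (absent) when their denominators are
    zero, never silently 0.
    """
    pred = np.asarray(predictions).astype(bool)
    lab = np.asarray(labels).astype(bool)
    if pred.shape != lab.shape or pred.size == 0:
        raise ValueError("predictions and labels must be equal-length and nonempty")
    tp = int((pred & lab).sum())
    fp = int((pred & ~lab).sum())
    tn = int((~pred & ~lab).sum())
    fn = int((~pred & lab).sum())
    accuracy = (tp + tn) / pred.size
    precision = tp / (tp + fp) if tp + fp > 0 else None
    recall = tp / (tp + fn) if tp + fn > 0 else None
    return MetricsReport(tp=tp, fp=fp, tn=tn, fn=fn, accuracy=accuracy,
                         precision=precision, recall=recall)


def roc_auc(scores: Sequence[float], labels: Sequence[int]) -> float:
    """Area under the ROC curve by the Mann-Whitney formulation.

    Ties count one half; equivalent to trapezoidal integration of the
    empirical ROC curve.
    """
    s = np.asarray(scores, dtype=np.float64)
    y = np.asarray(labels).astype(bool)
    n_pos = int(y.sum())
    n_neg = int((~y).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present")
    ranks = rankdata(s)  # average ranks handle ties as 1/2
    auc = (ranks[y].sum() - n_pos * (n_pos + 1) / 2.0) / (n_pos * n_neg)
    return float(auc)


@dataclass(frozen=True)
class FrocPoint:
    threshold: float
    sensitivity: float
    avg_fp_per_image: float


def _hits_at(detections: Sequence[tuple[tuple[float, float], float]],
             gt_regions: Sequence[np.ndarray],
             threshold: float) -> tuple[int, int]:
    """(hits, false positives) on one image at a score threshold.

    Detections are ``(centroid, score)``; ground-truth regions are
    boolean masks or (n, 2) coordinate arrays.  Greedy by score, one
    detection per region.
    """
    live = sorted((d for d in detections if d[1] >= threshold),
                  key=lambda d: -d[1])
    taken = [False] * len(gt_regions)
    hits = fps = 0
    for (cy, cx), _score in live:
        r, c = int(round(cy)), int(round(cx))
        matched = False
        for gi, region in enumerate(gt_regions):
            if taken[gi]:
                continue
            if region.ndim == 2 and region.shape[1] == 2:
                inside = bool(((region[:, 0] == r) & (region[:, 1] == c)).any())
            else:
                inside = (0 <= r < region.shape[0] and 0 <= c < region.shape[1]
                          and bool(region[r, c]))
            if inside:
                taken[gi] = True
                hits += 1
                matched = True
                break
        if not matched:
            fps += 1
    return hits, fps


def froc_curve(detections_per_image: Sequence[Sequence[tuple[tuple[float, float], float]]],
               gt_per_image: Sequence[Sequence[np.ndarray]]) -> list[FrocPoint]:
    """Sweep score thresholds over all images.

    Returns one point per distinct detection score (plus an empty-set
    point above the maximum), ordered by increasing false-positive
    rate.  Sensitivity is hits over total ground-truth regions.
    """
    if len(detections_per_image) != len(gt_per_image) or not gt_per_image:
        raise ValueError("need matching, nonempty per-image lists")
    n_images = len(gt_per_image)
    total_gt = sum(len(g) for g in gt_per_image)
    all_scores = sorted({s for dets in detections_per_image for _, s in dets},
                        reverse=True)
    thresholds = [np.inf] + all_scores
    points = []
    for t in thresholds:
        hits = fps = 0
        for dets, gts in zip(detections_per_image, gt_per_image):
            h, f = _hits_at(dets, [np.asarray(g) for g in gts], t)
            hits += h
            fps += f
        sens = hits / total_gt if total_gt else 0.0
        points.append(FrocPoint(threshold=float(t), sensitivity=sens,
                                avg_fp_per_image=fps / n_images))
    points.sort(key=lambda p: (p.avg_fp_per_image, p.sensitivity))
    return points


@dataclass(frozen=True)
class EnsembleSpec:
    """Two scored models combined with accuracy-proportional weights."""

    weights: tuple[float, float]

    def __post_init__(self) -> None:
        if len(self.weights) != 2:
            raise ValueError("exactly 2 members are combined")
        if any(w <= 0 for w in self.weights):
            raise ValueError("weights must be positive")

    @property
    def normalized(self) -> tuple[float, float]:
        s = sum(self.weights)
        return (self.weights[0] / s, self.weights[1] / s)


def ensemble_scores(spec: EnsembleSpec,
                    scores_a: Sequence[float],
                    scores_b: Sequence[float]) -> np.ndarray:
    """Elementwise weighted mean of two member score lists."""
    a = np.asarray(scores_a, dtype=np.float64)
    b = np.asarray(scores_b, dtype=np.float64)
    if a.shape != b.shape:
        raise ValueError("score lists must be equal length")
    wa, wb = spec.normalized
    return wa * a + wb * b


def kfold_indices(n: int, k: int, seed: int = 0) -> list[np.ndarray]:
    """Seeded shuffle split into k folds whose sizes differ by at most 1."""
    if k < 1 or k > n:
        raise ValueError("need 1 <= k <= n")
    rng = np.random.default_rng(seed)
    order = rng.permutation(n)
    return [np.sort(f) for f in np.array_split(order, k)]
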