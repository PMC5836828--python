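"""Detection metrics and dose-response summaries.

Two complementary views: *region-based* metrics score binarization
pixel-by-pixel; *centroid-based* metrics score detection object-by-object,
counting a prediction as a true positive when its centroid falls within a
matching radius (default 15 px) of an unclaimed ground-truth centroid.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, t as student_t


@dataclass
class MatchResult:
    tp: int
    fp: int
    fn: int
    precision: float
    recall: float
    f1: float
    pairs: list[tuple[int, int]] = field(default_factory=list)
    undefined_precision: bool = False
    undefined_recall: bool = False


def f1_score(precision: float, recall: float) -> float:
    """Harmonic mean of precision and recall (0 when both are 0)."""
    if not (0.0 <= precision <= 1.0 and 0.0 <= recall <= 1.0):
        raise ValueError("precision and recall must lie in [0, 1]")
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def _result(tp: int, fp: int, fn: int,
            pairs: list[tuple[int, int]] | None = None) -> MatchResult:
    undef_p = tp + fp == 0
    undef_r = tp + fn == 0
    precision = 0.0 if undef_p else tp / (tp + fp)
    recall = 0.0 if undef_r else tp / (tp + fn)
    return MatchResult(tp, fp, fn, precision, recall,
                       f1_score(precision, recall), pairs or [],
                       undefined_precision=undef_p, undefined_recall=undef_r)


def region_metrics(pred: np.ndarray, truth: np.ndarray) -> MatchResult:
    """Pixel-wise confusion between two binary masks of the same shape."""
    pred = np.asarray(pred) > 0
    truth = np.asarray(truth) > 0
    if pred.shape != truth.shape:
        raise ValueError(f"shape mismatch: {pred.shape} vs {truth.shape}")
    tp = int(np.sum(pred & truth))
    fp = int(np.sum(pred & ~truth))
    fn = int(np.sum(~pred & truth))
    return _result(tp, fp, fn)


def centroid_match(pred_centroids, truth_centroids, radius: float = 15.0) -> MatchResult:
    """One-to-one greedy matching by increasing centroid distance.

    Pairs closer than ``radius`` are accepted in distance order, each
    centroid used at most once; unmatched predictions are FPs and unmatched
    truths FNs.
    """
    if radius <= 0:
        raise ValueError("radius must be positive")
    pred = np.asarray(list(pred_centroids), dtype=np.float64).reshape(-1, 2)
    truth = np.asarray(list(truth_centroids), dtype=np.float64).reshape(-1, 2)
    if pred.size == 0 or truth.size == 0:
        return _result(0, len(pred), len(truth))
    d = np.linalg.norm(pred[:, None, :] - truth[None, :, :], axis=2)
    candidates = [(d[i, j], i, j)
                  for i in range(len(pred)) for j in range(len(truth))
                  if d[i, j] <= radius]
    candidates.sort()
    used_p: set[int] = set()
    used_t: set[int] = set()
    pairs: list[tuple[int, int]] = []
    for _, i, j in candidates:
        if i in used_p or j in used_t:
            continue
        used_p.add(i)
        used_t.add(j)
        pairs.append((i, j))
    tp = len(pairs)
    return _result(tp, len(pred) - tp, len(truth) - tp, pairs)


def heterogeneity_summary(tdna_values, bins: int = 10) -> dict:
    """Distribution of % DNA in tail across the comets of one image:
    mean, s.d., quartiles and a histogram."""
    values = np.asarray(list(tdna_values), dtype=np.float64)
    if values.size < 2:
        raise ValueError("need at least 2 TDNA values")
    q1, q2, q3 = np.percentile(values, [25, 50, 75])
    counts, edges = np.histogram(values, bins=bins, range=(0.0, 1.0))
    return {
        "n": int(values.size),
        "mean": float(values.mean()),
        "sd": float(values.std(ddof=1)),
        "q1": float(q1), "median": float(q2), "q3": float(q3),
        "hist_counts": counts.tolist(),
        "hist_edges": edges.tolist(),
    }


def equivalent_confidence(n_full: int, n_sub: int, conf_full: float,
                          use_t: bool = False) -> float:
    """Confidence level whose interval at ``n_sub`` comets has the same
    width as the ``conf_full`` interval at ``n_full`` comets.

    Under a normal-theory interval the half-width scales as z / sqrt(n), so
    conf_sub = 2*Phi(z_{conf_full} * sqrt(n_sub / n_full)) - 1.  The
    t-quantile reading (``use_t=True``) solves the same width equation with
    Student quantiles at n-1 degrees of freedom.
    """
    if not 0 < n_sub <= n_full:
        raise ValueError("require 0 < n_sub <= n_full")
    if not 0.0 < conf_full < 1.0:
        raise ValueError("conf_full must lie in (0, 1)")
    shrink = np.sqrt(n_sub / n_full)
    if use_t:
        q = student_t.ppf(0.5 + conf_full / 2.0, df=n_full - 1)
        return float(2.0 * student_t.cdf(q * shrink, df=n_sub - 1) - 1.0)
    z = norm.ppf(0.5 + conf_full / 2.0)
    return float(2.0 * norm.cdf(z * shrink) - 1.0)
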