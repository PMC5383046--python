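"""Discrimination, operating-point, calibration, and subgroup metrics.

AUC is computed in its Mann-Whitney form (probability a random positive
outscores a random negative, ties counted ½) with a DeLong normal-theory
95% confidence interval.  The operating threshold maximizes Youden's J
(sensitivity + specificity − 1) over all distinct scores, predicting
positive at score ≥ threshold; ties resolve to the lowest threshold,
favoring sensitivity.  Calibration is summarized in ten probability-decile
bins, each with the observed infection fraction and a Wilson interval.
The infection label itself is derived from discharge diagnosis codes by
membership in a user-supplied ICD-9-CM abstraction list (exact codes and
prefix patterns).
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import norm, rankdata
from sklearn.metrics import roc_curve
from statsmodels.stats.proportion import proportion_confint

__all__ = [
    "EvalReport",
    "label_infection",
    "compute_auc",
    "auc_ci",
    "delong_variance",
    "youden_threshold",
    "calibration_bins",
    "subgroup_sensitivity",
    "top_weights",
    "evaluate_scores",
]


def _check_two_class(labels: np.ndarray) -> None:
    if len(np.unique(labels)) < 2:
        raise ValueError("metric undefined: labels contain a single class")


def label_infection(icd9_codes, criterion) -> int:
    """1 iff any visit code matches the abstraction criterion.

    ``criterion`` entries are exact codes, or prefixes when suffixed with
    ``*``.  Codes and entries are dot-normalized before comparison, so
    "038.9" and "0389" match.
    """
    criterion = list(criterion)
    if not criterion:
        raise ValueError("criterion code set must be nonempty")
    exact = set()
    prefixes = []
    for entry in criterion:
        entry = str(entry).strip()
        if entry.endswith("*"):
            prefixes.append(entry[:-1].replace(".", ""))
        else:
            exact.add(entry.replace(".", ""))
    for code in icd9_codes:
        norm_code = str(code).strip().replace(".", "")
        if not norm_code:
            continue
        if norm_code in exact or any(norm_code.startswith(p) for p in prefixes):
            return 1
    return 0


def compute_auc(scores, labels) -> float:
    """Mann-Whitney AUC: P(score⁺ > score⁻) + ½ P(score⁺ = score⁻)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    ranks = rankdata(scores)
    n_pos = int(labels.sum())
    n_neg = labels.size - n_pos
    return float((ranks[labels == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


def _delong_components(scores, labels):
    """Per-observation placement values (midrank construction)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = pos.size, neg.size
    all_ranks = rankdata(np.concatenate([pos, neg]))
    pos_ranks = rankdata(pos)
    neg_ranks = rankdata(neg)
    # V10[i] = P(pos_i > random neg), V01[j] = P(random pos > neg_j)
    v10 = (all_ranks[:m] - pos_ranks) / n
    v01 = 1.0 - (all_ranks[m:] - neg_ranks) / m
    return v10, v01


def delong_variance(scores, labels) -> float:
    """DeLong variance estimate of the Mann-Whitney AUC."""
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    v10, v01 = _delong_components(scores, labels)
    m, n = v10.size, v01.size
    s10 = v10.var(ddof=1) if m > 1 else 0.0
    s01 = v01.var(ddof=1) if n > 1 else 0.0
    return float(s10 / m + s01 / n)


def auc_ci(scores, labels, level: float = 0.95) -> tuple[float, float]:
    """Normal-theory DeLong confidence interval, truncated to [0,1]."""
    auc = compute_auc(scores, labels)
    se = float(np.sqrt(delong_variance(scores, labels)))
    z = norm.ppf(0.5 + level / 2)
    return (max(0.0, auc - z * se), min(1.0, auc + z * se))


def youden_threshold(scores, labels) -> tuple[float, float, float, float]:
    """Operating point maximizing Youden's J over all distinct scores.

    Predict positive iff score >= threshold; among tied J values the lowest
    threshold wins (favoring sensitivity).  Returns
    (threshold, ppv, sensitivity, specificity).
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    _check_two_class(labels)
    order = np.argsort(scores)
    s_sorted = scores[order]
    y_sorted = labels[order]
    n_pos = y_sorted.sum()
    n_neg = y_sorted.size - n_pos
    # distinct candidate thresholds, ascending
    distinct_mask = np.r_[True, np.diff(s_sorted) > 0]
    starts = np.flatnonzero(distinct_mask)
    thresholds = s_sorted[starts]
    # positives/negatives strictly below each candidate threshold
    cum_pos = np.r_[0, np.cumsum(y_sorted)]
    cum_neg = np.r_[0, np.cumsum(1 - y_sorted)]
    tp = n_pos - cum_pos[starts]
    fp = n_neg - cum_neg[starts]
    sens = tp / n_pos
    spec = (n_neg - fp) / n_neg
    j = sens + spec - 1.0
    best = int(np.flatnonzero(j >= j.max() - 1e-12)[0])  # lowest threshold
    predicted_pos = tp[best] + fp[best]
    ppv = float(tp[best] / predicted_pos) if predicted_pos > 0 else float("nan")
    return float(thresholds[best]), ppv, float(sens[best]), float(spec[best])


def calibration_bins(probabilities, labels, width: float = 0.1, level: float = 0.95):
    """Observed event fraction per probability bin with Wilson intervals.

    Bins are [0,0.1), ..., [0.9,1.0]; empty bins get count 0 and NaN
    fraction.  Returns a list of dicts (lo, hi, n, observed, ci_low,
    ci_high).
    """
    p = np.asarray(probabilities, dtype=float)
    y = np.asarray(labels).astype(int)
    if np.any((p < 0) | (p > 1)):
        raise ValueError("probabilities must lie in [0,1]")
    edges = np.arange(0.0, 1.0 + width / 2, width)
    idx = np.minimum(np.floor(p / width).astype(int), len(edges) - 2)
    out = []
    for b in range(len(edges) - 1):
        mask = idx == b
        n = int(mask.sum())
        if n == 0:
            out.append(
                {"lo": edges[b], "hi": edges[b + 1], "n": 0,
                 "observed": float("nan"), "ci_low": float("nan"),
                 "ci_high": float("nan")}
            )
            continue
        k = int(y[mask].sum())
        lo, hi = proportion_confint(k, n, alpha=1 - level, method="wilson")
        out.append(
            {"lo": edges[b], "hi": edges[b + 1], "n": n,
             "observed": k / n, "ci_low": float(lo), "ci_high": float(hi)}
        )
    return out


def subgroup_sensitivity(scores, labels, threshold, subgroup_masks) -> dict[str, float]:
    """Sensitivity within each subgroup at a fixed threshold.

    Subgroups with no labeled positives report NaN rather than erroring.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    out = {}
    for name, mask in subgroup_masks.items():
        mask = np.asarray(mask, dtype=bool)
        pos = mask & (labels == 1)
        n_pos = int(pos.sum())
        if n_pos == 0:
            out[name] = float("nan")
            continue
        out[name] = float((scores[pos] >= threshold).sum() / n_pos)
    return out


def top_weights(feature_names, weights, k: int = 10):
    """k most positive and k most negative features by signed weight."""
    weights = np.asarray(weights, dtype=float)
    order = np.argsort(weights)
    k = min(k, weights.size)
    positive = [(feature_names[i], float(weights[i])) for i in order[::-1][:k]]
    negative = [(feature_names[i], float(weights[i])) for i in order[:k]]
    return positive, negative


@dataclass
class EvalReport:
    """Full evaluation of one model on one split."""

    auc: float
    auc_ci: tuple[float, float]
    roc: list[tuple[float, float, float]]
    threshold_star: float
    ppv: float
    sensitivity: float
    specificity: float
    calibration_bins: list[dict] = field(default_factory=list)
    subgroup_sensitivities: dict[str, float] = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "roc": [list(p) for p in self.roc],
            "threshold_star": self.threshold_star,
            "ppv": self.ppv,
            "sensitivity": self.sensitivity,
            "specificity": self.specificity,
            "calibration_bins": self.calibration_bins,
            "subgroup_sensitivities": self.subgroup_sensitivities,
        }


def evaluate_scores(
    scores,
    labels,
    probabilities=None,
    threshold: float | None = None,
    subgroup_masks: dict | None = None,
    max_roc_points: int = 512,
) -> EvalReport:
    """Assemble an :class:`EvalReport` from scores and labels.

    If ``threshold`` is None the Youden-optimal threshold of this split is
    used; otherwise the supplied (e.g. validation-chosen) threshold is
    applied and PPV/sensitivity/specificity are recomputed at it.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels).astype(int)
    auc = compute_auc(scores, labels)
    ci = auc_ci(scores, labels)
    fpr, tpr, thr = roc_curve(labels, scores)
    if fpr.size > max_roc_points:
        keep = np.linspace(0, fpr.size - 1, max_roc_points).astype(int)
        fpr, tpr, thr = fpr[keep], tpr[keep], thr[keep]
    roc = list(zip(fpr.tolist(), tpr.tolist(), thr.tolist()))
    if threshold is None:
        threshold, ppv, sens, spec = youden_threshold(scores, labels)
    else:
        pred = scores >= threshold
        tp = int((pred & (labels == 1)).sum())
        fp = int((pred & (labels == 0)).sum())
        fn = int((~pred & (labels == 1)).sum())
        tn = int((~pred & (labels == 0)).sum())
        ppv = tp / (tp + fp) if tp + fp else float("nan")
        sens = tp / (tp + fn)
        spec = tn / (tn + fp)
    bins = (
        calibration_bins(probabilities, labels) if probabilities is not None else []
    )
    subgroups = (
        subgroup_sensitivity(scores, labels, threshold, subgroup_masks)
        if subgroup_masks
        else {}
    )
    return EvalReport(
        auc=auc,
        auc_ci=ci,
        roc=roc,
        threshold_star=float(threshold),
        ppv=float(ppv),
        sensitivity=float(sens),
        specificity=float(spec),
        calibration_bins=bins,
        subgroup_sensitivities=subgroups,
    )
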