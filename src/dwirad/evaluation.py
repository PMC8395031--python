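"""Discrimination, calibration and clinical-utility statistics.

AUC is the Mann-Whitney pair-concordance probability; its variance and the
paired comparison of two correlated AUCs use DeLong's structural components
(per-positive and per-negative placement values).  Operating points maximize
Youden's J, with case-resampling bootstrap percentile CIs.  Calibration is
decile-grouped observed-vs-predicted with a lowess smooth, and clinical
utility is a decision curve: net benefit TP/n - FP/n * p_t/(1-p_t) against
treat-all and treat-none strategies over a threshold-probability grid.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from statsmodels.nonparametric.smoothers_lowess import lowess

Z95 = 1.959963984540054


@dataclass
class EvaluationReport:
    """AUC and operating-point summary for one model on one cohort."""

    auc: float
    auc_ci: tuple[float, float]
    sensitivity: float
    sensitivity_ci: tuple[float, float]
    specificity: float
    specificity_ci: tuple[float, float]
    accuracy: float
    accuracy_ci: tuple[float, float]
    cutoff: float
    n_pos: int
    n_neg: int
    degenerate_auc_variance: bool = False

    def to_dict(self) -> dict:
        return {
            "auc": self.auc,
            "auc_ci": list(self.auc_ci),
            "sensitivity": self.sensitivity,
            "sensitivity_ci": list(self.sensitivity_ci),
            "specificity": self.specificity,
            "specificity_ci": list(self.specificity_ci),
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "cutoff": self.cutoff,
            "n_pos": self.n_pos,
            "n_neg": self.n_neg,
        }


@dataclass
class DcaCurve:
    thresholds: np.ndarray
    net_benefit_model: np.ndarray
    net_benefit_all: np.ndarray
    net_benefit_none: np.ndarray = field(default=None)

    def __post_init__(self):
        if self.net_benefit_none is None:
            self.net_benefit_none = np.zeros_like(self.thresholds)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "threshold": self.thresholds,
                "model": self.net_benefit_model,
                "treat_all": self.net_benefit_all,
                "treat_none": self.net_benefit_none,
            }
        )


def percent(numerator: float, denominator: float) -> float:
    """A rate as a percentage (e.g. 75 of 167 -> 44.91...)."""
    if denominator == 0:
        raise ValueError("zero denominator")
    return 100.0 * numerator / denominator


def _split(scores, labels):
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be nonempty")
    return pos, neg


def auc_mann_whitney(scores, labels) -> float:
    """AUC = P(score+ > score-) + 0.5 P(tie) over all positive-negative pairs."""
    pos, neg = _split(scores, labels)
    order = np.sort(neg)
    below = np.searchsorted(order, pos, side="left")
    ties = np.searchsorted(order, pos, side="right") - below
    return float((below.sum() + 0.5 * ties.sum()) / (pos.size * neg.size))


def _placements(pos: np.ndarray, neg: np.ndarray):
    """DeLong structural components: per-positive and per-negative placements."""
    sneg = np.sort(neg)
    below = np.searchsorted(sneg, pos, side="left")
    ties = np.searchsorted(sneg, pos, side="right") - below
    v10 = (below + 0.5 * ties) / neg.size
    spos = np.sort(pos)
    above = pos.size - np.searchsorted(spos, neg, side="right")
    ties_n = np.searchsorted(spos, neg, side="right") - np.searchsorted(
        spos, neg, side="left"
    )
    v01 = (above + 0.5 * ties_n) / pos.size
    return v10, v01


def delong_variance(scores, labels) -> float:
    pos, neg = _split(scores, labels)
    if pos.size < 2 or neg.size < 2:
        raise ValueError("need at least 2 cases per class")
    v10, v01 = _placements(pos, neg)
    return float(np.var(v10, ddof=1) / pos.size + np.var(v01, ddof=1) / neg.size)


def delong_ci(scores, labels, level: float = 0.95):
    """AUC with a DeLong normal-approximation CI truncated to [0, 1].

    Perfect separation yields zero structural variance; the CI then collapses
    to the point estimate and the report is flagged.
    """
    auc = auc_mann_whitney(scores, labels)
    var = delong_variance(scores, labels)
    degenerate = var <= 0
    z = stats.norm.ppf(0.5 + level / 2.0)
    half = z * np.sqrt(max(var, 0.0))
    return (
        auc,
        float(np.clip(auc - half, 0.0, 1.0)),
        float(np.clip(auc + half, 0.0, 1.0)),
        degenerate,
    )


def delong_paired_test(scores_a, scores_b, labels):
    """Paired DeLong comparison of two correlated AUCs on the same cases."""
    scores_a = np.asarray(scores_a, dtype=float)
    scores_b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels)
    if scores_a.shape != scores_b.shape or scores_a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors must cover the same cases")
    pos_a, neg_a = _split(scores_a, labels)
    pos_b, neg_b = _split(scores_b, labels)
    v10a, v01a = _placements(pos_a, neg_a)
    v10b, v01b = _placements(pos_b, neg_b)
    auc_a = float(v10a.mean())
    auc_b = float(v10b.mean())
    m, n = pos_a.size, neg_a.size
    s10 = np.cov(np.vstack([v10a, v10b]), ddof=1)
    s01 = np.cov(np.vstack([v01a, v01b]), ddof=1)
    var = (s10[0, 0] + s10[1, 1] - 2 * s10[0, 1]) / m + (
        s01[0, 0] + s01[1, 1] - 2 * s01[0, 1]
    ) / n
    diff = auc_a - auc_b
    if var <= 0:
        z = 0.0 if diff == 0 else np.sign(diff) * np.inf
    else:
        z = diff / np.sqrt(var)
    p = float(2.0 * stats.norm.sf(abs(z))) if np.isfinite(z) else 0.0
    if diff == 0:
        z, p = 0.0, 1.0
    return auc_a, auc_b, float(z), p


# ---------------------------------------------------------------------------
# operating point


def _candidate_cutoffs(scores: np.ndarray) -> np.ndarray:
    u = np.unique(scores)
    mids = (u[:-1] + u[1:]) / 2.0
    return np.concatenate([[u[0] - 1.0], mids, [u[-1] + 1.0]])


def _confusion_rates(scores, labels, cutoff):
    pred = scores >= cutoff
    pos = labels == 1
    tp = np.sum(pred & pos)
    tn = np.sum(~pred & ~pos)
    sens = tp / pos.sum()
    spec = tn / (~pos).sum()
    acc = (tp + tn) / labels.size
    return float(sens), float(spec), float(acc)


def youden_cutoff(scores: np.ndarray, labels: np.ndarray) -> float:
    """Cutoff maximizing sensitivity + specificity - 1; ties -> lowest cutoff."""
    best_cut, best_j = None, -np.inf
    for cut in _candidate_cutoffs(np.asarray(scores, dtype=float)):
        sens, spec, _ = _confusion_rates(scores, labels, cut)
        j = sens + spec - 1.0
        if j > best_j + 1e-12:
            best_j, best_cut = j, cut
    return float(best_cut)


def operating_point(
    scores, labels, n_bootstrap: int = 2000, seed: int = 0
) -> EvaluationReport:
    """Youden operating point with bootstrap percentile CIs and DeLong AUC CI.

    The bootstrap resamples cases within each class (class sizes preserved)
    and re-estimates the cutoff on every resample.
    """
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels)
    pos_idx = np.flatnonzero(labels == 1)
    neg_idx = np.flatnonzero(labels == 0)
    if pos_idx.size == 0 or neg_idx.size == 0:
        raise ValueError("both classes must be nonempty")

    cutoff = youden_cutoff(scores, labels)
    sens, spec, acc = _confusion_rates(scores, labels, cutoff)
    auc, lo, hi, degenerate = delong_ci(scores, labels)

    rng = np.random.default_rng(seed)
    boot = np.empty((n_bootstrap, 3))
    for i in range(n_bootstrap):
        idx = np.concatenate(
            [
                rng.choice(pos_idx, pos_idx.size, replace=True),
                rng.choice(neg_idx, neg_idx.size, replace=True),
            ]
        )
        s, y = scores[idx], labels[idx]
        boot[i] = _confusion_rates(s, y, youden_cutoff(s, y))
    ci = np.percentile(boot, [2.5, 97.5], axis=0)

    return EvaluationReport(
        auc=auc,
        auc_ci=(lo, hi),
        sensitivity=sens,
        sensitivity_ci=(float(ci[0, 0]), float(ci[1, 0])),
        specificity=spec,
        specificity_ci=(float(ci[0, 1]), float(ci[1, 1])),
        accuracy=acc,
        accuracy_ci=(float(ci[0, 2]), float(ci[1, 2])),
        cutoff=cutoff,
        n_pos=int(pos_idx.size),
        n_neg=int(neg_idx.size),
        degenerate_auc_variance=degenerate,
    )


# ---------------------------------------------------------------------------
# calibration and decision curves


def calibration_curve(probabilities, labels, n_groups: int = 10):
    """Quantile-grouped predicted vs observed rates plus a lowess smooth."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    if labels.size < n_groups:
        n_groups = max(2, labels.size // 2)
        warnings.warn(f"few cases; reducing calibration groups to {n_groups}",
                      stacklevel=2)
    frame = pd.DataFrame({"p": probabilities, "y": labels})
    if np.ptp(probabilities) == 0:
        grouped = pd.DataFrame(
            {
                "predicted": [probabilities.mean()],
                "observed": [labels.mean()],
                "n": [labels.size],
            }
        )
    else:
        bins = pd.qcut(frame["p"], q=n_groups, duplicates="drop")
        agg = frame.groupby(bins, observed=True).agg(
            predicted=("p", "mean"), observed=("y", "mean"), n=("y", "size")
        )
        grouped = agg.reset_index(drop=True)
    smooth = lowess(labels, probabilities, frac=0.6, return_sorted=True)
    smoothed = pd.DataFrame({"predicted": smooth[:, 0], "observed": smooth[:, 1]})
    return grouped, smoothed


def decision_curve(probabilities, labels, thresholds=None) -> DcaCurve:
    """Net benefit of treating above each threshold probability p_t."""
    probabilities = np.asarray(probabilities, dtype=float)
    labels = np.asarray(labels, dtype=float)
    if thresholds is None:
        thresholds = np.arange(0.01, 1.0, 0.01)
    thresholds = np.asarray(thresholds, dtype=float)
    if (thresholds <= 0).any() or (thresholds >= 1).any():
        raise ValueError("threshold grid must lie strictly inside (0, 1)")
    if probabilities.min() < 0 or probabilities.max() > 1:
        raise ValueError("probabilities must lie in [0, 1]")
    n = labels.size
    prevalence = labels.mean()
    odds = thresholds / (1.0 - thresholds)
    nb_model = np.empty_like(thresholds)
    for i, (t, o) in enumerate(zip(thresholds, odds)):
        treat = probabilities >= t
        tp = np.sum(treat & (labels == 1))
        fp = np.sum(treat & (labels == 0))
        nb_model[i] = tp / n - fp / n * o
    nb_all = prevalence - (1.0 - prevalence) * odds
    return DcaCurve(
        thresholds=thresholds, net_benefit_model=nb_model, net_benefit_all=nb_all
    )


# ---------------------------------------------------------------------------
# cohort-description statistics


def chi_square_2x2(a: int, b: int, c: int, d: int):
    """Pearson chi-square (no continuity correction) on the 2x2 table
    [[a, b], [c, d]]; df = 1."""
    table = np.array([[a, b], [c, d]], dtype=float)
    if (table < 0).any():
        raise ValueError("counts must be nonnegative")
    if (table.sum(axis=0) == 0).any() or (table.sum(axis=1) == 0).any():
        raise ValueError("zero margin in the 2x2 table")
    chi2, p, _, _ = stats.chi2_contingency(table, correction=False)
    return float(chi2), float(p)


def two_sample_t(group_a, group_b):
    """Welch's two-sided t-test (unequal variances)."""
    a = np.asarray(group_a, dtype=float)
    b = np.asarray(group_b, dtype=float)
    if a.size < 2 or b.size < 2:
        raise ValueError("each group needs at least 2 observations")
    if a.std(ddof=1) == 0 and b.std(ddof=1) == 0:
        if a.mean() == b.mean():
            warnings.warn("zero variance in both groups; p defined as 1",
                          stacklevel=2)
            return 0.0, 1.0
        return np.inf * np.sign(a.mean() - b.mean()), 0.0
    t, p = stats.ttest_ind(a, b, equal_var=False)
    return float(t), float(p)
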