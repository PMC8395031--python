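"""Three-step feature selection: Wilcoxon screen, MRMR, backward stepwise AIC.

Step 1 keeps features whose two-sided Wilcoxon rank-sum p-value between the
two label groups is strictly below 0.1 (normal approximation with mid-rank
tie correction and continuity correction; exact permutation enumeration for
tiny samples).  Step 2 greedily picks 20 features maximizing mutual
information with the label minus the mean mutual information with the
already-selected set (the MID difference criterion, on equal-frequency
8-bin discretized features).  Step 3 fits a logistic model on the survivors
and removes one feature at a time, always the removal that most decreases
the AIC, until no removal decreases it.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .features import FeatureTable
from .models import fit_logistic

EXACT_WILCOXON_MAX_N = 12


@dataclass(frozen=True)
class SelectionConfig:
    wilcoxon_alpha: float = 0.1
    mrmr_k: int = 20
    mrmr_bins: int = 8
    mrmr_variant: str = "MID"  # or "MIQ"
    region: str = "combined"  # {intra, peri, combined}

    def validate(self) -> None:
        if not 0.0 < self.wilcoxon_alpha < 1.0:
            raise ValueError("wilcoxon_alpha must lie in (0, 1)")
        if self.mrmr_k < 1:
            raise ValueError("mrmr_k must be >= 1")
        if self.mrmr_variant not in ("MID", "MIQ"):
            raise ValueError("mrmr_variant must be MID or MIQ")


@dataclass
class SelectionTrace:
    """Audit record of the three stages (names nest: final in mrmr in screened)."""

    screened: pd.Series  # p-values indexed by screened feature name
    mrmr_names: list[str] = field(default_factory=list)
    final_names: list[str] = field(default_factory=list)
    aic_path: list[float] = field(default_factory=list)

    def to_dict(self) -> dict:
        return {
            "screened": {k: float(v) for k, v in self.screened.items()},
            "mrmr_names": list(self.mrmr_names),
            "final_names": list(self.final_names),
            "aic_path": [float(a) for a in self.aic_path],
        }


# ---------------------------------------------------------------------------
# step 1: Wilcoxon rank-sum screen


def _exact_ranksum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided p by full enumeration of label assignments (small n only)."""
    pooled = np.concatenate([x, y])
    n, nx = pooled.size, x.size
    ranks = stats.rankdata(pooled)  # mid-ranks
    observed = ranks[:nx].sum()
    mu = nx * (n + 1) / 2.0
    obs_dev = abs(observed - mu)
    count = 0
    total = 0
    for combo in itertools.combinations(range(n), nx):
        total += 1
        if abs(ranks[list(combo)].sum() - mu) >= obs_dev - 1e-12:
            count += 1
    return count / total


def rank_sum_p(x: np.ndarray, y: np.ndarray) -> float:
    """Two-sided Wilcoxon rank-sum p-value for one feature."""
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size == 0 or y.size == 0:
        raise ValueError("both groups must be nonempty")
    if np.ptp(np.concatenate([x, y])) == 0:
        return 1.0  # no rank separation at all
    if x.size + y.size <= EXACT_WILCOXON_MAX_N:
        return _exact_ranksum_p(x, y)
    res = stats.mannwhitneyu(
        x, y, alternative="two-sided", method="asymptotic", use_continuity=True
    )
    return float(res.pvalue)


def wilcoxon_screen(
    table: FeatureTable, labels: np.ndarray, alpha: float = 0.1
) -> tuple[list[str], pd.Series]:
    """Per-feature rank-sum test; keep features with p strictly below alpha."""
    labels = np.asarray(labels)
    if len(np.unique(labels)) < 2:
        raise ValueError("labels contain a single class")
    x = table.data.to_numpy()
    pos = x[labels == 1]
    neg = x[labels == 0]
    if pos.shape[0] + neg.shape[0] <= EXACT_WILCOXON_MAX_N:
        pvals = [rank_sum_p(pos[:, j], neg[:, j]) for j in range(x.shape[1])]
    else:
        res = stats.mannwhitneyu(
            pos, neg, alternative="two-sided", method="asymptotic",
            use_continuity=True, axis=0,
        )
        pvals = np.asarray(res.pvalue, dtype=float)
        # a feature constant across both groups has no rank separation
        constant = np.ptp(x, axis=0) == 0
        pvals = np.where(constant, 1.0, pvals)
    pvalues = pd.Series(pvals, index=table.data.columns)
    kept = pvalues.index[pvalues < alpha].tolist()
    return kept, pvalues


# ---------------------------------------------------------------------------
# step 2: MRMR (MID criterion, discretized mutual information)


def discretize_equal_frequency(values: np.ndarray, bins: int = 8) -> np.ndarray:
    """Equal-frequency binning; duplicate quantile edges collapse."""
    edges = np.unique(np.quantile(values, np.linspace(0, 1, bins + 1)[1:-1]))
    return np.searchsorted(edges, values, side="right")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) between two discrete label arrays via the contingency table."""
    a = np.asarray(a, dtype=np.int64)
    b = np.asarray(b, dtype=np.int64)
    na, nb = int(a.max()) + 1, int(b.max()) + 1
    table = np.bincount(a * nb + b, minlength=na * nb).reshape(na, nb).astype(float)
    p = table / table.sum()
    pi = p.sum(axis=1, keepdims=True)
    pj = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float((p[nz] * np.log(p[nz] / (pi @ pj)[nz])).sum())


def mrmr_select(
    table: FeatureTable,
    labels: np.ndarray,
    k: int = 20,
    bins: int = 8,
    variant: str = "MID",
) -> list[str]:
    """Greedy minimum-redundancy maximum-relevance selection, in pick order.

    Relevance is MI(feature; label); redundancy the mean MI with the selected
    set.  MID maximizes relevance - redundancy, MIQ relevance / redundancy.
    Returns min(k, #candidates) names (with a warning when the pool is short).
    """
    labels = np.asarray(labels)
    if set(np.unique(labels)) - {0, 1}:
        raise ValueError("labels must be binary 0/1")
    names = list(table.data.columns)
    if not names:
        raise ValueError("no candidate features")
    if k > len(names):
        warnings.warn(
            f"mrmr_k={k} exceeds the candidate pool ({len(names)}); returning all",
            stacklevel=2,
        )
    disc = {
        name: discretize_equal_frequency(table.data[name].to_numpy(), bins)
        for name in names
    }
    relevance = {name: mutual_information(disc[name], labels) for name in names}

    selected: list[str] = []
    redundancy_sum = dict.fromkeys(names, 0.0)
    while names and len(selected) < k:
        best_name, best_score = None, -np.inf
        for name in names:
            if selected:
                red = redundancy_sum[name] / len(selected)
                if variant == "MID":
                    score = relevance[name] - red
                else:  # MIQ
                    score = relevance[name] / max(red, 1e-12)
            else:
                score = relevance[name]
            # strict > keeps the first (stable) name on ties
            if score > best_score + 1e-15:
                best_name, best_score = name, score
        selected.append(best_name)
        names.remove(best_name)
        for name in names:
            redundancy_sum[name] += mutual_information(disc[name], disc[best_name])
    return selected


# ---------------------------------------------------------------------------
# step 3: backward stepwise elimination on AIC


def backward_stepwise(
    table: FeatureTable, labels: np.ndarray
) -> tuple[list[str], list[float]]:
    """Backward elimination from the full logistic model, guided by AIC.

    At each round the single feature whose removal most decreases the AIC is
    dropped (ties broken by lexicographic name); the procedure stops when no
    removal decreases AIC.  The returned path holds the AIC after the initial
    fit and after each accepted elimination; an empty final list means the
    intercept-only model won.
    """
    labels = np.asarray(labels)
    current = sorted(table.data.columns)
    model = fit_logistic(table.data[current], labels)
    aic_path = [model.aic]
    while current:
        best_aic, best_drop = aic_path[-1], None
        for name in current:  # lexicographic order -> deterministic ties
            reduced = [c for c in current if c != name]
            cand = fit_logistic(table.data[reduced], labels)
            if cand.aic < best_aic - 1e-10:
                best_aic, best_drop = cand.aic, name
        if best_drop is None:
            break
        current.remove(best_drop)
        aic_path.append(best_aic)
    return current, aic_path


# ---------------------------------------------------------------------------
# pipeline


def select_features(
    table: FeatureTable, labels: np.ndarray, config: SelectionConfig = SelectionConfig()
) -> SelectionTrace:
    """Run the three stages in order and return the audit trace."""
    config.validate()
    kept, pvalues = wilcoxon_screen(table, labels, config.wilcoxon_alpha)
    trace = SelectionTrace(screened=pvalues[kept])
    if not kept:
        return trace
    screened_table = FeatureTable(table.data[kept])
    trace.mrmr_names = mrmr_select(
        screened_table, labels, config.mrmr_k, config.mrmr_bins, config.mrmr_variant
    )
    mrmr_table = FeatureTable(table.data[trace.mrmr_names])
    trace.final_names, trace.aic_path = backward_stepwise(mrmr_table, labels)
    return trace
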