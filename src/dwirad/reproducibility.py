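"""ICC-based feature stability filtering across two readers.

Features are extracted twice, from two readers' segmentations of the same
cases; per-feature agreement is quantified by the two-way random-effects,
absolute-agreement, single-measurement intraclass correlation, ICC(2,1),
computed from the ANOVA mean squares.  Features with ICC strictly greater
than 0.8 are retained.  The consistency form ICC(3,1) is available as an
alternative.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .features import FeatureTable

ICC_THRESHOLD = 0.8


@dataclass
class IccResult:
    feature_name: str
    icc: float
    retained: bool
    degenerate: bool = False


def _anova_mean_squares(a: np.ndarray, b: np.ndarray):
    """Per-column two-way ANOVA mean squares for an n x 2 x F layout."""
    x = np.stack([a, b], axis=1)  # (n, 2, F)
    n, k, _ = x.shape
    grand = x.mean(axis=(0, 1))
    row_means = x.mean(axis=1)  # (n, F)
    col_means = x.mean(axis=0)  # (k, F)
    ssr = k * ((row_means - grand) ** 2).sum(axis=0)
    ssc = n * ((col_means - grand) ** 2).sum(axis=0)
    sst = ((x - grand) ** 2).sum(axis=(0, 1))
    sse = np.clip(sst - ssr - ssc, 0.0, None)
    msr = ssr / (n - 1)
    msc = ssc / (k - 1)
    mse = sse / ((n - 1) * (k - 1))
    return msr, msc, mse, n, k


def icc_two_way_random(
    rater_a: np.ndarray, rater_b: np.ndarray, form: str = "2,1"
) -> np.ndarray:
    """ICC for one or many features measured by two raters on the same cases.

    ``rater_a``/``rater_b`` are (n,) or (n, F); returns a scalar array of
    ICCs (NaN where the ANOVA denominator is zero, i.e. no variance at all).
    Form "2,1" is absolute agreement; "3,1" is consistency.
    """
    a = np.atleast_2d(np.asarray(rater_a, dtype=float).T).T
    b = np.atleast_2d(np.asarray(rater_b, dtype=float).T).T
    if a.shape != b.shape:
        raise ValueError("rater arrays must have identical shape")
    if a.shape[0] < 3:
        raise ValueError("ICC needs at least 3 cases")
    msr, msc, mse, n, k = _anova_mean_squares(a, b)
    with np.errstate(divide="ignore", invalid="ignore"):
        if form == "2,1":
            denom = msr + (k - 1) * mse + (k / n) * (msc - mse)
        elif form == "3,1":
            denom = msr + (k - 1) * mse
        else:
            raise ValueError(f"unknown ICC form {form!r}")
        icc = (msr - mse) / denom
    icc = np.where(denom <= 0, np.nan, icc)
    return icc if np.asarray(rater_a).ndim > 1 else float(icc[0])


def icc_filter(
    table_a: FeatureTable,
    table_b: FeatureTable,
    threshold: float = ICC_THRESHOLD,
    form: str = "2,1",
) -> tuple[list[str], pd.DataFrame]:
    """Per-feature ICC over two readers; retain features with ICC > threshold.

    Returns the retained names and a report frame (feature, icc, retained,
    degenerate).  Shape features are evaluated like all others.  Case sets
    and columns must agree.
    """
    if list(table_a.data.index) != list(table_b.data.index):
        raise ValueError("case sets differ between the two readers' tables")
    if list(table_a.data.columns) != list(table_b.data.columns):
        raise ValueError("feature columns differ between the two readers' tables")
    icc = icc_two_way_random(table_a.data.to_numpy(), table_b.data.to_numpy(), form)
    degenerate = np.isnan(icc)
    retained = ~degenerate & (icc > threshold)
    report = pd.DataFrame(
        {
            "feature": table_a.data.columns,
            "icc": icc,
            "retained": retained,
            "degenerate": degenerate,
        }
    )
    names = report.loc[report["retained"], "feature"].tolist()
    return names, report
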