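"""Logistic modeling: rad-scores, clinical screening, and the nomogram.

A rad-score is the linear predictor (intercept + sum of coefficient x
feature) of a logistic model fitted over the selected radiomic features of a
region; intratumoral, peritumoral and combined selections yield the intra-,
peri- and com-rad-scores.  Clinical covariates and the com-rad-score are
screened by univariate logistic regression (p < 0.05), survivors enter a
multivariate fit, and the multivariate p < 0.05 survivors become the
independent predictors of the nomogram — a points-scale re-parameterization
of that final logistic model.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm
from scipy import stats
from scipy.special import expit


@dataclass
class LogisticModel:
    """Fitted logistic regression with its estimation metadata."""

    feature_names: list[str]
    coefficients: pd.Series  # indexed by feature name
    intercept: float
    aic: float
    llf: float
    n_obs: int
    converged: bool = True
    separation: bool = False
    covariance: pd.DataFrame | None = None  # includes the intercept row/col
    bse: pd.Series | None = None  # standard errors incl. intercept
    pvalues: pd.Series | None = None

    def linear_predictor(self, features: pd.DataFrame | pd.Series) -> np.ndarray:
        return rad_score(self, features)

    def predict_proba(self, features: pd.DataFrame | pd.Series) -> np.ndarray:
        return expit(self.linear_predictor(features))

    def to_dict(self) -> dict:
        return {
            "feature_names": self.feature_names,
            "coefficients": {k: float(v) for k, v in self.coefficients.items()},
            "intercept": float(self.intercept),
            "aic": float(self.aic),
            "n_obs": int(self.n_obs),
            "converged": bool(self.converged),
            "separation": bool(self.separation),
        }


@dataclass
class AssociationResult:
    """Odds ratio with Wald 95% CI and p-value for one parameter."""

    parameter: str
    odds_ratio: float
    ci_low: float
    ci_high: float
    p_value: float
    separation: bool = False


def _check_design(design: pd.DataFrame, labels: np.ndarray) -> None:
    classes = np.unique(labels)
    if len(classes) < 2:
        raise ValueError("labels contain a single class")
    if not set(classes) <= {0, 1}:
        raise ValueError("labels must be coded 0/1")
    if design.shape[0] <= design.shape[1] + 1:
        raise ValueError(
            f"too few observations ({design.shape[0]}) for "
            f"{design.shape[1]} parameters plus intercept"
        )
    if design.shape[1] > 1:
        x = np.column_stack([np.ones(len(design)), design.to_numpy()])
        rank = np.linalg.matrix_rank(x)
        if rank < x.shape[1]:
            _, r = np.linalg.qr(x)
            diag = np.abs(np.diag(r))
            bad = diag < 1e-10 * diag.max()
            names = [
                (["const"] + list(design.columns))[i]
                for i in np.flatnonzero(bad)
            ]
            raise ValueError(f"rank-deficient design; collinear columns: {names}")


def _firth_fit(x: np.ndarray, y: np.ndarray, max_iter: int = 150, tol: float = 1e-8):
    """Firth's Jeffreys-prior penalized logistic fit (always finite).

    Maximizes llf + 0.5 log|I(beta)|; returns (beta, covariance,
    penalized llf).  The hat-diagonal correction h (0.5 - mu) keeps the score
    bounded, so coefficients stay finite under complete separation.
    """
    n, p = x.shape
    beta = np.zeros(p)
    for _ in range(max_iter):
        eta = x @ beta
        mu = expit(eta)
        w = np.clip(mu * (1.0 - mu), 1e-12, None)
        xw = x * w[:, None]
        info = x.T @ xw
        try:
            info_inv = np.linalg.inv(info)
        except np.linalg.LinAlgError:
            info_inv = np.linalg.pinv(info)
        # hat diagonal of W^1/2 X I^-1 X' W^1/2
        h = np.einsum("ij,jk,ik->i", x * np.sqrt(w)[:, None], info_inv,
                      x * np.sqrt(w)[:, None])
        score = x.T @ (y - mu + h * (0.5 - mu))
        step = info_inv @ score
        # damped Newton: halve until the step is modest
        while np.max(np.abs(step)) > 5.0:
            step *= 0.5
        beta = beta + step
        if np.max(np.abs(step)) < tol:
            break
    eta = x @ beta
    mu = np.clip(expit(eta), 1e-12, 1 - 1e-12)
    llf = float(np.sum(y * np.log(mu) + (1 - y) * np.log(1 - mu)))
    w = np.clip(mu * (1.0 - mu), 1e-12, None)
    info = x.T @ (x * w[:, None])
    sign, logdet = np.linalg.slogdet(info)
    pen_llf = llf + 0.5 * (logdet if sign > 0 else -np.inf)
    cov = np.linalg.pinv(info)
    return beta, cov, pen_llf


def fit_logistic(design: pd.DataFrame, labels: np.ndarray) -> LogisticModel:
    """Maximum-likelihood logistic fit with a Firth fallback on separation.

    The primary path is IRLS (statsmodels Logit).  Non-convergence, exploding
    coefficients or non-finite standard errors are treated as (quasi-)complete
    separation, where the MLE does not exist: the model is refit with Firth's
    Jeffreys-prior penalty and flagged, keeping coefficients, standard errors
    and the (penalized-likelihood) AIC finite and comparable so that small
    synthetic cohorts remain runnable and AIC-guided elimination cannot be
    gamed by a separating subset.  An empty design fits the intercept-only
    model.
    """
    design = pd.DataFrame(design)
    labels = np.asarray(labels, dtype=float)
    _check_design(design, labels)
    names = list(design.columns)
    x = sm.add_constant(design.to_numpy(), has_constant="add")
    n = len(labels)

    fitted = None
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        try:
            res = sm.Logit(labels, x).fit(disp=0, maxiter=200)
            ok = (
                res.mle_retvals.get("converged", False)
                and np.all(np.isfinite(res.params))
                and np.max(np.abs(res.params)) < 50.0
                and np.all(np.isfinite(res.bse))
            )
            if ok:
                idx = ["const"] + names
                fitted = LogisticModel(
                    feature_names=names,
                    coefficients=pd.Series(res.params[1:], index=names),
                    intercept=float(res.params[0]),
                    aic=float(res.aic),
                    llf=float(res.llf),
                    n_obs=n,
                    converged=True,
                    covariance=pd.DataFrame(
                        res.cov_params(), index=idx, columns=idx
                    ),
                    bse=pd.Series(res.bse, index=idx),
                    pvalues=pd.Series(res.pvalues, index=idx),
                )
        except Exception:
            fitted = None

    if fitted is not None:
        return fitted

    beta, cov, pen_llf = _firth_fit(x, labels)
    idx = ["const"] + names
    bse = np.sqrt(np.clip(np.diag(cov), 0.0, None))
    with np.errstate(divide="ignore", invalid="ignore"):
        zstats = np.where(bse > 0, beta / bse, np.inf)
    pvals = 2.0 * stats.norm.sf(np.abs(zstats))
    return LogisticModel(
        feature_names=names,
        coefficients=pd.Series(beta[1:], index=names),
        intercept=float(beta[0]),
        aic=2.0 * (len(names) + 1) - 2.0 * pen_llf,
        llf=pen_llf,
        n_obs=n,
        converged=True,
        separation=True,
        covariance=pd.DataFrame(cov, index=idx, columns=idx),
        bse=pd.Series(bse, index=idx),
        pvalues=pd.Series(pvals, index=idx),
    )


def rad_score(
    model: LogisticModel,
    features: pd.DataFrame | pd.Series,
    include_intercept: bool = True,
) -> np.ndarray:
    """The linear predictor beta0 + sum(beta_i x_i) of a fitted model."""
    if isinstance(features, pd.Series):
        features = features.to_frame().T
    missing = [f for f in model.feature_names if f not in features.columns]
    if missing:
        raise ValueError(f"missing features: {missing}")
    x = features[model.feature_names].to_numpy(dtype=float)
    eta = x @ model.coefficients.to_numpy() if model.feature_names else np.zeros(len(x))
    if include_intercept:
        eta = eta + model.intercept
    return eta


def univariate_odds(
    factor: np.ndarray, labels: np.ndarray, name: str = "factor"
) -> AssociationResult:
    """Single-predictor logistic fit: OR = exp(beta), Wald CI and p-value."""
    factor = np.asarray(factor, dtype=float)
    if np.ptp(factor) == 0:
        raise ValueError(f"factor {name!r} has a single level")
    model = fit_logistic(pd.DataFrame({name: factor}), labels)
    beta = float(model.coefficients[name])
    se = float(model.bse[name])
    return AssociationResult(
        parameter=name,
        odds_ratio=float(np.exp(beta)),
        ci_low=float(np.exp(beta - 1.959963984540054 * se)),
        ci_high=float(np.exp(beta + 1.959963984540054 * se)),
        p_value=float(model.pvalues[name]),
        separation=model.separation,
    )


# ---------------------------------------------------------------------------
# nomogram

CLINICAL_ENCODING = {
    "age_group": (">=40", "age_ge40"),
    "er": ("positive", "er_positive"),
    "pr": ("positive", "pr_positive"),
    "ki67": (">=14%", "ki67_ge14"),
}


def encode_clinical(frame: pd.DataFrame) -> pd.DataFrame:
    """Binary 0/1 encoding of the clinical table (reference category = 0)."""
    out = {}
    for column, (positive_level, new_name) in CLINICAL_ENCODING.items():
        out[new_name] = (frame[column] == positive_level).astype(float)
    return pd.DataFrame(out, index=frame.index)


@dataclass
class NomogramModel:
    """Final multivariate logistic model plus the audit of its selection."""

    model: LogisticModel
    predictors: list[str]
    data_ranges: pd.DataFrame  # min/max per predictor over the training data
    univariate: list[AssociationResult] = field(default_factory=list)
    multivariate: list[AssociationResult] = field(default_factory=list)

    def predict_proba(self, features: pd.DataFrame) -> np.ndarray:
        return self.model.predict_proba(features)


def _wald_results(model: LogisticModel) -> list[AssociationResult]:
    out = []
    for name in model.feature_names:
        beta = float(model.coefficients[name])
        se = float(model.bse[name]) if model.bse is not None else np.inf
        z = 1.959963984540054
        out.append(
            AssociationResult(
                parameter=name,
                odds_ratio=float(np.exp(beta)),
                ci_low=float(np.exp(beta - z * se)),
                ci_high=float(np.exp(beta + z * se)),
                p_value=(
                    float(model.pvalues[name]) if model.pvalues is not None else np.nan
                ),
                separation=model.separation,
            )
        )
    return out


def build_nomogram(
    clinical: pd.DataFrame,
    comrad: np.ndarray,
    labels: np.ndarray,
    alpha: float = 0.05,
) -> NomogramModel:
    """Screen candidates univariately, fit survivors jointly, keep p < alpha.

    ``clinical`` holds the raw categorical columns (age_group, er, pr, ki67);
    the com-rad-score enters as a continuous covariate.  The nomogram is the
    refitted logistic model over the multivariate p < alpha survivors.
    """
    design = encode_clinical(clinical)
    design["com_rad_score"] = np.asarray(comrad, dtype=float)
    labels = np.asarray(labels)

    univariate = []
    survivors = []
    for name in design.columns:
        try:
            res = univariate_odds(design[name].to_numpy(), labels, name)
        except ValueError:
            continue  # single-level factor in a small cohort: not a candidate
        univariate.append(res)
        if np.isfinite(res.p_value) and res.p_value < alpha:
            survivors.append(name)
    if not survivors:
        raise ValueError(
            "no candidate passed the univariate screen; "
            f"p-values: {[(r.parameter, round(r.p_value, 4)) for r in univariate]}"
        )

    multi_model = fit_logistic(design[survivors], labels)
    multivariate = _wald_results(multi_model)
    final = [
        r.parameter
        for r in multivariate
        if np.isfinite(r.p_value) and r.p_value < alpha
    ]
    if not final:
        raise ValueError(
            "no independent predictor survived the multivariate fit; "
            f"p-values: {[(r.parameter, round(r.p_value, 4)) for r in multivariate]}"
        )

    final_model = fit_logistic(design[final], labels)
    ranges = pd.DataFrame(
        {"min": design[final].min(), "max": design[final].max()}
    )
    return NomogramModel(
        model=final_model,
        predictors=final,
        data_ranges=ranges,
        univariate=univariate,
        multivariate=multivariate,
    )


def nomogram_points(
    nomogram: NomogramModel, n_curve: int = 101
) -> tuple[dict[str, pd.DataFrame], pd.DataFrame]:
    """Points tables per predictor and the total-points-to-probability curve.

    Each predictor contributes beta (x - x_ref) rescaled so that the largest
    observed contribution range spans exactly 0-100 points (x_ref is the end
    of the observed range at which the contribution is smallest, so points
    are nonnegative).
    """
    model = nomogram.model
    ranges = nomogram.data_ranges
    widths = {}
    for name in nomogram.predictors:
        beta = float(model.coefficients[name])
        span = float(ranges.loc[name, "max"] - ranges.loc[name, "min"])
        if span == 0:
            raise ValueError(f"predictor {name!r} has zero observed range")
        widths[name] = abs(beta) * span
    scale = 100.0 / max(widths.values())

    tables: dict[str, pd.DataFrame] = {}
    base = model.intercept
    for name in nomogram.predictors:
        beta = float(model.coefficients[name])
        lo, hi = float(ranges.loc[name, "min"]), float(ranges.loc[name, "max"])
        x_ref = lo if beta >= 0 else hi
        base += beta * x_ref
        if set(np.unique([lo, hi])) <= {0.0, 1.0}:
            xs = np.array([lo, hi])
        else:
            xs = np.linspace(lo, hi, 11)
        tables[name] = pd.DataFrame(
            {"value": xs, "points": beta * (xs - x_ref) * scale}
        )

    max_total = sum(t["points"].max() for t in tables.values())
    totals = np.linspace(0.0, max_total, n_curve)
    probability = expit(base + totals / scale)
    curve = pd.DataFrame({"total_points": totals, "probability": probability})
    return tables, curve
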