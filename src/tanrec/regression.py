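"""Covariate construction and multilinear models of functional reconfiguration.

Per-participant reconfiguration magnitudes (correlation distances between
tangent-FCs of two conditions) are modeled by ordinary least squares on seven
predictors: sex (male = 1), age (years), education (years), SSRT (ms), CES-D
depression score, a composite recent-drinking score, and family-history-of-AUD
status (FHA, 1 = positive).

Two composite covariates are built here:

* ``drinking_score`` — the first principal component of the standardized
  AUDIT score and three self-reported drinking measures (drinking days,
  drinks per week, drinks per drinking day), with the sign fixed so that the
  AUDIT loading is positive (higher score = more drinking);
* ``ssrt`` — stop signal reaction time, the x-th percentile of the Go
  reaction times minus the mean stop signal delay, where x is the
  stop-failure rate (linear-interpolation percentile).

Predictors enter the model unstandardized by default, so coefficients are in
natural units per predictor; an ``additive_r2`` sequence records the R^2 of
the nested models as predictors are introduced in a declared order.  Only
that sequence depends on the order — the final model does not.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
import statsmodels.api as sm

__all__ = [
    "PREDICTORS",
    "RESULTS_ORDER",
    "RAW_COVARIATE_COLUMNS",
    "RegressionResult",
    "LooDistribution",
    "drinking_score",
    "ssrt",
    "prepare_design",
    "fit_reconfig_model",
    "loo_model_stability",
]

#: default predictor order (the cohort-description order)
PREDICTORS = ("sex", "age", "education", "ssrt", "cesd", "drinking", "fha")

#: alternative order used when reporting additive variance sequences
RESULTS_ORDER = ("age", "sex", "education", "ssrt", "drinking", "cesd", "fha")

#: raw covariate-file columns from which the design is derived
RAW_COVARIATE_COLUMNS = (
    "sex",
    "age",
    "education",
    "ssrt",
    "cesd",
    "audit",
    "drinking_days",
    "drinks_per_week",
    "drinks_per_drinking_day",
    "fha",
)


@dataclass
class RegressionResult:
    """OLS fit of a reconfiguration vector on participant covariates."""

    params: pd.Series
    bse: pd.Series
    pvalues: pd.Series
    r_squared: float
    additive_r2: list
    residuals: np.ndarray
    fitted: np.ndarray
    predictor_order: list
    nobs: int
    conf_int: pd.DataFrame | None = None

    def summary(self) -> str:
        lines = [
            f"OLS reconfiguration model (n = {self.nobs}, "
            f"R^2 = {self.r_squared:.3f})",
            f"{'predictor':<12}{'coef':>12}{'SE':>12}{'p':>10}{'add R^2':>10}",
        ]
        add = dict(zip(self.predictor_order, self.additive_r2))
        for name in ["const"] + list(self.predictor_order):
            extra = f"{add[name]:>10.3f}" if name in add else f"{'':>10}"
            lines.append(
                f"{name:<12}{self.params[name]:>12.4g}{self.bse[name]:>12.4g}"
                f"{self.pvalues[name]:>10.4f}{extra}"
            )
        return "\n".join(lines)

    def to_dict(self) -> dict:
        return {
            "predictor_order": list(self.predictor_order),
            "coefficients": self.params.to_dict(),
            "standard_errors": self.bse.to_dict(),
            "p_values": self.pvalues.to_dict(),
            "r_squared": self.r_squared,
            "additive_r2": list(self.additive_r2),
            "n": int(self.nobs),
        }


@dataclass
class LooDistribution:
    """Leave-one-out coefficient distributions.

    ``coefficients`` is an n x (predictors + const) frame, one row per
    excluded participant; ``mode`` distinguishes model-level resampling
    (refit excluding the participant) from reference-level resampling
    (rebuild the tangent-space reference without the participant, refit on
    everyone).
    """

    coefficients: pd.DataFrame
    mode: str
    predictor_order: list = field(default_factory=list)

    @property
    def n(self) -> int:
        return len(self.coefficients)

    def spread(self) -> pd.Series:
        return self.coefficients.std(ddof=1)


def drinking_score(audit, drinking_days, drinks_per_week, drinks_per_drinking_day):
    """First principal component of four standardized drinking measures.

    Columns are z-scored; the leading eigenvector of their correlation matrix
    defines the component, its sign fixed so the AUDIT loading is positive,
    and the scores are standardized to unit variance.  Returns
    ``(scores, variance_explained)`` with ``variance_explained`` the leading
    eigenvalue divided by 4.
    """
    cols = [np.asarray(c, dtype=float).ravel() for c in
            (audit, drinking_days, drinks_per_week, drinks_per_drinking_day)]
    n = cols[0].size
    if any(c.size != n for c in cols) or n < 3:
        raise ValueError("drinking measures must share length >= 3")
    x = np.column_stack(cols)
    sd = x.std(axis=0, ddof=1)
    if np.any(sd == 0.0):
        dead = np.flatnonzero(sd == 0.0).tolist()
        raise ValueError(f"constant drinking column(s) {dead}: PCA undefined")
    z = (x - x.mean(axis=0)) / sd
    corr = z.T @ z / (n - 1)
    w, v = np.linalg.eigh(corr)
    lead = v[:, -1]
    if lead[0] < 0:
        lead = -lead
    scores = z @ lead
    scores = (scores - scores.mean()) / scores.std(ddof=1)
    return scores, float(w[-1] / 4.0)


def ssrt(go_rts, ssds, stop_failure_rate: float) -> float:
    """Stop signal reaction time in milliseconds.

    The x-th percentile of the Go reaction times (linear-interpolation
    percentile), with x equal to the stop-failure rate, minus the mean stop
    signal delay.
    """
    go = np.asarray(go_rts, dtype=float).ravel()
    sd = np.asarray(ssds, dtype=float).ravel()
    if go.size == 0 or sd.size == 0:
        raise ValueError("go_rts and ssds must be nonempty")
    if not 0.0 < stop_failure_rate < 1.0:
        raise ValueError("stop_failure_rate must lie strictly between 0 and 1")
    return float(np.quantile(go, stop_failure_rate) - sd.mean())


def prepare_design(covariates: pd.DataFrame):
    """Derive the seven-predictor design from a raw covariate table.

    Expects the raw columns of :data:`RAW_COVARIATE_COLUMNS`; computes the
    composite ``drinking`` score from the four drinking measures.  Returns
    ``(design, variance_explained)``.  A table that already carries a
    ``drinking`` column is passed through (variance_explained = nan).
    """
    df = covariates.copy()
    if "drinking" not in df.columns:
        missing = [c for c in RAW_COVARIATE_COLUMNS if c not in df.columns]
        if missing:
            raise ValueError(f"covariate table is missing column(s) {missing}")
        scores, var_exp = drinking_score(
            df["audit"], df["drinking_days"], df["drinks_per_week"],
            df["drinks_per_drinking_day"],
        )
        df["drinking"] = scores
    else:
        var_exp = float("nan")
    design = df[list(PREDICTORS)].astype(float)
    for col in ("sex", "fha"):
        vals = set(np.unique(design[col]))
        if not vals <= {0.0, 1.0}:
            raise ValueError(f"{col} must be binary 0/1, got values {sorted(vals)}")
    if design.isna().any().any():
        bad = design.columns[design.isna().any()].tolist()
        raise ValueError(f"missing values in modeled column(s) {bad}")
    return design, var_exp


def _design_matrix(X: pd.DataFrame, order) -> pd.DataFrame:
    order = list(order)
    missing = [c for c in order if c not in X.columns]
    if missing:
        raise ValueError(f"design is missing predictor(s) {missing}")
    d = sm.add_constant(X[order].astype(float), has_constant="add")
    rank = np.linalg.matrix_rank(d.values)
    if rank < d.shape[1]:
        # name the columns whose removal restores full rank
        collinear = []
        for c in order:
            reduced = d.drop(columns=[c])
            if np.linalg.matrix_rank(reduced.values) == rank:
                collinear.append(c)
        raise ValueError(f"rank-deficient design; collinear column(s): {collinear}")
    return d


def fit_reconfig_model(y, X: pd.DataFrame, predictor_order=PREDICTORS) -> RegressionResult:
    """OLS with intercept of a reconfiguration vector on raw covariates.

    ``additive_r2[k]`` is the R^2 of the nested model containing the first
    ``k + 1`` predictors of ``predictor_order``; the full-model coefficients
    and p values (two-sided t tests) do not depend on the order.
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    order = list(predictor_order)
    if len(yv) != len(X):
        raise ValueError("response and covariate table lengths differ")
    if len(yv) <= len(order) + 1:
        raise ValueError(
            f"need n > {len(order) + 1} observations for {len(order)} predictors"
        )
    d = _design_matrix(X, order)
    fit = sm.OLS(yv, d).fit()
    additive = []
    for k in range(1, len(order) + 1):
        dk = sm.add_constant(X[order[:k]].astype(float), has_constant="add")
        additive.append(float(sm.OLS(yv, dk).fit().rsquared))
    return RegressionResult(
        params=fit.params,
        bse=fit.bse,
        pvalues=fit.pvalues,
        r_squared=float(fit.rsquared),
        additive_r2=additive,
        residuals=np.asarray(fit.resid),
        fitted=np.asarray(fit.fittedvalues),
        predictor_order=order,
        nobs=int(fit.nobs),
        conf_int=fit.conf_int(alpha=0.05),
    )


def loo_model_stability(y, X: pd.DataFrame, predictor_order=PREDICTORS) -> LooDistribution:
    """Refit the model n times, each excluding one participant.

    Returns the full leave-one-out coefficient distributions (one row per
    excluded participant).
    """
    yv = np.asarray(getattr(y, "values", y), dtype=float).ravel()
    n = len(yv)
    rows = []
    index = list(X.index)
    for i in range(n):
        keep = np.arange(n) != i
        res = fit_reconfig_model(yv[keep], X.iloc[keep], predictor_order)
        rows.append(res.params)
    coef = pd.DataFrame(rows, index=index)
    return LooDistribution(
        coefficients=coef, mode="model_loo", predictor_order=list(predictor_order)
    )
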