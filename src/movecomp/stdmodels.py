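"""Standard (absolute-minutes) regression models and the moderation screen.

Each behaviour is modelled in isolation: OLS of a gray-matter-volume outcome
on its daily minutes, adjusted for sex, maturity offset (years from peak
height velocity), parental university education (two dummies, reference =
neither parent) and total brain volume. Weight-status moderation is screened
with a joint F-test of behaviour x group interaction terms at alpha = 0.15;
a positive screen triggers stratified fits.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping

import numpy as np
import pandas as pd
import statsmodels.api as sm

BEHAVIORS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")

MODERATION_ALPHA: float = 0.15

_OUTCOME_ALIASES = {
    "left_hippocampus": "gmv_left_hippocampus",
    "right_hippocampus": "gmv_right_hippocampus",
}


def resolve_outcome(df: pd.DataFrame, outcome: str) -> str:
    col = _OUTCOME_ALIASES.get(outcome, outcome)
    if col not in df.columns:
        raise KeyError(f"outcome column {outcome!r} not found")
    return col


def resolve_behavior(df: pd.DataFrame, behavior: str) -> str:
    col = f"{behavior}_min" if f"{behavior}_min" in df.columns else behavior
    if col not in df.columns:
        raise KeyError(f"behavior column {behavior!r} not found")
    return col


def covariate_design(df: pd.DataFrame, include_intercept: bool = True,
                     drop_empty_levels: bool = True) -> pd.DataFrame:
    """Fixed confounder design: sex, PHV offset, parental education, TBV.

    Categorical dummies that are constant in the sample (e.g. a parental-
    education level absent from a small stratum) are dropped when
    ``drop_empty_levels`` is set, keeping stratified designs full-rank.
    """
    for col in ("sex", "phv_offset", "parental_education", "total_brain_volume"):
        if col not in df.columns:
            raise KeyError(f"covariate column {col!r} missing from participant table")
        if df[col].isna().any():
            raise ValueError(f"covariate column {col!r} has missing values")
    X = pd.DataFrame(index=df.index)
    if include_intercept:
        X["const"] = 1.0
    X["sex_female"] = (df["sex"] == "female").astype(float)
    X["phv_offset"] = df["phv_offset"].astype(float)
    X["edu_one"] = (df["parental_education"] == "one").astype(float)
    X["edu_both"] = (df["parental_education"] == "both").astype(float)
    X["total_brain_volume"] = df["total_brain_volume"].astype(float)
    if drop_empty_levels:
        for col in ("sex_female", "edu_one", "edu_both"):
            if X[col].nunique() == 1:
                X = X.drop(columns=col)
    return X


def _check_full_rank(X: pd.DataFrame) -> None:
    A = X.to_numpy(dtype=float)
    rank = np.linalg.matrix_rank(A)
    if rank < A.shape[1]:
        # pivoted QR localizes the dependent columns for the error message
        from scipy.linalg import qr
        _, r, piv = qr(A, mode="economic", pivoting=True)
        diag = np.abs(np.diag(r))
        tol = diag.max() * max(A.shape) * np.finfo(float).eps
        bad = [X.columns[piv[i]] for i in range(len(diag)) if diag[i] < tol]
        bad += [str(c) for c in X.columns[A.shape[1]:]]
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")


@dataclasses.dataclass
class RegressionResult:
    behavior: str
    outcome: str
    coef: float            # non-standardized B, mm^3 per min/day
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    params: pd.Series      # all coefficients incl. covariates

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.coef <= self.ci_high):
            raise ValueError("coefficient outside its confidence interval")


def fit_absolute(df: pd.DataFrame, behavior: str, outcome: str,
                 covariates: bool = True) -> RegressionResult:
    """Covariate-adjusted OLS of the outcome on one behaviour's minutes."""
    bcol = resolve_behavior(df, behavior)
    ycol = resolve_outcome(df, outcome)
    if df[bcol].nunique() <= 1:
        raise ValueError(f"behavior column {bcol!r} is constant; "
                         "rank-deficient design")
    X = pd.DataFrame({"const": 1.0, bcol: df[bcol].astype(float)}, index=df.index)
    if covariates:
        X = pd.concat([X, covariate_design(df, include_intercept=False)], axis=1)
    if len(df) < X.shape[1] + 1:
        raise ValueError(f"need at least {X.shape[1] + 1} observations, "
                         f"got {len(df)}")
    _check_full_rank(X)
    fit = sm.OLS(df[ycol].astype(float), X).fit()
    ci = fit.conf_int().loc[bcol]
    return RegressionResult(
        behavior=behavior, outcome=ycol,
        coef=float(fit.params[bcol]), se=float(fit.bse[bcol]),
        ci_low=float(ci[0]), ci_high=float(ci[1]),
        p_value=float(fit.pvalues[bcol]), n=int(fit.nobs),
        params=fit.params,
    )


@dataclasses.dataclass
class ModerationResult:
    behavior: str
    outcome: str
    p_interaction: float
    moderated: bool
    df_num: int
    n: int

    def __post_init__(self) -> None:
        if self.moderated != (self.p_interaction < MODERATION_ALPHA):
            raise ValueError("moderated flag inconsistent with p_interaction")


def test_moderation(df: pd.DataFrame, behavior: str, outcome: str,
                    group_col: str = "weight_status") -> ModerationResult:
    """Joint F-test of behaviour x weight-status interaction terms.

    Compares the covariate-adjusted model with group main effects against the
    same model plus behaviour x group products. With all three groups present
    the test has 2 numerator df; with two groups it degrades to 1 df.
    """
    bcol = resolve_behavior(df, behavior)
    ycol = resolve_outcome(df, outcome)
    groups = [g for g, n in df[group_col].value_counts().items() if n > 0]
    if len(groups) < 2:
        raise ValueError("moderation test needs at least 2 weight-status groups")
    small = [g for g in groups if (df[group_col] == g).sum() < 3]
    if small:
        warnings.warn(f"weight-status group(s) {small} have fewer than 3 "
                      "participants; moderation test may be unstable", stacklevel=2)

    groups = sorted(groups)
    X0 = pd.DataFrame({"const": 1.0, bcol: df[bcol].astype(float)}, index=df.index)
    for g in groups[1:]:
        X0[f"grp[{g}]"] = (df[group_col] == g).astype(float)
    X0 = pd.concat([X0, covariate_design(df, include_intercept=False)], axis=1)
    X1 = X0.copy()
    for g in groups[1:]:
        X1[f"{bcol}:grp[{g}]"] = X0[bcol] * X0[f"grp[{g}]"]

    _check_full_rank(X1)
    y = df[ycol].astype(float)
    fit0 = sm.OLS(y, X0).fit()
    fit1 = sm.OLS(y, X1).fit()
    tss = float(((y - y.mean()) ** 2).sum())
    if fit0.ssr <= tss * 1e-12:
        # the no-interaction model already fits to numerical precision;
        # the F ratio is 0/0 noise there, so report no moderation evidence
        pval, df_num = 1.0, len(groups) - 1
    else:
        fstat, pval, df_num = fit1.compare_f_test(fit0)
    return ModerationResult(behavior=behavior, outcome=ycol,
                            p_interaction=float(pval),
                            moderated=bool(pval < MODERATION_ALPHA),
                            df_num=int(df_num), n=int(fit1.nobs))


def stratify_and_fit(df: pd.DataFrame, behavior: str, outcome: str,
                     group_col: str = "weight_status",
                     covariates: bool = True) -> dict[str, RegressionResult]:
    """fit_absolute within each weight-status group; tiny groups are skipped."""
    out: dict[str, RegressionResult] = {}
    for g, sub in df.groupby(group_col, sort=True):
        try:
            out[str(g)] = fit_absolute(sub, behavior, outcome, covariates=covariates)
        except ValueError as err:
            warnings.warn(f"group {g!r} skipped: {err}", stacklevel=2)
    return out


def results_to_frame(results: Mapping[str, RegressionResult] | list[RegressionResult]) -> pd.DataFrame:
    if isinstance(results, Mapping):
        items = [(g, r) for g, r in results.items()]
    else:
        items = [("all", r) for r in results]
    return pd.DataFrame([{
        "group": g, "behavior": r.behavior, "outcome": r.outcome, "B": r.coef,
        "se": r.se, "ci_low": r.ci_low, "ci_high": r.ci_high,
        "p_value": r.p_value, "n": r.n,
    } for g, r in items])
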