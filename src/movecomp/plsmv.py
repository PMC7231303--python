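"""Multivariate pattern analysis of the intensity spectrum.

Single-response partial least squares (PLS1) regression of a (covariate-
residualized) outcome on the 33-band awake-time intensity spectrum, which is
strongly collinear by construction. Monte-Carlo cross-validation (repeated
random 50/50 splits) selects the number of latent components; the fitted
model is compressed by target projection into one predictive component, and
per-band selectivity ratios (signed share of each band's variance explained
by that component, range -1..1) summarize the association pattern, with
percentile confidence intervals from the resampling splits.
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Sequence

import numpy as np
import pandas as pd

from . import accel


@dataclasses.dataclass
class PlsModel:
    n_components: int
    x_mean: np.ndarray
    x_scale: np.ndarray
    y_mean: float
    weights: np.ndarray       # p x k
    x_loadings: np.ndarray    # p x k
    y_loadings: np.ndarray    # k
    scores: np.ndarray        # n x k (training scores)
    coef: np.ndarray          # p, regression vector in pretreated X space
    explained_y_variance: float


def _pretreat(X: np.ndarray, x_mean: np.ndarray, x_scale: np.ndarray) -> np.ndarray:
    return (X - x_mean) / x_scale


def fit_pls(X: np.ndarray, y: np.ndarray, n_components: int,
            scale: bool = True, allow_fewer: bool = False) -> PlsModel:
    """Deterministic PLS1 (NIPALS) with mean-centered, unit-variance columns.

    Zero-variance columns are kept but scaled by 1 (they carry no weight), so
    duplicated and constant columns are tolerated. With ``allow_fewer`` the
    decomposition stops early (instead of raising) when the predictive rank
    is exhausted before ``n_components``.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n, p = X.shape
    if len(y) != n:
        raise ValueError("X and y length mismatch")
    if n_components < 1:
        raise ValueError("n_components must be >= 1")
    x_mean = X.mean(axis=0)
    sd = X.std(axis=0, ddof=1) if scale else np.ones(p)
    x_scale = np.where(sd > 0, sd, 1.0)
    Xc = _pretreat(X, x_mean, x_scale)
    if n_components > min(n - 1, p):
        raise ValueError(f"requested {n_components} components exceeds the "
                         "maximal rank of the centered predictor matrix")
    y_mean = float(y.mean())
    yc = y - y_mean

    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    T = np.zeros((n, n_components))
    q = np.zeros(n_components)
    Xd, yd = Xc.copy(), yc.copy()
    tol = max(np.linalg.norm(Xc.T @ yc), 1.0) * 1e-12
    achieved = 0
    for a in range(n_components):
        w = Xd.T @ yd
        nw = np.linalg.norm(w)
        if nw <= tol:
            if allow_fewer:
                break
            raise ValueError(
                "response is orthogonal to the remaining predictor variance; "
                f"component {a + 1} exceeds the predictive rank")
        w /= nw
        t = Xd @ w
        tt = float(t @ t)
        p_a = Xd.T @ t / tt
        q_a = float(yd @ t / tt)
        Xd -= np.outer(t, p_a)
        yd -= q_a * t
        W[:, a], P[:, a], T[:, a], q[a] = w, p_a, t, q_a
        achieved = a + 1
    if achieved < n_components:
        W, P, T, q = W[:, :achieved], P[:, :achieved], T[:, :achieved], q[:achieved]
        n_components = achieved

    coef = W @ np.linalg.solve(P.T @ W, q)
    ss_tot = float(yc @ yc)
    resid = yc - Xc @ coef
    explained = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
    return PlsModel(n_components=n_components, x_mean=x_mean, x_scale=x_scale,
                    y_mean=y_mean, weights=W, x_loadings=P, y_loadings=q,
                    scores=T, coef=coef, explained_y_variance=explained)


def predict(model: PlsModel, X: np.ndarray) -> np.ndarray:
    Xc = _pretreat(np.asarray(X, dtype=float), model.x_mean, model.x_scale)
    return model.y_mean + Xc @ model.coef


@dataclasses.dataclass
class TargetProjection:
    scores: np.ndarray     # n, single predictive component
    x_loadings: np.ndarray  # p
    y_loading: float


def target_project(model: PlsModel, X: np.ndarray) -> TargetProjection:
    """Compress the fitted model into one component along its regression vector.

    Scores are X projected on the normalized regression vector; loadings are
    the regression of X on those scores. Predictions from the single component
    reproduce the full model's predictions exactly.
    """
    bnorm = np.linalg.norm(model.coef)
    if bnorm == 0:
        raise ValueError("zero regression vector; target projection undefined")
    Xc = _pretreat(np.asarray(X, dtype=float), model.x_mean, model.x_scale)
    t = Xc @ (model.coef / bnorm)
    p_tp = Xc.T @ t / float(t @ t)
    return TargetProjection(scores=t, x_loadings=p_tp, y_loading=bnorm)


def predict_tp(model: PlsModel, tp: TargetProjection) -> np.ndarray:
    return model.y_mean + tp.scores * tp.y_loading


def selectivity_ratios(tp: TargetProjection, X: np.ndarray,
                       model: PlsModel) -> np.ndarray:
    """Signed per-variable selectivity ratio in [-1, 1].

    |SR_j| is the fraction of band j's variance explained by the target-
    projection component (squared correlation with its scores); the sign is
    the sign of the loading, i.e. the direction of association with the
    outcome. Zero-variance bands yield NaN.
    """
    Xc = _pretreat(np.asarray(X, dtype=float), model.x_mean, model.x_scale)
    t = tp.scores
    expl = np.outer(t, tp.x_loadings)
    v_exp = expl.var(axis=0, ddof=1)
    v_tot = Xc.var(axis=0, ddof=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        sr = np.sign(tp.x_loadings) * v_exp / v_tot
    sr[v_tot == 0] = np.nan
    return sr


@dataclasses.dataclass
class McCvPlan:
    n_repetitions: int = 1000
    holdout_fraction: float = 0.5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.holdout_fraction < 1:
            raise ValueError("holdout_fraction must lie in (0, 1)")
        if self.n_repetitions < 1:
            raise ValueError("n_repetitions must be >= 1")


@dataclasses.dataclass
class McCvResult:
    selected_k: int            # 0 means "no predictive model"
    mean_error: np.ndarray     # k_max+1 mean held-out MSE, index = k
    se_error: np.ndarray
    errors: np.ndarray         # n_repetitions x (k_max+1)

    @property
    def has_model(self) -> bool:
        return self.selected_k > 0


def mc_cross_validate(X: np.ndarray, y: np.ndarray, plan: McCvPlan,
                      k_max: int = 3) -> McCvResult:
    """Held-out MSE per component count over repeated random 50/50 splits.

    k = 0 is the train-mean predictor. The selected k is the smallest whose
    mean error is within one standard error of the minimum; selecting k = 0
    declares "no predictive model".
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=float).ravel()
    n = len(y)
    if n < 10:
        raise ValueError("need at least 10 observations for Monte-Carlo CV")
    if plan.n_repetitions < 10:
        warnings.warn("very few Monte-Carlo repetitions; validation error "
                      "estimates will be unstable", stacklevel=2)
    rng = np.random.default_rng(plan.seed)
    n_test = max(1, int(round(n * plan.holdout_fraction)))
    errors = np.empty((plan.n_repetitions, k_max + 1))
    for r in range(plan.n_repetitions):
        perm = rng.permutation(n)
        test, train = perm[:n_test], perm[n_test:]
        Xtr, ytr, Xte, yte = X[train], y[train], X[test], y[test]
        errors[r, 0] = float(np.mean((yte - ytr.mean()) ** 2))
        m = fit_pls(Xtr, ytr, k_max, allow_fewer=True)
        Xte_c = _pretreat(Xte, m.x_mean, m.x_scale)
        for k in range(1, k_max + 1):
            if k > m.n_components:
                errors[r, k] = errors[r, k - 1]  # rank exhausted on this split
                continue
            bk = m.weights[:, :k] @ np.linalg.solve(
                m.x_loadings[:, :k].T @ m.weights[:, :k], m.y_loadings[:k])
            errors[r, k] = float(np.mean((yte - m.y_mean - Xte_c @ bk) ** 2))
    mean = errors.mean(axis=0)
    if plan.n_repetitions > 1:
        se = errors.std(axis=0, ddof=1) / np.sqrt(plan.n_repetitions)
    else:
        se = np.zeros_like(mean)
    best = int(np.argmin(mean))
    selected = int(np.flatnonzero(mean <= mean[best] + se[best])[0])
    return McCvResult(selected_k=selected, mean_error=mean, se_error=se,
                      errors=errors)


@dataclasses.dataclass
class SelectivityProfile:
    sr: np.ndarray
    ci_low: np.ndarray
    ci_high: np.ndarray
    n_components: int
    explained_y_variance: float
    band_labels: list[str] = dataclasses.field(default_factory=accel.band_labels)

    def to_frame(self) -> pd.DataFrame:
        edges = accel.band_edges()
        return pd.DataFrame({
            "band": self.band_labels,
            "band_low_mg": [lo for lo, _ in edges],
            "band_high_mg": [hi for _, hi in edges],
            "sr": self.sr, "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def selectivity_profile(X: np.ndarray, y: np.ndarray, n_components: int,
                        plan: McCvPlan | None = None) -> SelectivityProfile:
    """Point SR from the full fit; CIs from SRs on each resampling training half."""
    model = fit_pls(X, y, n_components)
    sr = selectivity_ratios(target_project(model, X), X, model)
    if plan is None:
        lo = hi = np.full_like(sr, np.nan)
    else:
        rng = np.random.default_rng(plan.seed)
        n = len(y)
        n_test = max(1, int(round(n * plan.holdout_fraction)))
        draws = np.empty((plan.n_repetitions, X.shape[1]))
        for r in range(plan.n_repetitions):
            train = rng.permutation(n)[n_test:]
            try:
                m = fit_pls(X[train], y[train], n_components)
                draws[r] = selectivity_ratios(target_project(m, X[train]),
                                              X[train], m)
            except ValueError:
                draws[r] = np.nan
        lo = np.nanpercentile(draws, 2.5, axis=0)
        hi = np.nanpercentile(draws, 97.5, axis=0)
    return SelectivityProfile(sr=sr, ci_low=lo, ci_high=hi,
                              n_components=n_components,
                              explained_y_variance=model.explained_y_variance)


def residualize(y: np.ndarray, C: np.ndarray) -> np.ndarray:
    """Residuals of y on a covariate matrix (intercept added if absent)."""
    C = np.asarray(C, dtype=float)
    if not np.any(C.std(axis=0) == 0):
        C = np.column_stack([np.ones(len(C)), C])
    beta, *_ = np.linalg.lstsq(C, np.asarray(y, dtype=float), rcond=None)
    return y - C @ beta


def analyze_spectrum(df: pd.DataFrame, outcome: str,
                     plan: McCvPlan | None = None, k_max: int = 3,
                     adjust: bool = True) -> tuple[McCvResult, SelectivityProfile | None]:
    """Full workflow on a participant table: residualize, select k, profile SRs.

    Returns the CV result and, when a predictive model was found, the
    selectivity profile (otherwise None).
    """
    from .stdmodels import covariate_design, resolve_outcome

    plan = plan or McCvPlan()
    X = df[accel.band_labels()].to_numpy(dtype=float)
    y = df[resolve_outcome(df, outcome)].to_numpy(dtype=float)
    if adjust:
        y = residualize(y, covariate_design(df, include_intercept=True).to_numpy())
    cv = mc_cross_validate(X, y, plan, k_max=k_max)
    if not cv.has_model:
        return cv, None
    return cv, selectivity_profile(X, y, cv.selected_k, plan=plan)
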