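"""Compositional data analysis of 24-h movement behaviours.

The daily time-use composition {sleep, SED, LPA, MVPA} is constrained to
1440 min. Associations with an outcome are therefore modelled on isometric
log-ratio (ilr) *pivot coordinates*: the first coordinate contrasts a focal
behaviour against the geometric mean of the remaining ones, and its
regression coefficient (gamma) is the relative association of that behaviour.
Time reallocations between two behaviours are evaluated by moving the
composition along the corresponding direction and propagating the fitted
coefficient covariance (delta method).
"""

from __future__ import annotations

import dataclasses
import warnings
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
import scipy.stats
import statsmodels.api as sm

PARTS: tuple[str, ...] = ("sleep", "sed", "lpa", "mvpa")
TOTAL_MIN: float = 1440.0

PART_COLUMNS: dict[str, str] = {p: f"{p}_min" for p in PARTS}


def close(parts: Sequence[float], total: float = TOTAL_MIN) -> np.ndarray:
    """Rescale strictly positive parts to sum to ``total``.

    Raises ``ValueError`` on zero or negative parts; a zero part must be
    handled by an explicit replacement strategy before closure
    (see :func:`replace_zeros`).
    """
    x = np.asarray(parts, dtype=float)
    if x.ndim not in (1, 2):
        raise ValueError("parts must be a vector or a matrix of row compositions")
    if np.any(x <= 0):
        raise ValueError(
            "compositional parts must be strictly positive; apply a "
            "zero-replacement strategy (e.g. replace_zeros) before closing"
        )
    s = x.sum(axis=-1, keepdims=True)
    return x / s * total


def replace_zeros(parts: Sequence[float], floor: float = 1.0,
                  total: float = TOTAL_MIN) -> np.ndarray:
    """Multiplicative replacement of zero parts by ``floor`` minutes."""
    x = np.asarray(parts, dtype=float).copy()
    if np.any(x < 0):
        raise ValueError("parts must be non-negative")
    zero = x == 0
    if zero.any():
        x = np.where(zero, floor, x)
    return close(x, total)


def pivot_order(focal: str, parts: Sequence[str] = PARTS) -> tuple[str, ...]:
    """Part ordering with the focal behaviour rotated to the first position."""
    if focal not in parts:
        raise ValueError(f"unknown part {focal!r}; expected one of {tuple(parts)}")
    return (focal, *(p for p in parts if p != focal))


def pivot_basis(n_parts: int) -> np.ndarray:
    """Orthonormal ilr contrast matrix V (n_parts x n_parts-1).

    Coordinate k (1-based) is sqrt((D-k)/(D-k+1)) * ln(x_k / gmean(x_{k+1..D})),
    so z = V.T @ ln(x) and clr(x) = V @ z.
    """
    d = n_parts
    v = np.zeros((d, d - 1))
    for k in range(1, d):
        a = np.sqrt((d - k) / (d - k + 1))
        v[k - 1, k - 1] = a
        v[k:, k - 1] = -a / (d - k)
    return v


def ilr_pivot(comp: Sequence[float], order: Sequence[str] | None = None,
              parts: Sequence[str] = PARTS) -> np.ndarray:
    """Pivot ilr coordinates of composition(s) given in canonical part order.

    ``comp`` rows are in ``parts`` order; ``order`` states the pivot ordering
    (defaults to ``parts`` itself). Scale-invariant: proportional inputs map
    to identical coordinates.
    """
    x = np.atleast_2d(np.asarray(comp, dtype=float))
    if np.any(x <= 0):
        raise ValueError("ilr requires strictly positive parts")
    if order is None:
        order = tuple(parts)
    idx = [list(parts).index(p) for p in order]
    logx = np.log(x[:, idx])
    z = logx @ pivot_basis(len(idx))
    return z[0] if np.asarray(comp).ndim == 1 else z


def ilr_inverse(z: Sequence[float], order: Sequence[str] | None = None,
                parts: Sequence[str] = PARTS,
                total: float = TOTAL_MIN) -> np.ndarray:
    """Inverse pivot transform; returns composition in canonical part order."""
    zz = np.atleast_2d(np.asarray(z, dtype=float))
    if order is None:
        order = tuple(parts)
    clr = zz @ pivot_basis(len(order)).T
    x = np.exp(clr)
    x = x / x.sum(axis=1, keepdims=True) * total
    out = np.empty_like(x)
    for j, p in enumerate(order):
        out[:, list(parts).index(p)] = x[:, j]
    return out[0] if np.asarray(z).ndim == 1 else out


def first_pivot_coordinate(comp: Sequence[float], focal: str,
                           parts: Sequence[str] = PARTS) -> np.ndarray | float:
    """First pivot coordinate: focal behaviour vs geometric mean of the rest."""
    z = ilr_pivot(comp, order=pivot_order(focal, parts), parts=parts)
    return z[..., 0] if np.asarray(comp).ndim > 1 else z[0]


def composition_matrix(df: pd.DataFrame, parts: Sequence[str] = PARTS) -> np.ndarray:
    """Extract the n x D matrix of behaviour minutes from a participant table."""
    cols = [PART_COLUMNS.get(p, p) for p in parts]
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise KeyError(f"participant table lacks columns {missing}")
    return df[cols].to_numpy(dtype=float)


def compositional_mean(comps: Sequence[Sequence[float]] | pd.DataFrame,
                       total: float = TOTAL_MIN) -> np.ndarray:
    """Closed geometric mean: component-wise gmean, re-closed to ``total``."""
    if isinstance(comps, pd.DataFrame):
        comps = composition_matrix(comps)
    x = np.asarray(comps, dtype=float)
    if np.any(x <= 0):
        raise ValueError("compositional mean requires strictly positive parts")
    g = np.exp(np.log(x).mean(axis=0))
    return close(g, total)


@dataclasses.dataclass
class CompositionalFit:
    """Covariate-adjusted regression of an outcome on pivot coordinates."""

    focal: str
    outcome: str
    gamma: float
    se: float
    ci_low: float
    ci_high: float
    p_value: float
    n: int
    order: tuple[str, ...]
    coord_coefs: np.ndarray          # coefficients of the 3 pivot coordinates
    coord_cov: np.ndarray            # their 3x3 covariance
    df_resid: float
    params: pd.Series
    compositional_mean: np.ndarray   # closed geometric mean of the fitting sample

    def __post_init__(self) -> None:
        if not (self.ci_low <= self.gamma <= self.ci_high):
            raise ValueError("gamma outside its confidence interval")


def fit_compositional(df: pd.DataFrame, focal: str, outcome: str,
                      covariates: bool = True) -> CompositionalFit:
    """OLS of ``outcome`` on all pivot coordinates (focal first) + covariates.

    gamma is the coefficient of the first coordinate: the association of the
    focal behaviour relative to the remaining behaviours.
    """
    from .stdmodels import covariate_design, resolve_outcome  # deferred: avoids cycle

    order = pivot_order(focal)
    comp = composition_matrix(df)
    z = ilr_pivot(comp, order=order)
    ycol = resolve_outcome(df, outcome)
    y = df[ycol].to_numpy(dtype=float)

    zcols = [f"z{k+1}" for k in range(z.shape[1])]
    X = pd.DataFrame(z, columns=zcols, index=df.index)
    if covariates:
        X = pd.concat([X, covariate_design(df, include_intercept=False)], axis=1)
    X = sm.add_constant(X, prepend=True)
    if len(df) < X.shape[1] + 1:
        raise ValueError(f"need at least {X.shape[1] + 1} observations for the "
                         f"compositional model, got {len(df)}")
    if np.linalg.matrix_rank(X.to_numpy()) < X.shape[1]:
        raise ValueError("rank-deficient design in compositional model")
    fit = sm.OLS(y, X).fit()
    ci = fit.conf_int().loc["z1"]
    return CompositionalFit(
        focal=focal,
        outcome=ycol,
        gamma=float(fit.params["z1"]),
        se=float(fit.bse["z1"]),
        ci_low=float(ci[0]),
        ci_high=float(ci[1]),
        p_value=float(fit.pvalues["z1"]),
        n=int(fit.nobs),
        order=order,
        coord_coefs=fit.params[zcols].to_numpy(),
        coord_cov=fit.cov_params().loc[zcols, zcols].to_numpy(),
        df_resid=float(fit.df_resid),
        params=fit.params,
        compositional_mean=compositional_mean(comp),
    )


def fit_all_gammas(df: pd.DataFrame, outcome: str,
                   covariates: bool = True) -> dict[str, CompositionalFit]:
    """One compositional fit per behaviour rotated to the focal position."""
    return {p: fit_compositional(df, p, outcome, covariates=covariates) for p in PARTS}


def reallocate(base: Sequence[float] | Mapping[str, float], donor: str,
               receiver: str, delta_min: float,
               parts: Sequence[str] = PARTS) -> np.ndarray:
    """Move ``delta_min`` minutes from donor to receiver, other parts fixed."""
    if isinstance(base, Mapping):
        x = np.array([base[p] for p in parts], dtype=float)
    else:
        x = np.asarray(base, dtype=float).copy()
    di, ri = list(parts).index(donor), list(parts).index(receiver)
    if x[di] - delta_min <= 0:
        raise ValueError(
            f"reallocating {delta_min} min exceeds available {parts[di]} "
            f"({x[di]:.1f} min)")
    if x[ri] + delta_min <= 0:
        raise ValueError(
            f"reallocating {delta_min} min would deplete {parts[ri]} "
            f"({x[ri]:.1f} min)")
    x[di] -= delta_min
    x[ri] += delta_min
    return close(x, x.sum())  # sum unchanged: closure is the identity


@dataclasses.dataclass
class ReallocationCurve:
    donor: str
    receiver: str
    deltas: np.ndarray
    diff: np.ndarray        # predicted outcome difference vs baseline, mm^3
    ci_low: np.ndarray
    ci_high: np.ndarray
    base: np.ndarray

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({
            "donor": self.donor, "receiver": self.receiver,
            "delta_min": self.deltas, "diff_mm3": self.diff,
            "ci_low": self.ci_low, "ci_high": self.ci_high,
        })


def substitution_curve(fit: CompositionalFit,
                       base: Sequence[float] | Mapping[str, float] | None,
                       donor: str, receiver: str,
                       deltas: Sequence[float]) -> ReallocationCurve:
    """Predicted outcome change for donor→receiver reallocations.

    Covariates cancel in the difference, which depends only on the pivot
    coordinates' displacement; the CI comes from the coefficient covariance
    propagated through that displacement (delta method). Infeasible deltas
    (donor depleted) are dropped with a warning.
    """
    if base is None:
        base = fit.compositional_mean
    if isinstance(base, Mapping):
        base = np.array([base[p] for p in PARTS], dtype=float)
    base = np.asarray(base, dtype=float)
    di = list(PARTS).index(donor)
    ri = list(PARTS).index(receiver)

    deltas = np.asarray(deltas, dtype=float)
    feasible = (base[di] - deltas > 0) & (base[ri] + deltas > 0)
    if not feasible.all():
        warnings.warn(
            f"{(~feasible).sum()} delta(s) outside the feasible reallocation "
            "range were dropped", stacklevel=2)
        deltas = deltas[feasible]

    z0 = ilr_pivot(base, order=fit.order)
    diff = np.zeros_like(deltas)
    var = np.zeros_like(deltas)
    for i, d in enumerate(deltas):
        if d == 0:
            continue
        znew = ilr_pivot(reallocate(base, donor, receiver, d), order=fit.order)
        dz = znew - z0
        diff[i] = float(fit.coord_coefs @ dz)
        var[i] = float(dz @ fit.coord_cov @ dz)
    tcrit = scipy.stats.t.ppf(0.975, fit.df_resid)
    half = tcrit * np.sqrt(var)
    return ReallocationCurve(donor=donor, receiver=receiver, deltas=deltas,
                             diff=diff, ci_low=diff - half, ci_high=diff + half,
                             base=base)
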