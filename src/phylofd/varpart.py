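"""Adjusted-R² variance partitioning of productivity between FD and PD.

Two predictor blocks X1 (functional diversity, e.g. FDis) and X2
(phylogenetic diversity, e.g. PSV) jointly explain a response y (log
annual aboveground biomass increment).  Using Ezekiel-adjusted R²,
the explained variance splits into Venn fractions

    [a] unique to X1 = R²adj(X1 ∪ X2) − R²adj(X2)
    [b] shared       = R²adj(X1) + R²adj(X2) − R²adj(X1 ∪ X2)
    [c] unique to X2 = R²adj(X1 ∪ X2) − R²adj(X1)
    [d] residual     = 1 − R²adj(X1 ∪ X2)

Adjusted fractions can be slightly negative; they are reported as-is.
The testable fractions [a] and [c] get p-values from a Freedman–Lane
permutation test: permute residuals of the reduced model (conditioning
block only), rebuild pseudo-responses, refit, and compare the observed
partial F against the permutation distribution.  The shared fraction [b]
cannot be tested.  With 999 permutations and the +1 convention the
smallest attainable p-value is 0.001.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
import statsmodels.api as sm

from ._rand import as_rng as _as_rng, spawn_seeds as _spawn_seeds

__all__ = [
    "OLSFit",
    "VarPartResult",
    "ols_fit",
    "adjusted_r2",
    "varpart_fractions",
    "varpart_two",
    "freedman_lane_test",
    "fit_productivity_model",
]


def _as_matrix(X) -> tuple[np.ndarray, list[str]]:
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), [str(c) for c in X.columns]
    if isinstance(X, pd.Series):
        return X.to_numpy(dtype=float).reshape(-1, 1), [str(X.name or "x0")]
    X = np.asarray(X, dtype=float)
    if X.ndim == 1:
        X = X.reshape(-1, 1)
    return X, [f"x{i}" for i in range(X.shape[1])]


def _as_vector(y) -> np.ndarray:
    y = np.asarray(y.to_numpy() if isinstance(y, pd.Series) else y, dtype=float)
    if y.ndim != 1:
        raise ValueError("response must be one-dimensional")
    if np.isnan(y).any():
        raise ValueError("missing values in response")
    return y


@dataclass
class OLSFit:
    coef: pd.Series  # intercept first
    fitted: np.ndarray
    residuals: np.ndarray
    r2: float


def ols_fit(y, X) -> OLSFit:
    """Ordinary least squares with intercept; errors on rank deficiency."""
    yv = _as_vector(y)
    Xm, names = _as_matrix(X)
    if np.isnan(Xm).any():
        raise ValueError("missing values in predictors")
    n = len(yv)
    if Xm.shape[0] != n:
        raise ValueError("response and predictors have different lengths")
    Z = np.column_stack([np.ones(n), Xm])
    rank = np.linalg.matrix_rank(Z)
    if rank < Z.shape[1]:
        # identify offending columns by incremental rank growth
        bad, r = [], 1
        for j, name in enumerate(names):
            r_new = np.linalg.matrix_rank(Z[:, : j + 2])
            if r_new == r:
                bad.append(name)
            r = r_new
        raise ValueError(f"rank-deficient design; collinear columns: {bad}")
    beta, _, _, _ = np.linalg.lstsq(Z, yv, rcond=None)
    fitted = Z @ beta
    resid = yv - fitted
    ss_res = float(resid @ resid)
    yc = yv - yv.mean()
    ss_tot = float(yc @ yc)
    r2 = 1.0 - ss_res / ss_tot if ss_tot > 0 else 0.0
    return OLSFit(
        coef=pd.Series(beta, index=["intercept", *names]),
        fitted=fitted,
        residuals=resid,
        r2=r2,
    )


def adjusted_r2(r2: float, n: int, p: int) -> float:
    """Ezekiel correction: R²adj = 1 − (1 − R²)(n − 1)/(n − p − 1)."""
    if n <= p + 1:
        raise ValueError(f"need n > p + 1 (got n={n}, p={p})")
    return 1.0 - (1.0 - r2) * (n - 1) / (n - p - 1)


def varpart_fractions(
    r2adj_x1: float, r2adj_x2: float, r2adj_both: float
) -> tuple[float, float, float, float]:
    """Venn fractions (a, b, c, d) from the three adjusted R² values."""
    a = r2adj_both - r2adj_x2
    c = r2adj_both - r2adj_x1
    b = r2adj_x1 + r2adj_x2 - r2adj_both
    d = 1.0 - r2adj_both
    return a, b, c, d


@dataclass
class VarPartResult:
    """Two-block adjusted-R² partition with permutation tests.

    ``frac_b`` (shared) carries no p-value: it is not an estimable model
    contrast and cannot be tested.  Negative adjusted fractions are
    possible and left unclipped.
    """

    r2adj_x1: float
    r2adj_x2: float
    r2adj_both: float
    frac_a: float
    frac_b: float
    frac_c: float
    frac_d: float
    p_a: float | None
    p_c: float | None
    n_perm: int
    n_obs: int

    def as_dict(self) -> dict:
        return {
            "r2adj_x1": self.r2adj_x1,
            "r2adj_x2": self.r2adj_x2,
            "r2adj_both": self.r2adj_both,
            "frac_a_unique_x1": self.frac_a,
            "frac_b_shared": self.frac_b,
            "frac_c_unique_x2": self.frac_c,
            "frac_d_residual": self.frac_d,
            "p_a": self.p_a,
            "p_c": self.p_c,
            "n_perm": self.n_perm,
            "n_obs": self.n_obs,
        }


@dataclass
class FreedmanLaneResult:
    p_value: float
    f_obs: float
    n_perm: int


def _qr_basis(Z: np.ndarray) -> np.ndarray:
    Q, _ = np.linalg.qr(Z)
    return Q


def freedman_lane_test(
    y,
    X_test,
    X_cond=None,
    n_perm: int = 999,
    seed=None,
    chunk: int = 256,
) -> FreedmanLaneResult:
    """Permutation test of block ``X_test`` conditional on ``X_cond``.

    Statistic: partial F of adding X_test to the model y ~ X_cond.  Null
    distribution: permute the residuals of the reduced fit (y ~ X_cond),
    add them back to its fitted values, and recompute the partial F on
    each pseudo-response.  p = (1 + #{F* >= F_obs}) / (1 + n_perm).
    """
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    yv = _as_vector(y)
    n = len(yv)
    Xt, t_names = _as_matrix(X_test)
    if X_cond is None or (hasattr(X_cond, "__len__") and len(X_cond) == 0):
        Xc = np.empty((n, 0))
        c_names: list[str] = []
    else:
        Xc, c_names = _as_matrix(X_cond)
    named = isinstance(X_test, (pd.DataFrame, pd.Series)) and isinstance(
        X_cond, (pd.DataFrame, pd.Series)
    )
    if named and set(t_names) & set(c_names):
        raise ValueError(
            f"test and conditioning blocks overlap: {sorted(set(t_names) & set(c_names))}"
        )
    Zc = np.column_stack([np.ones(n), Xc])
    Zf = np.column_stack([Zc, Xt])
    q = Xt.shape[1]
    df_full = n - Zf.shape[1]
    if df_full <= 0:
        raise ValueError("not enough observations for the full model")
    Qc = _qr_basis(Zc)
    Qf = _qr_basis(Zf)

    def partial_f(Y: np.ndarray) -> np.ndarray:
        # Y: (n,) or (n, m); RSS via orthonormal projections
        yy = np.sum(np.atleast_2d(Y.T) ** 2, axis=1)
        rss_c = yy - np.sum((Qc.T @ Y) ** 2, axis=0)
        rss_f = yy - np.sum((Qf.T @ Y) ** 2, axis=0)
        rss_f = np.maximum(rss_f, 1e-300)
        return ((rss_c - rss_f) / q) / (rss_f / df_full)

    f_obs = float(partial_f(yv)[0])
    fitted_c = Qc @ (Qc.T @ yv)
    resid_c = yv - fitted_c

    rng = _as_rng(seed)
    exceed = 0
    done = 0
    while done < n_perm:
        m = min(chunk, n_perm - done)
        P = np.empty((n, m))
        for k in range(m):
            P[:, k] = rng.permutation(resid_c)
        F = partial_f(fitted_c[:, None] + P)
        exceed += int(np.sum(F >= f_obs - 1e-12))
        done += m
    p = (1 + exceed) / (1 + n_perm)
    return FreedmanLaneResult(p_value=float(p), f_obs=f_obs, n_perm=n_perm)


def varpart_two(
    y, X1, X2, n_perm: int = 999, seed=None, permute: bool = True
) -> VarPartResult:
    """Partition variance in y between predictor blocks X1 and X2.

    Fits the three OLS models (X1, X2, X1 ∪ X2), converts their R² to
    adjusted R², derives the four Venn fractions, and (optionally) tests
    the two unique fractions by Freedman–Lane permutation.
    """
    yv = _as_vector(y)
    X1m, n1 = _as_matrix(X1)
    X2m, n2 = _as_matrix(X2)
    n = len(yv)
    Xb = np.column_stack([X1m, X2m])

    def r2_adj_rank(Xm: np.ndarray) -> float:
        # the union block can be collinear (e.g. identical predictors in
        # both blocks); project onto the column space and adjust by rank
        Z = np.column_stack([np.ones(n), Xm])
        rank = np.linalg.matrix_rank(Z)
        Q = np.linalg.svd(Z, full_matrices=False)[0][:, :rank]
        fitted = Q @ (Q.T @ yv)
        yc = yv - yv.mean()
        ss_tot = float(yc @ yc)
        resid = yv - fitted
        r2 = 1.0 - float(resid @ resid) / ss_tot if ss_tot > 0 else 0.0
        return adjusted_r2(r2, n, rank - 1)

    r2a_1 = r2_adj_rank(X1m)
    r2a_2 = r2_adj_rank(X2m)
    r2a_b = r2_adj_rank(Xb)
    a, b, c, d = varpart_fractions(r2a_1, r2a_2, r2a_b)
    p_a = p_c = None
    if permute:
        ss = _spawn_seeds(seed, 2)
        B1 = pd.DataFrame(X1m, columns=[f"X1.{c}" for c in n1])
        B2 = pd.DataFrame(X2m, columns=[f"X2.{c}" for c in n2])
        p_a = freedman_lane_test(
            yv, B1, B2, n_perm=n_perm, seed=np.random.default_rng(ss[0])
        ).p_value
        p_c = freedman_lane_test(
            yv, B2, B1, n_perm=n_perm, seed=np.random.default_rng(ss[1])
        ).p_value
    return VarPartResult(
        r2adj_x1=r2a_1, r2adj_x2=r2a_2, r2adj_both=r2a_b,
        frac_a=a, frac_b=b, frac_c=c, frac_d=d,
        p_a=p_a, p_c=p_c, n_perm=n_perm if permute else 0, n_obs=n,
    )


@dataclass
class ProductivityModelResult:
    """Full multiple-regression model of (log) productivity.

    ``coef_table`` has columns coef, se, t, p (classic OLS inference from
    statsmodels); ``fl_pvalues`` holds per-term Freedman–Lane permutation
    p-values, each term tested conditional on all other terms.
    """

    coef_table: pd.DataFrame
    r2: float
    r2adj: float
    fl_pvalues: dict[str, float]
    n_obs: int
    n_perm: int


def fit_productivity_model(
    data: pd.DataFrame,
    response: str,
    predictors: list[str],
    n_perm: int = 999,
    seed=None,
) -> ProductivityModelResult:
    """Multiple regression of the response on all predictor columns.

    Mirrors the structure productivity ~ covariates + CWM + FDis + PSV:
    every predictor enters linearly, and each one's contribution is also
    tested by Freedman–Lane permutation conditional on the rest.
    """
    missing = [c for c in [response, *predictors] if c not in data.columns]
    if missing:
        raise ValueError(f"columns absent from table: {missing}")
    sub = data[[response, *predictors]].astype(float)
    if sub.isna().any().any():
        raise ValueError("missing values in model columns")
    y = sub[response]
    X = sub[predictors]
    model = sm.OLS(y, sm.add_constant(X)).fit()
    coef_table = pd.DataFrame(
        {"coef": model.params, "se": model.bse, "t": model.tvalues, "p": model.pvalues}
    )
    ss = _spawn_seeds(seed, len(predictors))
    fl = {}
    for k, term in enumerate(predictors):
        others = [t for t in predictors if t != term]
        fl[term] = freedman_lane_test(
            y, X[[term]], X[others] if others else None,
            n_perm=n_perm, seed=np.random.default_rng(ss[k]),
        ).p_value
    return ProductivityModelResult(
        coef_table=coef_table,
        r2=float(model.rsquared),
        r2adj=float(model.rsquared_adj),
        fl_pvalues=fl,
        n_obs=int(model.nobs),
        n_perm=n_perm,
    )
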