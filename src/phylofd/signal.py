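"""Phylogenetic signal: Pagel's lambda and Moran's I correlograms.

Pagel's lambda measures how much of a continuous trait's cross-species
covariance is explained by shared ancestry under Brownian motion (BM).
The trait vector x is modelled as multivariate normal with mean z0*1 and
covariance sigma2 * V(lambda), where V(lambda) multiplies the
off-diagonal of the tree's BM covariance matrix V by lambda.  lambda = 1
is pure BM; lambda = 0 makes tips independent.  The maximum-likelihood
fit profiles z0 and sigma2 out analytically (GLS) and optimizes the
one-dimensional profile likelihood over lambda in [eps, 1] with
eps = 1e-7.  Confidence intervals come from a parametric bootstrap:
simulate traits from the fitted model, refit, take percentiles.

Because an ultrametric tree has constant V diagonal T, the transformed
matrix V(lambda) = lambda*V + (1-lambda)*T*I shares V's eigenvectors;
after one eigendecomposition every profile-likelihood evaluation (and
every bootstrap simulation) is O(n).  That makes thousand-replicate
bootstraps and recovery simulations cheap.

Moran's I complements lambda by localizing signal in evolutionary time:
with a binary weight matrix selecting species pairs whose patristic
distance falls in a class, I measures whether those pairs are more
(I > 0) or less (I < 0) similar than random expectation -1/(n-1).
Computing I over a ladder of distance classes yields a phylogenetic
correlogram.  Significance is by permutation of trait values across tips
(default) or by the classic normal approximation.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, replace

import numpy as np
import pandas as pd
from scipy import linalg, optimize, stats

from ._rand import as_rng as _as_rng, spawn_seeds as _spawn_seeds
from .treeio import (
    LAMBDA_EPS,
    Phylogeny,
    check_ultrametric,
    patristic_distances,
    phylo_vcv,
)

__all__ = [
    "LambdaFit",
    "MoranResult",
    "DistanceClassSpec",
    "bm_loglik",
    "fit_lambda",
    "parametric_bootstrap_ci",
    "estimate_lambda",
    "moran_i",
    "build_distance_classes",
    "phylo_correlogram",
]


# ---------------------------------------------------------------------------
# Pagel's lambda


@dataclass
class LambdaFit:
    """Maximum-likelihood Pagel's lambda fit for one trait.

    ``sigma2_hat`` is the ML Brownian rate (trait units^2 per unit
    branch length), ``z0_hat`` the inferred root state.  ``ci_low`` /
    ``ci_high`` hold 95% parametric-bootstrap percentile bounds once
    :func:`parametric_bootstrap_ci` has been run (``n_boot`` successful
    replicates, ``n_dropped`` discarded ones).
    """

    lambda_hat: float
    sigma2_hat: float
    z0_hat: float
    loglik: float
    n_tips: int
    trait: str | None = None
    ci_low: float | None = None
    ci_high: float | None = None
    n_boot: int = 0
    n_dropped: int = 0


def _align_trait(x, labels: list[str]) -> np.ndarray:
    if isinstance(x, pd.Series):
        missing = [l for l in labels if l not in x.index]
        if missing:
            raise ValueError(f"trait values missing for species: {sorted(missing)}")
        return x.loc[labels].to_numpy(dtype=float)
    x = np.asarray(x, dtype=float)
    if x.shape != (len(labels),):
        raise ValueError(f"trait vector length {x.shape} != number of tips {len(labels)}")
    return x


def bm_loglik(x, V: pd.DataFrame, sigma2: float, z0: float) -> float:
    """Log-likelihood of trait vector x under BM: N(z0*1, sigma2*V).

    Dense Cholesky evaluation; independent of the eigendecomposition
    path used by :func:`fit_lambda`.
    """
    if sigma2 <= 0:
        raise ValueError("sigma2 must be positive")
    labels = list(V.index)
    xv = _align_trait(x, labels) - z0
    S = sigma2 * V.to_numpy(dtype=float)
    try:
        c, low = linalg.cho_factor(S, lower=True)
    except linalg.LinAlgError as exc:
        raise linalg.LinAlgError(
            "covariance matrix is singular; consider adding a small diagonal jitter"
        ) from exc
    alpha = linalg.cho_solve((c, low), xv)
    logdet = 2.0 * np.sum(np.log(np.diag(c)))
    n = len(xv)
    return float(-0.5 * (n * np.log(2.0 * np.pi) + logdet + xv @ alpha))


class _LambdaProfile:
    """Profile likelihood of lambda on an ultrametric tree.

    Eigendecomposes V once; V(lambda) = U diag(lambda*w + (1-lambda)*T) U'.
    Each call returns (loglik, z0_hat, sigma2_hat) in O(n).
    """

    def __init__(self, V: np.ndarray):
        self.n = V.shape[0]
        self.T = float(np.mean(np.diag(V)))
        self.w, self.U = np.linalg.eigh(V)
        self.ones_t = self.U.T @ np.ones(self.n)

    def set_trait(self, x: np.ndarray) -> None:
        self.x_t = self.U.T @ x

    def __call__(self, lam: float) -> tuple[float, float, float]:
        d = lam * self.w + (1.0 - lam) * self.T
        if np.any(d <= 0):
            return -np.inf, np.nan, np.nan
        inv_d = 1.0 / d
        z0 = float((self.ones_t * inv_d) @ self.x_t / ((self.ones_t**2) @ inv_d))
        r = self.x_t - z0 * self.ones_t
        sigma2 = float((r**2) @ inv_d / self.n)
        if sigma2 <= 0:
            return -np.inf, z0, sigma2
        ll = -0.5 * (
            self.n * np.log(2.0 * np.pi * sigma2) + np.sum(np.log(d)) + self.n
        )
        return float(ll), z0, sigma2

    def simulate(self, lam: float, sigma2: float, z0: float, rng) -> np.ndarray:
        d = lam * self.w + (1.0 - lam) * self.T
        z = rng.standard_normal(self.n)
        return z0 + self.U @ (np.sqrt(np.maximum(sigma2 * d, 0.0)) * z)


def _maximize_profile(prof: _LambdaProfile, eps: float = LAMBDA_EPS) -> tuple[float, float, float, float]:
    """Grid scan + local bounded refinement; robust to mild multimodality."""
    grid = np.linspace(eps, 1.0, 21)
    lls = np.array([prof(l)[0] for l in grid])
    i = int(np.argmax(lls))
    lo = grid[max(i - 1, 0)]
    hi = grid[min(i + 1, len(grid) - 1)]
    best_lam, best_ll = grid[i], lls[i]
    if hi > lo:
        res = optimize.minimize_scalar(
            lambda l: -prof(l)[0],
            bounds=(lo, hi),
            method="bounded",
            options={"xatol": 1e-8},
        )
        if np.isfinite(res.fun) and -res.fun > best_ll:
            best_lam, best_ll = float(res.x), float(-res.fun)
    # endpoints can dominate when the profile is monotone
    for cand in (eps, 1.0):
        ll = prof(cand)[0]
        if ll > best_ll:
            best_lam, best_ll = cand, ll
    ll, z0, sigma2 = prof(best_lam)
    return best_lam, sigma2, z0, ll


def _profile_for_tree(tree: Phylogeny) -> tuple[_LambdaProfile, list[str]]:
    ok, dev = check_ultrametric(tree)
    if not ok:
        raise ValueError(
            f"fit_lambda requires an ultrametric tree (max relative deviation {dev:.3g})"
        )
    V = phylo_vcv(tree)
    return _LambdaProfile(V.to_numpy(dtype=float)), list(V.index)


def fit_lambda(x, tree: Phylogeny, trait_name: str | None = None) -> LambdaFit:
    """ML estimate of Pagel's lambda for one continuous trait.

    The profile likelihood over lambda in [1e-7, 1] is maximized with a
    coarse grid scan followed by bounded scalar refinement; z0 and sigma2
    are profiled out by GLS at each lambda.  Requires an ultrametric
    tree, at least 4 tips, and a nonconstant trait.
    """
    prof, labels = _profile_for_tree(tree)
    if prof.n < 4:
        raise ValueError("fit_lambda needs at least 4 tips")
    xv = _align_trait(x, labels)
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant across tips; lambda is undefined")
    prof.set_trait(xv)
    lam, sigma2, z0, ll = _maximize_profile(prof)
    name = trait_name or (x.name if isinstance(x, pd.Series) else None)
    return LambdaFit(
        lambda_hat=lam, sigma2_hat=sigma2, z0_hat=z0, loglik=ll,
        n_tips=prof.n, trait=name,
    )


def parametric_bootstrap_ci(
    fit: LambdaFit,
    tree: Phylogeny,
    n_sim: int = 1000,
    alpha: float = 0.05,
    seed=None,
) -> LambdaFit:
    """95% (by default) percentile CI for lambda by parametric bootstrap.

    Simulates ``n_sim`` trait vectors from the fitted
    (lambda, sigma2, z0) model on the same tree, refits each, and takes
    the (alpha/2, 1-alpha/2) percentiles of the replicate estimates.  A
    replicate whose refit fails is retried once on a fresh draw, then
    dropped with a logged count.  Returns a copy of ``fit`` with the CI
    fields populated; deterministic given ``seed``.
    """
    if n_sim < 2:
        raise ValueError("n_sim must be >= 2")
    rng = _as_rng(seed)
    prof, _ = _profile_for_tree(tree)
    lams = []
    dropped = 0
    for _ in range(n_sim):
        est = np.nan
        for _attempt in range(2):
            xs = prof.simulate(fit.lambda_hat, fit.sigma2_hat, fit.z0_hat, rng)
            if np.ptp(xs) == 0:
                continue
            prof.set_trait(xs)
            lam, _, _, ll = _maximize_profile(prof)
            if np.isfinite(ll):
                est = lam
                break
        if np.isnan(est):
            dropped += 1
        else:
            lams.append(est)
    if dropped:
        warnings.warn(f"dropped {dropped} non-converging bootstrap replicates")
    lo, hi = np.percentile(lams, [100 * alpha / 2, 100 * (1 - alpha / 2)])
    if not (lo <= fit.lambda_hat <= hi):
        warnings.warn(
            "bootstrap percentile CI does not bracket the point estimate "
            "(Monte-Carlo noise)"
        )
    return replace(
        fit, ci_low=float(lo), ci_high=float(hi), n_boot=len(lams), n_dropped=dropped
    )


def estimate_lambda(
    x, tree: Phylogeny, n_boot: int = 1000, seed=None, trait_name: str | None = None
) -> LambdaFit:
    """Convenience: ML fit plus parametric-bootstrap CI in one call."""
    fit = fit_lambda(x, tree, trait_name=trait_name)
    return parametric_bootstrap_ci(fit, tree, n_sim=n_boot, seed=seed)


# ---------------------------------------------------------------------------
# Moran's I and the phylogenetic correlogram


@dataclass
class MoranResult:
    I: float
    expected: float
    p_value: float
    n_pairs: int
    method: str


def moran_i(
    x,
    W: np.ndarray | pd.DataFrame,
    n_perm: int = 999,
    seed=None,
    method: str = "permutation",
) -> MoranResult:
    """Moran's I autocorrelation of trait values under a binary weight matrix.

    I = (n / S0) * sum_ij w_ij (x_i - xbar)(x_j - xbar) / sum_i (x_i - xbar)^2

    with S0 = sum_ij w_ij.  Expectation under no autocorrelation is
    -1/(n-1).  ``method="permutation"`` (default) computes a two-sided
    p-value from ``n_perm`` random relabelings of trait values across
    tips, counting replicates at least as far from the expectation as
    observed, with the +1 convention so the smallest attainable p is
    1/(n_perm+1).  ``method="normal"`` uses the classic normality
    approximation instead.
    """
    if isinstance(W, pd.DataFrame):
        if isinstance(x, pd.Series):
            x = x.loc[W.index]
        W = W.to_numpy(dtype=float)
    W = np.asarray(W, dtype=float)
    xv = np.asarray(x.to_numpy() if isinstance(x, pd.Series) else x, dtype=float)
    n = len(xv)
    if W.shape != (n, n):
        raise ValueError("weight matrix shape does not match trait vector")
    if not np.allclose(W, W.T):
        raise ValueError("weight matrix must be symmetric")
    if np.any(np.diag(W) != 0):
        raise ValueError("weight matrix must have a zero diagonal")
    S0 = W.sum()
    if S0 <= 0:
        raise ValueError("weight matrix has no positive weights")
    if np.ptp(xv) == 0:
        raise ValueError("trait is constant; Moran's I is undefined")

    xc = xv - xv.mean()
    denom = float(xc @ xc)
    I = float(n / S0 * (xc @ W @ xc) / denom)
    expected = -1.0 / (n - 1)

    if method == "normal":
        S1 = 0.5 * np.sum((W + W.T) ** 2)
        S2 = np.sum((W.sum(axis=0) + W.sum(axis=1)) ** 2)
        var = (n**2 * S1 - n * S2 + 3 * S0**2) / (S0**2 * (n**2 - 1)) - expected**2
        z = (I - expected) / np.sqrt(var)
        p = float(2.0 * stats.norm.sf(abs(z)))
    elif method == "permutation":
        if n_perm < 1:
            raise ValueError("n_perm must be >= 1")
        rng = _as_rng(seed)
        P = np.empty((n_perm, n))
        for k in range(n_perm):
            P[k] = rng.permutation(xc)
        quad = np.einsum("ki,ij,kj->k", P, W, P)
        I_perm = n / S0 * quad / denom
        exceed = np.sum(np.abs(I_perm - expected) >= np.abs(I - expected) - 1e-12)
        p = float((1 + exceed) / (1 + n_perm))
    else:
        raise ValueError(f"unknown method {method!r}")

    n_pairs = int(round(np.count_nonzero(W) / 2))
    return MoranResult(I=I, expected=expected, p_value=p, n_pairs=n_pairs, method=method)


@dataclass
class DistanceClassSpec:
    """Partition of patristic distances into half-open classes.

    ``bounds`` has length ``n_classes + 1`` and spans [0, max distance];
    class k covers [bounds[k], bounds[k+1]), with the last class closed
    at the top so the maximum distance is included.
    """

    n_classes: int
    bounds: np.ndarray
    scheme: str

    def __post_init__(self):
        self.bounds = np.asarray(self.bounds, dtype=float)
        if len(self.bounds) != self.n_classes + 1:
            raise ValueError("bounds must have n_classes + 1 edges")
        if np.any(np.diff(self.bounds) <= 0):
            raise ValueError("class bounds must be strictly increasing")


def build_distance_classes(
    D: pd.DataFrame, n_classes: int = 8, scheme: str = "equal_width"
) -> tuple[DistanceClassSpec, list[np.ndarray]]:
    """Distance classes plus one binary weight matrix per class.

    ``scheme="equal_width"`` (default) slices [0, max distance] into
    equal-width bins — with clumped divergence times (e.g. a deep
    angiosperm/gymnosperm split) some bins can legitimately hold no
    species pair and are reported empty.  ``scheme="equal_frequency"``
    places edges at quantiles of the pairwise distances so classes hold
    near-equal pair counts.  Every off-diagonal pair lands in exactly one
    class.
    """
    if n_classes < 2:
        raise ValueError("need at least 2 distance classes")
    Dv = D.to_numpy(dtype=float)
    n = Dv.shape[0]
    iu = np.triu_indices(n, k=1)
    dists = Dv[iu]
    max_d = dists.max()
    if max_d <= 0:
        raise ValueError("all pairwise distances are zero")
    if n_classes > len(np.unique(dists)):
        warnings.warn(
            f"{n_classes} classes exceed the {len(np.unique(dists))} distinct "
            "distances; some classes will be empty"
        )
    if scheme == "equal_width":
        bounds = np.linspace(0.0, max_d, n_classes + 1)
    elif scheme == "equal_frequency":
        # cut between tie blocks at the achievable cumulative count nearest
        # each quantile target; tied distances cannot be split across classes
        uniq, counts = np.unique(dists, return_counts=True)
        cum = np.cumsum(counts)
        edges = [0.0]
        for i in range(1, n_classes):
            target = i * len(dists) / n_classes
            j = int(np.argmin(np.abs(cum - target)))
            if j + 1 < len(uniq):
                edges.append(0.5 * (uniq[j] + uniq[j + 1]))
        edges.append(max_d)
        bounds = np.unique(edges)
        if len(bounds) < n_classes + 1:
            warnings.warn(
                "tied distances collapsed "
                f"{n_classes} requested classes to {len(bounds) - 1}"
            )
            n_classes = len(bounds) - 1
    else:
        raise ValueError(f"unknown scheme {scheme!r}")
    spec = DistanceClassSpec(n_classes=n_classes, bounds=bounds, scheme=scheme)

    idx = np.clip(np.searchsorted(bounds, Dv, side="right") - 1, 0, n_classes - 1)
    weights = []
    for k in range(n_classes):
        Wk = ((idx == k) & ~np.eye(n, dtype=bool)).astype(float)
        weights.append(Wk)
    return spec, weights


def phylo_correlogram(
    x,
    tree: Phylogeny,
    n_classes: int = 8,
    scheme: str = "equal_width",
    n_perm: int = 999,
    seed=None,
    method: str = "permutation",
) -> pd.DataFrame:
    """Moran's I phylogenetic correlogram of one trait.

    Returns one row per distance class: ``class_lo``, ``class_hi``,
    ``n_pairs``, ``I``, ``expected``, ``p_value``, ``empty``.  Classes
    containing no species pair (possible with equal-width classes on
    deeply split trees) are flagged ``empty`` and carry NaN statistics —
    no comparison is possible there.  Deterministic given ``seed``.
    """
    D = patristic_distances(tree)
    xv = _align_trait(x, list(D.index))
    spec, weights = build_distance_classes(D, n_classes=n_classes, scheme=scheme)
    child_seeds = _spawn_seeds(seed, spec.n_classes)
    rows = []
    for k, Wk in enumerate(weights):
        n_pairs = int(round(Wk.sum() / 2))
        row = {
            "class_lo": spec.bounds[k],
            "class_hi": spec.bounds[k + 1],
            "n_pairs": n_pairs,
            "I": np.nan,
            "expected": np.nan,
            "p_value": np.nan,
            "empty": n_pairs == 0,
        }
        if n_pairs > 0:
            res = moran_i(
                xv, Wk, n_perm=n_perm,
                seed=np.random.default_rng(child_seeds[k]), method=method,
            )
            row.update(I=res.I, expected=res.expected, p_value=res.p_value)
        rows.append(row)
    out = pd.DataFrame(rows)
    out.index.name = "class"
    return out
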