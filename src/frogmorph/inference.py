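"""PERMANOVA with pairwise contrasts, and PGLS with ML Pagel's λ.

PERMANOVA follows Anderson's pseudo-F partition of a distance matrix. The
distance here is Euclidean on the supplied (log-shape) matrix, for which
the Gower-centered partition reduces exactly to the familiar centroid
sums of squares: SS_between = Σ_g n_g‖x̄_g − x̄‖², SS_within = SS_total −
SS_between, F = (SS_between/(k−1))/(SS_within/(n−k)). Significance comes
from free permutation of row labels; p = (1 + #{F* ≥ F})/(1 + n_perm).

PGLS fits y = Xβ + ε with ε ~ N(0, σ²·C(λ)), where C(λ) is the Pagel-λ
transform of the Brownian-motion covariance. β̂ is the GLS estimator via
Cholesky solves; λ̂ maximizes the ML profile log-likelihood over
[0, λ_max] on a 0.01 grid with local refinement. λ_max is the largest λ
keeping C(λ) PSD, which exceeds 1 on non-ultrametric trees — λ̂ > 1 is a
legitimate outcome there and is not clamped.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field
from typing import Mapping, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from scipy.optimize import minimize_scalar

from .phylo import PhyloCovariance, lambda_max, lambda_transform

__all__ = [
    "PermanovaResult",
    "PglsFit",
    "permanova",
    "pairwise_permanova",
    "pgls_fit",
    "select_model",
    "build_design",
]


@dataclass
class PermanovaResult:
    grouping: str
    pseudo_f: float
    r_squared: float
    n_perm: int
    p_value: float
    seed: int | None = None
    pairwise: pd.DataFrame | None = None
    adjust: str | None = None


@dataclass
class PglsFit:
    response: str
    design_description: str
    lam: float
    lam_interval: tuple[float, float]
    coefficients: pd.DataFrame  # estimate, se, t, p per term
    sigma2: float
    log_likelihood: float
    aic: float
    n: int
    df_residual: int
    lam_profile: pd.DataFrame | None = None
    boundary: bool = False

    @property
    def k(self) -> int:
        return len(self.coefficients)


def _ss_partition(X: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    """(SS_between, SS_within) for Euclidean distance via group centroids."""
    n = X.shape[0]
    grand = X.mean(axis=0)
    ss_total = float(((X - grand) ** 2).sum())
    ss_between = 0.0
    for g in range(k):
        rows = X[codes == g]
        if len(rows):
            diff = rows.mean(axis=0) - grand
            ss_between += len(rows) * float(diff @ diff)
    return ss_between, ss_total - ss_between


def _pseudo_f(X: np.ndarray, codes: np.ndarray, k: int) -> tuple[float, float]:
    n = X.shape[0]
    ssb, ssw = _ss_partition(X, codes, k)
    f = (ssb / (k - 1)) / (ssw / (n - k)) if ssw > 0 else np.inf
    r2 = ssb / (ssb + ssw) if (ssb + ssw) > 0 else 0.0
    return f, r2


def permanova(
    X: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    seed: int | np.random.Generator = 0,
    grouping: str = "group",
) -> PermanovaResult:
    """One-way PERMANOVA on the Euclidean distances of ``X`` rows."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = pd.Series(list(groups))
    if n_perm < 1:
        raise ValueError("n_perm must be >= 1")
    levels = list(dict.fromkeys(groups))
    counts = groups.value_counts()
    small = [g for g in levels if counts[g] < 2]
    if len(levels) < 2 or small:
        raise ValueError(f"need >= 2 groups of size >= 2; too small: {small}")
    codes = np.asarray([levels.index(g) for g in groups])
    k = len(levels)
    f_obs, r2 = _pseudo_f(X, codes, k)
    rng = np.random.default_rng(seed)
    exceed = 0
    for _ in range(n_perm):
        f_perm, _ = _pseudo_f(X, rng.permutation(codes), k)
        if f_perm >= f_obs:
            exceed += 1
    p = (1 + exceed) / (1 + n_perm)
    return PermanovaResult(grouping, f_obs, r2, n_perm, p,
                           seed=seed if isinstance(seed, int) else None)


_ADJUSTERS = {
    "bonferroni": lambda p: np.minimum(p * len(p), 1.0),
    "holm": None,  # handled below
    "bh": None,
}


def _adjust_p(p: np.ndarray, method: str) -> np.ndarray:
    p = np.asarray(p, dtype=float)
    m = len(p)
    if method == "bonferroni":
        return np.minimum(p * m, 1.0)
    order = np.argsort(p)
    out = np.empty(m)
    if method == "holm":
        running = 0.0
        for rank, i in enumerate(order):
            running = max(running, (m - rank) * p[i])
            out[i] = min(running, 1.0)
        return out
    if method == "bh":
        prev = 1.0
        for rank in range(m - 1, -1, -1):
            i = order[rank]
            prev = min(prev, p[i] * m / (rank + 1))
            out[i] = prev
        return out
    raise ValueError(f"unknown adjustment {method!r}")


def pairwise_permanova(
    X: np.ndarray,
    groups: Sequence[str],
    n_perm: int = 999,
    adjust: str = "bonferroni",
    seed: int | np.random.Generator = 0,
    grouping: str = "group",
) -> PermanovaResult:
    """Overall PERMANOVA plus one test per group pair, p-adjusted."""
    X = np.atleast_2d(np.asarray(X, dtype=float))
    if X.shape[0] == 1:
        X = X.T
    groups = pd.Series(list(groups))
    overall = permanova(X, groups, n_perm=n_perm, seed=seed, grouping=grouping)
    rng = np.random.default_rng(seed)
    levels = list(dict.fromkeys(groups))
    rows = []
    for a, b in itertools.combinations(levels, 2):
        mask = groups.isin([a, b]).to_numpy()
        sub = permanova(
            X[mask], groups[mask].tolist(), n_perm=n_perm,
            seed=rng, grouping=f"{a} vs {b}",
        )
        rows.append({"pair": f"{a} vs {b}", "pseudo_f": sub.pseudo_f,
                     "r_squared": sub.r_squared, "p_raw": sub.p_value})
    table = pd.DataFrame(rows)
    table["p_adjusted"] = _adjust_p(table["p_raw"].to_numpy(), adjust)
    overall.pairwise = table
    overall.adjust = adjust
    return overall


# --------------------------------------------------------------------------
# PGLS


def build_design(
    predictors: pd.DataFrame,
    coding: str = "integer",
    level_orders: Mapping[str, Sequence[str]] | None = None,
) -> tuple[np.ndarray, list[str], str]:
    """Design matrix with intercept from a predictor table.

    ``coding="integer"`` maps each categorical predictor to 0, 1, 2, … in
    its declared level order, yielding a single coefficient per factor
    (the convention behind single-row factor coefficients in compact PGLS
    tables). ``coding="dummy"`` expands k−1 treatment-coded columns.
    """
    level_orders = dict(level_orders or {})
    cols: list[np.ndarray] = [np.ones(len(predictors))]
    names = ["Intercept"]
    for name in predictors.columns:
        col = predictors[name]
        if pd.api.types.is_numeric_dtype(col):
            cols.append(col.to_numpy(dtype=float))
            names.append(name)
            continue
        levels = list(level_orders.get(name) or dict.fromkeys(col))
        unknown = sorted(set(col) - set(levels))
        if unknown:
            raise ValueError(f"{name}: values {unknown} not in level order {levels}")
        codes = np.asarray([levels.index(v) for v in col], dtype=float)
        if coding == "integer":
            cols.append(codes)
            names.append(name)
        elif coding == "dummy":
            for j, lev in enumerate(levels[1:], start=1):
                cols.append((codes == j).astype(float))
                names.append(f"{name}[{lev}]")
        else:
            raise ValueError("coding must be 'integer' or 'dummy'")
    X = np.column_stack(cols)
    return X, names, coding


def _gls_loglik(
    y: np.ndarray, X: np.ndarray, cov: PhyloCovariance, lam: float
) -> tuple[float, np.ndarray, float, np.ndarray]:
    """(logLik, beta, sigma2_ml, XtVinvX_inv) at a fixed λ."""
    V = lambda_transform(cov, lam)
    n = len(y)
    Vinv_X = V.solve(X)
    Vinv_y = V.solve(y[:, None]).ravel()
    XtVX = X.T @ Vinv_X
    beta = np.linalg.solve(XtVX, X.T @ Vinv_y)
    r = y - X @ beta
    rss = float(r @ V.solve(r[:, None]).ravel())
    sigma2 = rss / n
    if sigma2 <= 0:
        sigma2 = np.finfo(float).tiny
    ll = -0.5 * (n * np.log(2 * np.pi * sigma2) + V.log_det() + n)
    return ll, beta, sigma2, np.linalg.inv(XtVX)


def pgls_fit(
    y: np.ndarray | pd.Series,
    design: pd.DataFrame | np.ndarray,
    cov: PhyloCovariance,
    lam: float | str = "ML",
    coding: str = "integer",
    level_orders: Mapping[str, Sequence[str]] | None = None,
    grid_step: float = 0.01,
    response: str = "y",
) -> PglsFit:
    """Phylogenetic GLS with fixed or ML-estimated Pagel's λ.

    Rows of ``y`` and ``design`` must follow ``cov.tip_order``. Standard
    errors use the unbiased residual variance (rss/(n−k)) so that λ=0
    reproduces OLS inference exactly; the reported log-likelihood and AIC
    use the ML variance. AIC counts the coefficients plus σ² and λ.
    """
    y = np.asarray(y, dtype=float).ravel()
    if isinstance(design, pd.DataFrame):
        X, names, coding_used = build_design(design, coding, level_orders)
        desc = f"{' + '.join(design.columns) or '1'} [{coding_used}]"
    else:
        X = np.atleast_2d(np.asarray(design, dtype=float))
        names = [f"x{j}" for j in range(X.shape[1])]
        desc = "custom matrix"
    n, k = X.shape
    if n != len(y) or n != cov.n:
        raise ValueError("y, design and covariance sizes disagree")
    if np.linalg.matrix_rank(X) < k:
        raise ValueError("singular design matrix")

    lam_hi = lambda_max(cov)
    profile = None
    boundary = False
    if lam == "ML":
        grid = np.arange(0.0, lam_hi + 1e-12, grid_step)
        if grid[-1] < lam_hi:
            grid = np.append(grid, lam_hi)
        lls = np.array([_gls_loglik(y, X, cov, g)[0] for g in grid])
        best = int(np.argmax(lls))
        lo = grid[max(best - 1, 0)]
        hi = grid[min(best + 1, len(grid) - 1)]
        if hi > lo:
            opt = minimize_scalar(
                lambda g: -_gls_loglik(y, X, cov, g)[0],
                bounds=(lo, hi), method="bounded",
                options={"xatol": 1e-6},
            )
            lam_hat = float(opt.x)
            if _gls_loglik(y, X, cov, lam_hat)[0] < lls[best]:
                lam_hat = float(grid[best])
        else:
            lam_hat = float(grid[best])
        boundary = best in (0, len(grid) - 1)
        profile = pd.DataFrame({"lambda": grid, "log_likelihood": lls})
    else:
        lam_hat = float(lam)
        if lam_hat < 0 or lam_hat > lam_hi + 1e-9:
            raise ValueError(f"lambda {lam_hat} outside [0, {lam_hi:.4f}]")

    ll, beta, sigma2_ml, XtVX_inv = _gls_loglik(y, X, cov, lam_hat)
    df = n - k
    sigma2_resid = sigma2_ml * n / df
    se = np.sqrt(np.diag(XtVX_inv) * sigma2_resid)
    t = beta / se
    p = 2 * stats.t.sf(np.abs(t), df)
    coef = pd.DataFrame(
        {"estimate": beta, "se": se, "t": t, "p": p}, index=names
    )
    aic = -2 * ll + 2 * (k + 2)
    return PglsFit(
        response=response,
        design_description=desc,
        lam=lam_hat,
        lam_interval=(0.0, lam_hi),
        coefficients=coef,
        sigma2=sigma2_ml,
        log_likelihood=ll,
        aic=aic,
        n=n,
        df_residual=df,
        lam_profile=profile,
        boundary=boundary,
    )


def select_model(
    y: np.ndarray | pd.Series,
    candidates: Mapping[str, pd.DataFrame],
    cov: PhyloCovariance,
    response: str = "y",
    **kwargs,
) -> list[PglsFit]:
    """Fit each candidate design with ML λ and rank by AIC (ties: declaration order)."""
    if len(candidates) < 2:
        raise ValueError("need at least two candidate designs")
    sizes = {len(d) for d in candidates.values()}
    if len(sizes) != 1:
        raise ValueError("candidate designs cover mismatched species sets")
    fits = []
    for order, (name, design) in enumerate(candidates.items()):
        fit = pgls_fit(y, design, cov, lam="ML", response=response, **kwargs)
        fit.design_description = f"{response} ~ {name}"
        fits.append((fit.aic, order, fit))
    fits.sort(key=lambda t: (t[0], t[1]))
    return [f for _, _, f in fits]
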