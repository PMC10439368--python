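"""Phylogenetic PCA, shape PCA and bootstrap ratio spectra.

Two ordinations of log-shape data are provided:

* **pPCA** — principal components of the evolutionary covariance
  R = (X − 1a)' C⁻¹ (X − 1a)/(n−1), where C is the Brownian-motion
  covariance of the phylogeny and a = (1'C⁻¹1)⁻¹ 1'C⁻¹X is the
  phylogenetic (GLS) mean. Scores are (X − 1a)·V. Percent variance is
  taken from the eigenvalues of R (covariance-mode convention).

* **SPCA** — ordinary covariance PCA after projecting each specimen's
  log-measurements orthogonally to the isometric size direction
  (row-centering), i.e. PCA in isometry-free shape space. At most p−1
  eigenvalues are nonzero because the isometry direction is annihilated.

A PCA *ratio spectrum* orders one component's loadings on a line: the gap
between two variables approximates how much of that component's variance
the corresponding log-ratio explains, so the endpoint pair is the dominant
ratio. Uncertainty comes from bootstrap resampling of species, with
replicate axes aligned to the point estimate by maximal |dot| matching and
sign flips.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance

__all__ = [
    "OrdinationResult",
    "RatioSpectrum",
    "ppca",
    "spca",
    "ratio_spectrum",
    "allometry_spectrum",
]


@dataclass
class OrdinationResult:
    """Eigen-decomposition of a (phylogenetic or shape) covariance."""

    method: str  # "pPCA" | "SPCA"
    variables: tuple[str, ...]
    eigenvalues: np.ndarray  # descending
    loadings: np.ndarray  # p × k, orthonormal columns
    scores: np.ndarray  # n × k
    percent_variance: np.ndarray
    mean: np.ndarray  # phylogenetic (pPCA) or ordinary (SPCA) column mean
    evolutionary_covariance: np.ndarray | None = None  # pPCA only
    species: tuple[str, ...] = ()

    @property
    def n_axes(self) -> int:
        return self.loadings.shape[1]

    def scores_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        idx = list(self.species) if self.species else None
        return pd.DataFrame(self.scores, columns=cols, index=idx)

    def loadings_frame(self) -> pd.DataFrame:
        cols = [f"PC{i + 1}" for i in range(self.n_axes)]
        return pd.DataFrame(self.loadings, index=list(self.variables), columns=cols)


@dataclass
class RatioSpectrum:
    """One axis's loadings with bootstrap intervals and the dominant pair."""

    axis: str
    variables: tuple[str, ...]
    point: np.ndarray
    lower: np.ndarray
    upper: np.ndarray
    n_boot: int
    ci: float
    dominant_pair: tuple[str, str]
    skipped_replicates: int = 0
    axis_swaps: int = 0
    replicates: np.ndarray | None = None  # n_boot × p aligned bootstrap draws

    def frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            {"point": self.point, "lower": self.lower, "upper": self.upper},
            index=list(self.variables),
        )


def _fix_signs(vectors: np.ndarray) -> np.ndarray:
    """Make each column's largest-|loading| entry positive (reproducibility)."""
    V = vectors.copy()
    for j in range(V.shape[1]):
        i = int(np.argmax(np.abs(V[:, j])))
        if V[i, j] < 0:
            V[:, j] = -V[:, j]
    return V


def _eig_descending(S: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    w, V = np.linalg.eigh(S)
    order = np.argsort(w)[::-1]
    return w[order], _fix_signs(V[:, order])


def ppca(
    X: np.ndarray,
    cov: PhyloCovariance,
    variables: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
    mode: str = "covariance",
) -> OrdinationResult:
    """Phylogenetic PCA under Brownian motion.

    Rows of ``X`` must follow ``cov.tip_order``. ``mode`` is
    ``"covariance"`` (default) or ``"correlation"``.
    """
    X = np.asarray(X, dtype=float)
    n, p = X.shape
    if n != cov.n:
        raise ValueError("X rows do not match the covariance tip order")
    ones = np.ones((n, 1))
    Cinv_X = cov.solve(X)
    Cinv_1 = cov.solve(ones)
    a = (ones.T @ Cinv_X) / float((ones.T @ Cinv_1)[0, 0])  # 1 × p GLS mean
    Xc = X - a
    R = Xc.T @ cov.solve(Xc) / (n - 1)
    if mode == "correlation":
        d = np.sqrt(np.diag(R))
        R = R / np.outer(d, d)
    elif mode != "covariance":
        raise ValueError("mode must be 'covariance' or 'correlation'")
    w, V = _eig_descending(R)
    w = np.where(np.abs(w) < 1e-12 * max(w.max(), 1.0), np.abs(w), w)
    if w.min() < -1e-10:
        raise ValueError("evolutionary covariance has a significantly negative eigenvalue")
    scores = Xc @ V
    pct = 100.0 * w / w.sum()
    return OrdinationResult(
        "pPCA",
        tuple(variables) if variables is not None else tuple(f"v{j}" for j in range(p)),
        w, V, scores, pct, a.ravel(),
        evolutionary_covariance=R,
        species=tuple(species) if species is not None else tuple(cov.tip_order),
    )


def isometry_basis(p: int) -> np.ndarray:
    """Orthonormal basis (p × p−1) of the subspace orthogonal to isometry.

    Helmert-style contrasts. Projecting log-shape rows onto this basis
    gives full-rank coordinates of shape space — log-shape itself sums to
    zero per row, so its covariance is singular in the original p
    variables. Discriminant analysis, being affine-invariant, is run in
    these coordinates.
    """
    H = np.zeros((p, p - 1))
    for j in range(1, p):
        H[:j, j - 1] = 1.0 / np.sqrt(j * (j + 1))
        H[j, j - 1] = -j / np.sqrt(j * (j + 1))
    return H


def isometry_free(Y: np.ndarray) -> np.ndarray:
    """Project log-measurements orthogonally to the isometric size axis.

    Row-centering: identical to taking log-Mosimann shape variables.
    """
    Y = np.asarray(Y, dtype=float)
    return Y - Y.mean(axis=1, keepdims=True)


def spca(
    Y: np.ndarray,
    variables: Sequence[str] | None = None,
    species: Sequence[str] | None = None,
) -> OrdinationResult:
    """Shape PCA: covariance PCA of log-measurements in isometry-free space."""
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n < 3:
        raise ValueError("SPCA needs at least 3 species")
    if np.any(np.ptp(Y, axis=0) == 0):
        raise ValueError("constant column in log-measurement matrix")
    Z = isometry_free(Y)
    Zc = Z - Z.mean(axis=0, keepdims=True)
    S = Zc.T @ Zc / (n - 1)
    w, V = _eig_descending(S)
    w = np.clip(w, 0.0, None)
    scores = Zc @ V
    pct = 100.0 * w / w.sum()
    return OrdinationResult(
        "SPCA",
        tuple(variables) if variables is not None else tuple(f"v{j}" for j in range(p)),
        w, V, scores, pct, Z.mean(axis=0),
        species=tuple(species) if species is not None else (),
    )


def _align_to(point: np.ndarray, reps: np.ndarray) -> tuple[np.ndarray, bool]:
    """Pick the replicate column best matching ``point`` and fix its sign.

    ``reps`` is p × k (all replicate axes); returns the aligned axis and
    whether an axis swap occurred.
    """
    dots = point @ reps
    j = int(np.argmax(np.abs(dots)))
    vec = reps[:, j] if dots[j] >= 0 else -reps[:, j]
    return vec, j != 0


def ratio_spectrum(
    Y: np.ndarray,
    axis: int = 0,
    n_boot: int = 999,
    ci: float = 0.68,
    seed: int | np.random.Generator = 0,
    variables: Sequence[str] | None = None,
) -> RatioSpectrum:
    """Bootstrap ratio spectrum for one SPCA axis.

    Species (rows) are resampled with replacement; each replicate's SPCA
    axes are matched to the point-estimate axis by maximal |dot| and
    sign-aligned before taking the central ``ci`` percentile interval.
    Degenerate replicates are skipped and redrawn up to 10 × ``n_boot``
    attempts.
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    if axis > p - 2:
        raise ValueError("axis exceeds the p-1 nonzero SPCA axes")
    rng = np.random.default_rng(seed)
    res = spca(Y, variables=variables)
    point = res.loadings[:, axis]
    # compare against the leading axes around the target when matching
    k = min(p - 1, max(axis + 3, 5))
    reps = np.empty((n_boot, p))
    skipped = swaps = 0
    got = 0
    attempts = 0
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        attempts += 1
        rows = rng.integers(0, n, size=n)
        Yb = Y[rows]
        try:
            rb = spca(Yb)
        except ValueError:
            skipped += 1
            continue
        vec, swapped = _align_to(point, rb.loadings[:, :k])
        swaps += int(swapped)
        reps[got] = vec
        got += 1
    alpha = (1.0 - ci) / 2.0
    lower = np.quantile(reps, alpha, axis=0)
    upper = np.quantile(reps, 1.0 - alpha, axis=0)
    lower = np.minimum(lower, point)
    upper = np.maximum(upper, point)
    names = res.variables
    dom = (names[int(np.argmax(point))], names[int(np.argmin(point))])
    return RatioSpectrum(
        f"PC{axis + 1}", names, point, lower, upper,
        n_boot, ci, dom, skipped_replicates=skipped, axis_swaps=swaps,
        replicates=reps,
    )


def _allometry_coefficients(Y: np.ndarray) -> np.ndarray:
    """Per-variable slope of log-shape on log isometric size (row mean)."""
    size = Y.mean(axis=1)
    shape = Y - size[:, None]
    s = size - size.mean()
    denom = float(s @ s)
    if denom == 0:
        raise ValueError("zero variance in size")
    return s @ (shape - shape.mean(axis=0)) / denom


def allometry_spectrum(
    Y: np.ndarray,
    n_boot: int = 999,
    ci: float = 0.68,
    seed: int | np.random.Generator = 0,
    variables: Sequence[str] | None = None,
) -> RatioSpectrum:
    """Allometry ratio spectrum: per-variable allometric slopes with bootstrap CIs.

    A coefficient of 0 for every variable is perfect isometry. "Shape not
    significantly correlated with size" is operationalized as: every
    pairwise difference of coefficients has a CI covering 0 (see
    :func:`pairwise_difference_covers_zero`).
    """
    Y = np.asarray(Y, dtype=float)
    n, p = Y.shape
    if n_boot < 1:
        raise ValueError("n_boot must be >= 1")
    rng = np.random.default_rng(seed)
    point = _allometry_coefficients(Y)
    reps = np.empty((n_boot, p))
    skipped = 0
    got = 0
    attempts = 0
    while got < n_boot:
        if attempts >= 10 * n_boot:
            raise RuntimeError("too many degenerate bootstrap replicates")
        attempts += 1
        rows = rng.integers(0, n, size=n)
        try:
            reps[got] = _allometry_coefficients(Y[rows])
        except ValueError:
            skipped += 1
            continue
        got += 1
    alpha = (1.0 - ci) / 2.0
    lower = np.minimum(np.quantile(reps, alpha, axis=0), point)
    upper = np.maximum(np.quantile(reps, 1.0 - alpha, axis=0), point)
    names = tuple(variables) if variables is not None else tuple(
        f"v{j}" for j in range(p)
    )
    dom = (names[int(np.argmax(point))], names[int(np.argmin(point))])
    return RatioSpectrum(
        "allometry", names, point, lower, upper,
        n_boot, ci, dom, skipped_replicates=skipped, replicates=reps,
    )


def pairwise_difference_covers_zero(
    spectrum: RatioSpectrum, alpha: float = 0.05
) -> bool:
    """Family-wise test that no pairwise coefficient contrast is nonzero.

    Bootstrap percentile CIs of each pairwise difference v_i − v_j at the
    Bonferroni-adjusted level 1 − alpha/m (m = p(p−1)/2 pairs), so the
    family false-positive rate is ≈ alpha. "Shape not significantly
    correlated with size" corresponds to this returning True for the
    allometry spectrum.
    """
    reps = spectrum.replicates
    if reps is None:
        raise ValueError("spectrum carries no bootstrap replicates")
    p = reps.shape[1]
    m = p * (p - 1) // 2
    a = alpha / m / 2.0
    for i in range(p):
        for j in range(i + 1, p):
            d = reps[:, i] - reps[:, j]
            lo, hi = np.quantile(d, a), np.quantile(d, 1.0 - a)
            if lo > 0 or hi < 0:
                return False
    return True
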