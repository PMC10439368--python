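"""Linear and phylogenetic flexible discriminant analysis.

LDA is the classical Gaussian discriminant with a pooled within-class
covariance and priors defaulting to observed class proportions; its
resubstitution confusion matrix is the headline classification metric.

pFDA accounts for phylogenetic covariance in the estimation step: with
C(λ) the Pagel-λ transform of the Brownian-motion covariance and L its
lower Cholesky factor, both the predictor matrix X and the class-indicator
matrix G are premultiplied by L⁻¹ (GLS whitening). Class means are then
the GLS estimates (G*'G*)⁻¹G*'X* and the pooled within-class covariance
comes from the whitened residuals — the evolutionary (rate-scale)
covariance. Classification applies the usual Gaussian rule to the raw
trait rows with these phylogenetically estimated parameters; with linear
regression this optimal-scoring construction reduces at λ=0 on a
unit-height ultrametric tree exactly to LDA.

The "optimal" λ maximizes the Gaussian log-likelihood of the whitened
multivariate regression of X on the class indicators — including the
−p/2·log|C(λ)| Jacobian of the whitening transform, without which the
criterion would not trade whitening benefit against variance shrinkage.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from .phylo import PhyloCovariance, lambda_max, lambda_transform

__all__ = [
    "DiscriminantModel",
    "ConfusionMatrix",
    "CasewisePrediction",
    "lda_fit",
    "pfda_fit",
    "optimal_lambda",
    "predict",
    "predict_unlabeled_tips",
    "confusion",
    "confusion_from_counts",
    "casewise_report",
]


@dataclass
class DiscriminantModel:
    method: str  # "LDA" | "pFDA"
    levels: tuple[str, ...]
    priors: np.ndarray
    class_means: np.ndarray  # k × p
    pooled_cov: np.ndarray  # p × p
    variables: tuple[str, ...]
    directions: np.ndarray  # p × min(p, k-1) discriminant directions
    proportion_of_trace: np.ndarray  # percent per direction
    lam: float | None = None
    tip_order: tuple[str, ...] = ()
    lam_trace: pd.DataFrame | None = None
    # training covariance context for held-out prediction (pFDA)
    _cov: PhyloCovariance | None = field(default=None, repr=False)

    @property
    def k(self) -> int:
        return len(self.levels)


@dataclass
class ConfusionMatrix:
    """Rows = true class, columns = predicted class (Tables 4–5 layout)."""

    levels: tuple[str, ...]
    counts: pd.DataFrame

    @property
    def row_n(self) -> pd.Series:
        return self.counts.sum(axis=1)

    @property
    def row_percent(self) -> pd.DataFrame:
        return 100.0 * self.counts.div(self.row_n.replace(0, np.nan), axis=0)

    @property
    def accuracy(self) -> float:
        """Overall accuracy in percent: 100·trace/total."""
        total = float(self.counts.to_numpy().sum())
        return 100.0 * float(np.trace(self.counts.to_numpy())) / total

    def to_text(self) -> str:
        pct = self.row_percent.round(1)
        lines = [f"overall accuracy: {self.accuracy:.1f}%", "counts:",
                 self.counts.to_string(), "row %:", pct.to_string()]
        return "\n".join(lines)


@dataclass
class CasewisePrediction:
    species_id: str
    true_label: str | None
    predicted: str
    posterior: dict[str, float]
    correct: bool | None = None
    matches_alternative: bool | None = None
    proxy_label_used: bool = False


def _check_classes(labels: pd.Series, levels: Sequence[str] | None):
    if levels is None:
        levels = list(dict.fromkeys(labels))
    counts = labels.value_counts()
    small = [g for g in levels if counts.get(g, 0) < 2]
    if small:
        raise ValueError(f"class(es) with fewer than 2 members: {small}")
    return tuple(levels)


def _discriminant_axes(
    means: np.ndarray, pooled: np.ndarray, priors: np.ndarray
) -> tuple[np.ndarray, np.ndarray]:
    """Directions and proportion-of-trace from the between/within eigenproblem."""
    k, p = means.shape
    grand = priors @ means
    Bhalf = (means - grand) * np.sqrt(priors)[:, None]
    B = Bhalf.T @ Bhalf  # between-class covariance (prior-weighted)
    # solve W^{-1}B via the symmetric whitened problem
    evals_w, evecs_w = np.linalg.eigh(pooled)
    evals_w = np.clip(evals_w, 1e-12 * evals_w.max(), None)
    Whalf_inv = evecs_w @ np.diag(evals_w**-0.5) @ evecs_w.T
    M = Whalf_inv @ B @ Whalf_inv
    w, V = np.linalg.eigh(M)
    order = np.argsort(w)[::-1]
    n_axes = min(p, k - 1)
    w = np.clip(w[order][:n_axes], 0.0, None)
    directions = Whalf_inv @ V[:, order][:, :n_axes]
    for j in range(directions.shape[1]):
        i = int(np.argmax(np.abs(directions[:, j])))
        if directions[i, j] < 0:
            directions[:, j] = -directions[:, j]
    pot = 100.0 * w / w.sum() if w.sum() > 0 else np.zeros_like(w)
    return directions, pot


def _gaussian_fit(
    X: np.ndarray,
    G: np.ndarray,
    levels: tuple[str, ...],
    priors: np.ndarray,
) -> tuple[np.ndarray, np.ndarray]:
    """Class means (G'G)⁻¹G'X and pooled covariance of the residuals."""
    n, p = X.shape
    k = len(levels)
    GtG = G.T @ G
    try:
        means = np.linalg.solve(GtG, G.T @ X)
    except np.linalg.LinAlgError as exc:
        raise ValueError("degenerate class-indicator system") from exc
    resid = X - G @ means
    pooled = resid.T @ resid / (n - k)
    if np.linalg.matrix_rank(pooled, tol=1e-10 * np.abs(pooled).max()) < p:
        raise ValueError(
            "singular pooled within-class covariance; "
            "remove collinear or constant variables"
        )
    return means, pooled


def lda_fit(
    X: np.ndarray,
    labels: Sequence[str],
    priors: str | np.ndarray = "proportional",
    levels: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> DiscriminantModel:
    """Gaussian LDA with shared covariance and proportional priors by default."""
    X = np.asarray(X, dtype=float)
    labels = pd.Series(list(labels))
    levels = _check_classes(labels, levels)
    k = len(levels)
    n, p = X.shape
    counts = np.array([(labels == g).sum() for g in levels], dtype=float)
    if isinstance(priors, str):
        if priors == "proportional":
            pri = counts / n
        elif priors == "uniform":
            pri = np.full(k, 1.0 / k)
        else:
            raise ValueError("priors must be 'proportional', 'uniform' or an array")
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    G = np.zeros((n, k))
    for j, g in enumerate(levels):
        G[np.asarray(labels == g), j] = 1.0
    means, pooled = _gaussian_fit(X, G, levels, pri)
    directions, pot = _discriminant_axes(means, pooled, pri)
    return DiscriminantModel(
        "LDA", levels, pri, means, pooled,
        tuple(variables) if variables is not None else tuple(f"v{j}" for j in range(p)),
        directions, pot,
    )


def _posteriors(model: DiscriminantModel, X: np.ndarray) -> np.ndarray:
    """Gaussian class posteriors with the pooled covariance."""
    evals, evecs = np.linalg.eigh(model.pooled_cov)
    evals = np.clip(evals, 1e-12 * evals.max(), None)
    Whalf_inv = evecs @ np.diag(evals**-0.5) @ evecs.T
    Z = X @ Whalf_inv
    M = model.class_means @ Whalf_inv
    d2 = ((Z[:, None, :] - M[None, :, :]) ** 2).sum(axis=2)
    logp = -0.5 * d2 + np.log(model.priors)[None, :]
    logp -= logp.max(axis=1, keepdims=True)
    post = np.exp(logp)
    return post / post.sum(axis=1, keepdims=True)


def predict(
    model: DiscriminantModel,
    X: np.ndarray,
    species: Sequence[str] | None = None,
    true_labels: Sequence[str] | None = None,
    alt_labels: Sequence[str | None] | None = None,
    proxy_flags: Sequence[bool] | None = None,
) -> list[CasewisePrediction]:
    """Case-wise class predictions with posteriors.

    ``X`` holds raw trait rows for both LDA and pFDA models (pFDA differs
    only in how means and covariance were estimated); tips inside the
    training tree but without labels go through
    :func:`predict_unlabeled_tips`, which conditions on the training
    residuals. Posterior ties resolve to the first class in declared level
    order (argmax keeps the earliest index).
    """
    X = np.asarray(X, dtype=float)
    if X.shape[1] != len(model.variables):
        raise ValueError("column mismatch with training variables")
    post = _posteriors(model, X)
    pred_idx = np.argmax(post, axis=1)
    n = X.shape[0]
    species = list(species) if species is not None else [f"s{i}" for i in range(n)]
    out = []
    for i in range(n):
        truth = true_labels[i] if true_labels is not None else None
        alt = alt_labels[i] if alt_labels is not None else None
        pred = model.levels[pred_idx[i]]
        out.append(
            CasewisePrediction(
                species_id=species[i],
                true_label=truth,
                predicted=pred,
                posterior={g: float(post[i, j]) for j, g in enumerate(model.levels)},
                correct=(pred == truth) if truth is not None else None,
                matches_alternative=(pred == alt) if alt else None,
                proxy_label_used=bool(proxy_flags[i]) if proxy_flags is not None else False,
            )
        )
    return out


def confusion(
    truth: Sequence[str],
    predicted: Sequence[str],
    levels: Sequence[str] | None = None,
) -> ConfusionMatrix:
    """Count matrix (rows true, columns predicted) with row % and accuracy."""
    truth = list(truth)
    predicted = list(predicted)
    if len(truth) != len(predicted):
        raise ValueError("truth and predicted lengths differ")
    if levels is None:
        levels = list(dict.fromkeys(list(truth) + predicted))
    unseen = sorted((set(truth) | set(predicted)) - set(levels))
    if unseen:
        raise ValueError(f"label(s) outside the level set: {unseen}")
    levels = tuple(levels)
    counts = pd.DataFrame(0, index=list(levels), columns=list(levels))
    for t, p in zip(truth, predicted):
        counts.loc[t, p] += 1
    return ConfusionMatrix(levels, counts)


def confusion_from_counts(
    counts: pd.DataFrame | np.ndarray, levels: Sequence[str] | None = None
) -> ConfusionMatrix:
    """Wrap an already-tabulated count matrix (e.g. a published table)."""
    if isinstance(counts, pd.DataFrame):
        levels = tuple(levels) if levels is not None else tuple(counts.index)
        df = counts.copy()
        df.index = list(levels)
        df.columns = list(levels)
    else:
        arr = np.asarray(counts)
        if levels is None:
            levels = tuple(f"c{i}" for i in range(arr.shape[0]))
        df = pd.DataFrame(arr, index=list(levels), columns=list(levels))
    if (df.to_numpy() < 0).any():
        raise ValueError("negative count")
    return ConfusionMatrix(tuple(levels), df)


# --------------------------------------------------------------------------
# pFDA


def _whiten(cov: PhyloCovariance, lam: float, *arrays: np.ndarray) -> list[np.ndarray]:
    V = lambda_transform(cov, lam)
    L = V.cholesky_lower()
    from scipy.linalg import solve_triangular

    return [solve_triangular(L, A, lower=True) for A in arrays]


def _whitened_regression_loglik(
    X: np.ndarray, G: np.ndarray, cov: PhyloCovariance, lam: float
) -> float:
    """Gaussian log-likelihood of X ~ matrix-normal(G·M, C(λ), Σ̂)."""
    n, p = X.shape
    Xw, Gw = _whiten(cov, lam, X, G)
    GtG = Gw.T @ Gw
    M = np.linalg.solve(GtG, Gw.T @ Xw)
    R = Xw - Gw @ M
    S = R.T @ R / n
    sign, logdet_S = np.linalg.slogdet(S + 1e-12 * np.trace(S) / p * np.eye(p))
    if sign <= 0:
        return -np.inf
    V = lambda_transform(cov, lam)
    return float(
        -0.5 * n * logdet_S - 0.5 * p * V.log_det()
        - 0.5 * n * p * (1 + np.log(2 * np.pi))
    )


def optimal_lambda(
    X: np.ndarray,
    labels: Sequence[str],
    cov: PhyloCovariance,
    grid_step: float = 0.01,
    levels: Sequence[str] | None = None,
) -> tuple[float, pd.DataFrame]:
    """Grid-search λ maximizing the whitened-regression log-likelihood.

    Returns the argmax and the full (λ, log-likelihood) trace for audit.
    """
    X = np.asarray(X, dtype=float)
    if np.all(np.ptp(X, axis=0) == 0):
        raise ValueError("constant predictor matrix; lambda is unidentifiable")
    labels = pd.Series(list(labels))
    levels = _check_classes(labels, levels)
    n = len(labels)
    G = np.zeros((n, len(levels)))
    for j, g in enumerate(levels):
        G[np.asarray(labels == g), j] = 1.0
    hi = lambda_max(cov, cap=1.0)
    grid = np.arange(0.0, hi + 1e-12, grid_step)
    lls = np.array([_whitened_regression_loglik(X, G, cov, g) for g in grid])
    best = int(np.argmax(lls))
    trace = pd.DataFrame({"lambda": grid, "log_likelihood": lls})
    return float(grid[best]), trace


def pfda_fit(
    X: np.ndarray,
    labels: Sequence[str],
    cov: PhyloCovariance,
    lam: float | str = "optimal",
    priors: str | np.ndarray = "proportional",
    levels: Sequence[str] | None = None,
    variables: Sequence[str] | None = None,
) -> DiscriminantModel:
    """Phylogenetic flexible discriminant analysis.

    Rows of ``X`` must follow ``cov.tip_order``. λ may be a number or
    ``"optimal"`` (grid-search via :func:`optimal_lambda`).
    """
    X = np.asarray(X, dtype=float)
    labels = pd.Series(list(labels))
    levels = _check_classes(labels, levels)
    k = len(levels)
    n, p = X.shape
    if n != cov.n:
        raise ValueError("X rows do not match the covariance tip order")
    trace = None
    if lam == "optimal":
        lam, trace = optimal_lambda(X, labels, cov, levels=levels)
    lam = float(lam)
    G = np.zeros((n, k))
    for j, g in enumerate(levels):
        G[np.asarray(labels == g), j] = 1.0
    Xw, Gw = _whiten(cov, lam, X, G)
    counts = G.sum(axis=0)
    if isinstance(priors, str):
        pri = counts / n if priors == "proportional" else np.full(k, 1.0 / k)
    else:
        pri = np.asarray(priors, dtype=float)
        pri = pri / pri.sum()
    means, pooled = _gaussian_fit(Xw, Gw, levels, pri)
    directions, pot = _discriminant_axes(means, pooled, pri)
    model = DiscriminantModel(
        "pFDA", levels, pri, means, pooled,
        tuple(variables) if variables is not None else tuple(f"v{j}" for j in range(p)),
        directions, pot,
        lam=lam, tip_order=cov.tip_order, lam_trace=trace,
        _cov=cov,
    )
    return model


def predict_unlabeled_tips(
    model: DiscriminantModel,
    X_new: np.ndarray,
    new_tips: Sequence[str],
    full_cov: PhyloCovariance,
    X_train: np.ndarray,
    species: Sequence[str] | None = None,
) -> list[CasewisePrediction]:
    """Classify held-out tips with phylogenetically conditioned residuals.

    ``full_cov`` is the Brownian covariance over training + held-out tips;
    under class g a held-out row x_h is Gaussian with mean
    m_g + c_hT C_TT⁻¹ (X_T − Ĝ M̂) and covariance scaled by the Schur
    complement c_hh − c_hT C_TT⁻¹ c_Th. With a star tree (c_hT = 0) this
    reduces to plain discriminant prediction on x_h. An LDA model ignores
    the tree context entirely.
    """
    X_new = np.atleast_2d(np.asarray(X_new, dtype=float))
    new_tips = list(new_tips)
    if len(new_tips) == 0:
        return []
    if X_new.shape[0] != len(new_tips):
        raise ValueError("X_new rows and new_tips lengths differ")
    missing = sorted(set(new_tips) - set(full_cov.tip_order))
    if missing:
        raise ValueError(f"held-out tip(s) absent from tree: {missing}")
    species = list(species) if species is not None else new_tips

    if model.method == "LDA":
        return predict(model, X_new, species=species)

    if model._cov is None:
        raise ValueError("pFDA model lacks training context")
    train_tips = list(model.tip_order)
    lam = float(model.lam)
    Cfull = lambda_transform(full_cov, lam)
    order = {t: i for i, t in enumerate(Cfull.tip_order)}
    ti = [order[t] for t in train_tips]
    hi = [order[t] for t in new_tips]
    C_TT = Cfull.matrix[np.ix_(ti, ti)]
    C_hT = Cfull.matrix[np.ix_(hi, ti)]
    C_hh = Cfull.matrix[np.ix_(hi, hi)]
    X_train = np.asarray(X_train, dtype=float)

    Ainv = np.linalg.solve(C_TT, np.eye(len(ti)))
    out: list[CasewisePrediction] = []
    k = model.k
    means_raw = model.class_means  # GLS class means are on the raw trait scale
    # posterior per held-out tip, conditioning on the training residuals
    for h in range(len(new_tips)):
        w = C_hT[h] @ Ainv  # 1 × n_train
        scale = float(C_hh[h, h] - C_hT[h] @ Ainv @ C_hT[h])
        scale = max(scale, 1e-12 * C_hh[h, h] if C_hh[h, h] > 0 else 1e-12)
        logp = np.empty(k)
        evals, evecs = np.linalg.eigh(model.pooled_cov * scale)
        evals = np.clip(evals, 1e-12 * evals.max(), None)
        Whalf_inv = evecs @ np.diag(evals**-0.5) @ evecs.T
        for j in range(k):
            mean_h = means_raw[j] + w @ (X_train - means_raw[j][None, :])
            z = (X_new[h] - mean_h) @ Whalf_inv
            logp[j] = -0.5 * float(z @ z) + np.log(model.priors[j])
        logp -= logp.max()
        post = np.exp(logp)
        post /= post.sum()
        pred = model.levels[int(np.argmax(post))]
        out.append(
            CasewisePrediction(
                species_id=species[h],
                true_label=None,
                predicted=pred,
                posterior={g: float(post[j]) for j, g in enumerate(model.levels)},
            )
        )
    return out


def casewise_report(
    predictions: list[CasewisePrediction],
    comparison: list[CasewisePrediction] | None = None,
) -> dict:
    """Aggregate case-wise predictions into agreement counts.

    Counts primary-correct, alternative-correct (secondary label matched
    when the primary was missed), proxy-correct (correct where the label
    came from a related proxy species) and misclassified-despite-certainty
    (wrong, no secondary label, no proxy). With a second prediction set,
    the cross-method agreement rate is added.
    """
    counts = {
        "n": len(predictions),
        "primary_correct": 0,
        "alternative_correct": 0,
        "proxy_correct": 0,
        "misclassified_certain": 0,
    }
    for pr in predictions:
        if pr.correct is None:
            continue
        if pr.correct:
            counts["primary_correct"] += 1
            if pr.proxy_label_used:
                counts["proxy_correct"] += 1
        elif pr.matches_alternative:
            counts["alternative_correct"] += 1
        elif not pr.proxy_label_used and pr.matches_alternative is None:
            counts["misclassified_certain"] += 1
    if comparison is not None:
        by_id = {pr.species_id: pr.predicted for pr in comparison}
        ids = [pr.species_id for pr in predictions]
        missing = sorted(set(ids) - set(by_id))
        if missing:
            raise ValueError(f"comparison set lacks species {missing}")
        agree = sum(pr.predicted == by_id[pr.species_id] for pr in predictions)
        counts["agreement_rate"] = agree / len(predictions) if predictions else 1.0
    return counts
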