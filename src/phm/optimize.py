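"""Feature optimization: QDA discriminant scores and the OFNDA projection.

Two alternative branches (evaluated separately, never chained):

* **QDA** — per-activity Gaussian discriminants
  δ_m(x) = −½ log|Σ_m| − ½ (x−μ_m)ᵀ Σ_m⁻¹ (x−μ_m) + log π_m
  with diagonal shrinkage Σ_m ← (1−λ_s)·S_m + λ_s·diag(S_m).  The
  "optimized" representation of a sample is its M-vector of class scores.

* **OFNDA** — orthogonal fuzzy neighborhood discriminant analysis: fuzzy
  memberships from a regularized objective with an exponential
  distance-growth weight exp((|x_k−v_i|/(η_i/3))²), η_i = max_k|x_k−v_i|;
  centers iterated to convergence; fuzzy within/between scatters; leading
  eigenvectors of pinv(S_w)·S_b orthonormalized by Gram–Schmidt give the
  projection W with WᵀW = I.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# QDA
# ---------------------------------------------------------------------------

@dataclass
class QdaModel:
    """Per-activity Gaussian discriminant parameters."""

    classes: np.ndarray
    means: np.ndarray  # M × d
    covs: np.ndarray  # M × d × d (after shrinkage + numerical ridge)
    priors: np.ndarray
    _chol: np.ndarray = field(default=None, repr=False)
    _logdet: np.ndarray = field(default=None, repr=False)


def fit_qda(X: np.ndarray, y: np.ndarray, shrinkage: float = 0.1) -> QdaModel:
    """Fit per-class means, shrunk covariances and empirical priors.

    ``shrinkage`` λ_s ∈ [0, 1] blends the sample covariance toward its own
    diagonal; a tiny uniform ridge keeps log-determinants finite when
    feature blocks are constant within a class.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if not (0.0 <= shrinkage <= 1.0):
        raise ValueError("shrinkage must be in [0, 1]")
    classes = np.unique(y)
    d = X.shape[1]
    means = np.empty((len(classes), d))
    covs = np.empty((len(classes), d, d))
    priors = np.empty(len(classes))
    ridge_scale = 1e-8 * max(X.var(), 1.0)
    for m, c in enumerate(classes):
        Xc = X[y == c]
        if len(Xc) < 2 and shrinkage < 1.0:
            raise ValueError(f"class {c!r} has fewer than 2 samples")
        means[m] = Xc.mean(axis=0)
        S = np.cov(Xc, rowvar=False, bias=True) if len(Xc) > 1 else np.zeros((d, d))
        S = np.atleast_2d(S)
        S = (1.0 - shrinkage) * S + shrinkage * np.diag(np.diag(S))
        covs[m] = S + ridge_scale * np.eye(d)
        priors[m] = len(Xc) / len(X)
    model = QdaModel(classes, means, covs, priors)
    model._chol = np.array([np.linalg.cholesky(S) for S in covs])
    model._logdet = np.array(
        [2.0 * np.sum(np.log(np.diag(L))) for L in model._chol]
    )
    return model


def qda_scores(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Discriminant scores δ_m(x) for every class; shape n × M."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.means.shape[1]:
        raise ValueError(
            f"dimension mismatch: model has {model.means.shape[1]} features,"
            f" input has {X.shape[1]}"
        )
    out = np.empty((X.shape[0], len(model.classes)))
    for m in range(len(model.classes)):
        diff = X - model.means[m]
        L = model._chol[m]
        w = np.linalg.solve(L, diff.T)
        maha = np.sum(w**2, axis=0)
        out[:, m] = -0.5 * model._logdet[m] - 0.5 * maha + np.log(model.priors[m])
    return out


def qda_transform(model: QdaModel, X: np.ndarray) -> np.ndarray:
    """Map samples to their class-score vectors (the QDA-optimized features)."""
    return qda_scores(model, X)


def qda_predict(model: QdaModel, X: np.ndarray) -> np.ndarray:
    return model.classes[np.argmax(qda_scores(model, X), axis=1)]


# ---------------------------------------------------------------------------
# OFNDA
# ---------------------------------------------------------------------------

@dataclass
class OfndaModel:
    """Fuzzy partition + orthogonal discriminant projection."""

    classes: np.ndarray
    memberships: np.ndarray  # a × n
    centers: np.ndarray  # a × d
    radii: np.ndarray  # a
    projection: np.ndarray  # d × d_out, orthonormal columns
    objective: list[float]
    converged: bool
    fuzzifier: float


def _ofnda_weights(X, centers, radii):
    """Distance-growth weights exp((|x_k − v_i| / (η_i/3))²)."""
    d = np.linalg.norm(X[None, :, :] - centers[:, None, :], axis=2)  # a × n
    eta = np.where(radii > 0, radii, 1.0)
    z = d / (eta[:, None] / 3.0)
    return np.exp(np.clip(z**2, 0.0, 50.0))


def _memberships(W, p):
    """Constrained minimizer of Σ μ^p w s.t. Σ_i μ_ik = 1 (Lagrange)."""
    inv = W ** (1.0 / (1.0 - p))
    return inv / inv.sum(axis=0, keepdims=True)


def fit_ofnda(
    X: np.ndarray,
    y: np.ndarray,
    d_out: int | None = None,
    p: float = 2.0,
    max_iter: int = 200,
    tol: float = 1e-6,
) -> OfndaModel:
    """Alternating membership/center fit followed by the scatter projection.

    Initial centers are the class means (the class structure seeds the
    fuzzy neighborhoods); each center update (membership-weighted mean) is
    accepted only while the objective decreases, which makes the recorded
    objective trace non-increasing.
    """
    X = np.asarray(X, float)
    y = np.asarray(y)
    if p <= 1.0:
        raise ValueError("fuzzifier p must be > 1")
    classes = np.unique(y)
    a, (n, d) = len(classes), X.shape
    d_out = d_out if d_out is not None else max(a - 1, 1)
    if d_out > d:
        raise ValueError(f"d_out={d_out} exceeds input dimension {d}")

    centers = np.vstack([X[y == c].mean(axis=0) for c in classes])
    radii = np.linalg.norm(X[None] - centers[:, None], axis=2).max(axis=1)
    W = _ofnda_weights(X, centers, radii)
    mu = _memberships(W, p)
    objective = [float(np.sum(mu**p * W))]
    converged = False
    for _ in range(max_iter):
        wp = mu**p
        new_centers = (wp @ X) / wp.sum(axis=1, keepdims=True)
        new_radii = np.linalg.norm(X[None] - new_centers[:, None], axis=2).max(axis=1)
        Wn = _ofnda_weights(X, new_centers, new_radii)
        mun = _memberships(Wn, p)
        obj = float(np.sum(mun**p * Wn))
        shift = np.linalg.norm(new_centers - centers)
        if obj > objective[-1] + 1e-12:
            # weighted-mean step no longer lowers the exp objective: a
            # fixed-point plateau counts as convergence
            converged = shift < np.sqrt(tol) * max(np.abs(X).max(), 1.0)
            break
        centers, radii, W, mu = new_centers, new_radii, Wn, mun
        objective.append(obj)
        if shift < tol:
            converged = True
            break
    if not converged:
        log.warning("OFNDA center iteration stopped before tolerance")

    # fuzzy scatters
    wp = mu**p
    Sw = np.zeros((d, d))
    for i in range(a):
        diff = X - centers[i]
        Sw += (wp[i][:, None] * diff).T @ diff
    vbar = centers.mean(axis=0)
    Sb = np.zeros((d, d))
    for i in range(a):
        dv = (centers[i] - vbar)[:, None]
        Sb += wp[i].sum() * (dv @ dv.T)

    M = np.linalg.pinv(Sw) @ Sb
    eigval, eigvec = np.linalg.eig(M)
    order = np.argsort(eigval.real)[::-1]
    V = eigvec[:, order].real
    # sequential Gram–Schmidt orthonormalization of the leading directions
    Wproj = np.zeros((d, d_out))
    col = 0
    for j in range(V.shape[1]):
        v = V[:, j].copy()
        for kcol in range(col):
            v -= (Wproj[:, kcol] @ v) * Wproj[:, kcol]
        nv = np.linalg.norm(v)
        if nv < 1e-10:
            continue
        Wproj[:, col] = v / nv
        col += 1
        if col == d_out:
            break
    if col < d_out:
        raise np.linalg.LinAlgError("could not extract d_out independent directions")

    return OfndaModel(classes, mu, centers, radii, Wproj, objective, converged, p)


def ofnda_transform(model: OfndaModel, X: np.ndarray) -> np.ndarray:
    """Project samples: X W."""
    X = np.atleast_2d(np.asarray(X, float))
    if X.shape[1] != model.projection.shape[0]:
        raise ValueError(
            f"dimension mismatch: projection expects {model.projection.shape[0]}"
            f" features, input has {X.shape[1]}"
        )
    return X @ model.projection


def fisher_ratio(x: np.ndarray, y: np.ndarray) -> float:
    """Between/within variance ratio of a 1-D feature (two or more classes)."""
    x = np.asarray(x, float).ravel()
    classes = np.unique(y)
    grand = x.mean()
    between = sum((x[y == c].mean() - grand) ** 2 * np.sum(y == c) for c in classes)
    within = sum(np.sum((x[y == c] - x[y == c].mean()) ** 2) for c in classes)
    return float(between / within) if within > 0 else np.inf
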