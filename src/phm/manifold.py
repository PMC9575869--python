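"""Semi-supervised classification by manifold regularization.

The estimator minimizes, over a reproducing-kernel Hilbert space H,

    Σ_i (y_i − f(x_i))² + γ_A ‖f‖²_H + γ_I fᵀ L f

where L is the graph Laplacian of a k-nearest-neighbor graph with
heat-kernel weights built over labeled *and* unlabeled inputs.  With
γ_I = 0 this is plain kernel regularized least squares (RLS); with the
Laplacian term it is LapRLS, whose minimizer is a kernel expansion over all
n = l + u training points with coefficients

    α = (J K + γ_A l I + γ_I l/(l+u)² · L K)⁻¹ J y

(J the labeled-indicator diagonal).  A Nyström variant solves the
equivalent symmetric system by preconditioned conjugate gradients, with the
preconditioner built from a uniform landmark subsample of the kernel.

Multiclass handling is one-vs-rest with ±1 targets and argmax prediction.
The module also houses the evaluation report (confusion matrix, accuracy,
per-class precision/recall/F1, RMSE of scores against ±1 targets).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
from scipy.sparse.linalg import LinearOperator, cg
from scipy.spatial.distance import cdist

log = logging.getLogger(__name__)


# ---------------------------------------------------------------------------
# Kernel and graph
# ---------------------------------------------------------------------------

def median_heuristic(X: np.ndarray) -> float:
    """RBF width = median pairwise distance (subsampled above 500 points)."""
    X = np.asarray(X, float)
    if len(X) > 500:
        rng = np.random.default_rng(0)
        X = X[rng.choice(len(X), 500, replace=False)]
    d = cdist(X, X)
    med = np.median(d[np.triu_indices_from(d, k=1)])
    return float(med) if med > 0 else 1.0


def rbf_kernel(A: np.ndarray, B: np.ndarray, sigma: float) -> np.ndarray:
    d2 = cdist(np.atleast_2d(A), np.atleast_2d(B), "sqeuclidean")
    return np.exp(-d2 / (2.0 * sigma**2))


@dataclass(frozen=True)
class GraphSpec:
    """k-NN graph with heat-kernel weights exp(−‖xi−xj‖²/σ_g²)."""

    k: int = 7
    sigma: float | None = None  # None → median heuristic
    normalized: bool = False

    def __post_init__(self):
        if self.k < 1:
            raise ValueError("k must be >= 1")
        if self.sigma is not None and self.sigma <= 0:
            raise ValueError("sigma must be > 0")


def build_laplacian(X: np.ndarray, spec: GraphSpec = GraphSpec()) -> np.ndarray:
    """Symmetric kNN-graph Laplacian L = D − W (or normalized variant).

    The graph is the union of directed kNN edges; self-loops are excluded.
    L is symmetric positive semi-definite and annihilates the constant
    vector in the unnormalized case.
    """
    X = np.atleast_2d(np.asarray(X, float))
    n = len(X)
    if n < spec.k + 1:
        raise ValueError(f"need at least k+1 = {spec.k + 1} points")
    sigma = spec.sigma if spec.sigma is not None else median_heuristic(X)
    d2 = cdist(X, X, "sqeuclidean")
    np.fill_diagonal(d2, np.inf)
    idx = np.argpartition(d2, spec.k, axis=1)[:, : spec.k]
    W = np.zeros((n, n))
    rows = np.repeat(np.arange(n), spec.k)
    cols = idx.ravel()
    W[rows, cols] = np.exp(-d2[rows, cols] / sigma**2)
    W = np.maximum(W, W.T)  # union of directed edges
    D = W.sum(axis=1)
    L = np.diag(D) - W
    if spec.normalized:
        with np.errstate(divide="ignore"):
            dinv = np.where(D > 0, 1.0 / np.sqrt(D), 0.0)
        L = np.eye(n) - dinv[:, None] * W * dinv[None, :]
    return L


# ---------------------------------------------------------------------------
# Models
# ---------------------------------------------------------------------------

def _targets(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """±1 one-vs-rest target matrix (n × n_classes)."""
    return np.where(y[:, None] == classes[None, :], 1.0, -1.0)


@dataclass
class ManifoldModel:
    """Fitted kernel expansion f_c(x) = Σ_i α_ic k(x_i, x)."""

    algorithm: str  # rls | laprls | nystrom
    classes: np.ndarray
    X_train: np.ndarray  # expansion points (labeled [+ unlabeled])
    alpha: np.ndarray  # n × n_classes
    sigma_k: float
    gamma_a: float
    gamma_i: float = 0.0
    info: dict = field(default_factory=dict)


def fit_rls(
    X_l: np.ndarray,
    y_l: np.ndarray,
    gamma_a: float = 1e-3,
    sigma_k: float | None = None,
) -> ManifoldModel:
    """Kernel regularized least squares on labeled data only:
    α = (K + γ_A l I)⁻¹ y±."""
    if gamma_a <= 0:
        raise ValueError("gamma_a must be > 0")
    X_l = np.atleast_2d(np.asarray(X_l, float))
    y_l = np.asarray(y_l)
    classes = np.unique(y_l)
    sigma = sigma_k if sigma_k is not None else median_heuristic(X_l)
    l = len(X_l)
    K = rbf_kernel(X_l, X_l, sigma)
    alpha = np.linalg.solve(K + gamma_a * l * np.eye(l), _targets(y_l, classes))
    return ManifoldModel("rls", classes, X_l, alpha, sigma, gamma_a)


def fit_laprls(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u: np.ndarray,
    gamma_a: float = 1e-3,
    gamma_i: float = 1e-2,
    sigma_k: float | None = None,
    spec: GraphSpec = GraphSpec(),
) -> ManifoldModel:
    """Laplacian RLS over labeled + unlabeled points (closed form)."""
    if gamma_i < 0:
        raise ValueError("gamma_i must be >= 0")
    X_l = np.atleast_2d(np.asarray(X_l, float))
    X_u = np.atleast_2d(np.asarray(X_u, float)) if len(np.asarray(X_u)) else np.empty((0, X_l.shape[1]))
    y_l = np.asarray(y_l)
    classes = np.unique(y_l)
    X = np.vstack([X_l, X_u])
    l, n = len(X_l), len(X)
    sigma = sigma_k if sigma_k is not None else median_heuristic(X)
    K = rbf_kernel(X, X, sigma)
    J = np.zeros((n, n))
    J[np.arange(l), np.arange(l)] = 1.0
    Y = np.zeros((n, len(classes)))
    Y[:l] = _targets(y_l, classes)
    if gamma_i > 0 and n > spec.k:
        L = build_laplacian(X, spec)
        A = J @ K + gamma_a * l * np.eye(n) + (gamma_i * l / n**2) * (L @ K)
    else:
        A = J @ K + gamma_a * l * np.eye(n)
    alpha = np.linalg.solve(A, J @ Y)
    return ManifoldModel("laprls", classes, X, alpha, sigma, gamma_a, gamma_i)


def fit_nystrom_laprls(
    X_l: np.ndarray,
    y_l: np.ndarray,
    X_u: np.ndarray,
    m: int,
    gamma_a: float = 1e-3,
    gamma_i: float = 1e-2,
    sigma_k: float | None = None,
    spec: GraphSpec = GraphSpec(),
    pcg_tol: float = 1e-8,
    max_pcg_iter: int = 500,
    seed: int = 0,
) -> ManifoldModel:
    """LapRLS solved by preconditioned CG with a Nyström preconditioner.

    The nonsymmetric closed-form system (M K + γ_A l I) α = J y with
    M = J + c L is symmetrized by a left multiplication with K (both sides
    live in the range of K), giving the PSD system
    (K M K + γ_A l K) α = K J y, solved by CG.  The preconditioner is
    the dense inverse of the same operator with K replaced by its Nyström
    approximation K̃ = K_nm K_mm⁺ K_mn from ``m`` uniformly sampled
    landmarks.
    """
    X_l = np.atleast_2d(np.asarray(X_l, float))
    X_u = np.atleast_2d(np.asarray(X_u, float)) if len(np.asarray(X_u)) else np.empty((0, X_l.shape[1]))
    y_l = np.asarray(y_l)
    classes = np.unique(y_l)
    X = np.vstack([X_l, X_u])
    l, n = len(X_l), len(X)
    if not (1 <= m <= n):
        raise ValueError("landmark count m must satisfy 1 <= m <= n")
    sigma = sigma_k if sigma_k is not None else median_heuristic(X)
    K = rbf_kernel(X, X, sigma)
    J = np.zeros(n)
    J[:l] = 1.0
    Y = np.zeros((n, len(classes)))
    Y[:l] = _targets(y_l, classes)

    c = gamma_i * l / n**2 if gamma_i > 0 else 0.0
    L = build_laplacian(X, spec) if c > 0 and n > spec.k else np.zeros((n, n))
    Mmat = np.diag(J) + c * L

    A = K @ Mmat @ K + gamma_a * l * K
    b = K @ (J[:, None] * Y)

    # Nyström approximation of K for the preconditioner
    rng = np.random.default_rng(seed)
    landmarks = np.sort(rng.choice(n, size=m, replace=False))
    Knm = K[:, landmarks]
    Kmm = K[np.ix_(landmarks, landmarks)]
    try:
        Kmm_inv = np.linalg.pinv(Kmm, rcond=1e-10)
    except np.linalg.LinAlgError:
        log.warning("K_mm singular; adding jitter")
        Kmm_inv = np.linalg.pinv(Kmm + 1e-8 * np.eye(m))
    Ktil = Knm @ Kmm_inv @ Knm.T
    P = Ktil @ Mmat @ Ktil + gamma_a * l * Ktil
    P_inv = np.linalg.inv(P + 1e-8 * np.eye(n))  # jitter for invertibility
    precond = LinearOperator((n, n), matvec=lambda v: P_inv @ v)

    alpha = np.empty((n, len(classes)))
    info_all = []
    for cidx in range(len(classes)):
        # solve a notch tighter than requested so the contract on the true
        # residual holds even when CG's internal criterion is optimistic
        sol, cg_info = cg(A, b[:, cidx], rtol=0.1 * pcg_tol, atol=0.0,
                          maxiter=max_pcg_iter, M=precond)
        resid = np.linalg.norm(A @ sol - b[:, cidx]) / max(
            np.linalg.norm(b[:, cidx]), 1e-300
        )
        if resid > pcg_tol:
            log.warning("PCG did not converge (info=%s, resid=%.2e)", cg_info, resid)
        info_all.append({"cg_info": int(cg_info), "residual": float(resid)})
        alpha[:, cidx] = sol
    return ManifoldModel(
        "nystrom", classes, X, alpha, sigma, gamma_a, gamma_i,
        info={"landmarks": landmarks.tolist(), "pcg": info_all},
    )


def decision_scores(model: ManifoldModel, X_new: np.ndarray) -> np.ndarray:
    """Kernel-expansion scores at new points (out-of-sample extension)."""
    X_new = np.atleast_2d(np.asarray(X_new, float))
    if X_new.shape[1] != model.X_train.shape[1]:
        raise ValueError(
            f"dimension mismatch: model expects {model.X_train.shape[1]}"
            f" features, input has {X_new.shape[1]}"
        )
    return rbf_kernel(X_new, model.X_train, model.sigma_k) @ model.alpha


def predict(model: ManifoldModel, X_new: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    """Labels (argmax of class scores) and the real-valued scores."""
    scores = decision_scores(model, X_new)
    return model.classes[np.argmax(scores, axis=1)], scores


# ---------------------------------------------------------------------------
# Evaluation
# ---------------------------------------------------------------------------

@dataclass
class EvaluationReport:
    """Confusion matrix and the derived accuracy/precision/recall/F1/RMSE."""

    classes: np.ndarray
    confusion: np.ndarray  # true × predicted
    accuracy: float
    macro_accuracy: float
    precision: np.ndarray
    recall: np.ndarray
    f1: np.ndarray
    rmse: float | None = None
    extra_predicted: list = field(default_factory=list)

    @property
    def macro_precision(self) -> float:
        return float(self.precision.mean())

    @property
    def macro_recall(self) -> float:
        return float(self.recall.mean())

    @property
    def macro_f1(self) -> float:
        return float(self.f1.mean())

    def to_dict(self) -> dict:
        return {
            "classes": [str(c) for c in self.classes],
            "confusion": self.confusion.tolist(),
            "accuracy": self.accuracy,
            "macro_accuracy": self.macro_accuracy,
            "precision": self.precision.tolist(),
            "recall": self.recall.tolist(),
            "f1": self.f1.tolist(),
            "macro_precision": self.macro_precision,
            "macro_recall": self.macro_recall,
            "macro_f1": self.macro_f1,
            "rmse": self.rmse,
        }


def evaluate(
    pred_labels: np.ndarray,
    true_labels: np.ndarray,
    scores: np.ndarray | None = None,
    score_classes: np.ndarray | None = None,
    partition: np.ndarray | None = None,
) -> EvaluationReport:
    """Confusion matrix, ACC = correct/total, per-class precision, recall
    and F1 = 2PR/(P+R) with macro means, and the RMSE of real-valued scores
    against ±1 one-vs-rest targets on an optional boolean ``partition``.

    Predicted labels never seen in the truth get their own confusion column
    and are reported in ``extra_predicted``.
    """
    pred = np.asarray(pred_labels)
    true = np.asarray(true_labels)
    if len(pred) != len(true):
        raise ValueError("prediction and truth lengths differ")
    classes = np.unique(true)
    extra = sorted(set(pred) - set(classes))
    if extra:
        log.warning("predictions contain unseen labels: %s", extra)
    all_cols = np.concatenate([classes, np.array(extra, dtype=classes.dtype)]) if extra else classes
    cmat = np.zeros((len(classes), len(all_cols)), dtype=int)
    col_of = {c: j for j, c in enumerate(all_cols)}
    row_of = {c: i for i, c in enumerate(classes)}
    for t, p in zip(true, pred):
        cmat[row_of[t], col_of[p]] += 1

    diag = np.array([cmat[i, i] for i in range(len(classes))])
    accuracy = float(diag.sum() / len(true))
    with np.errstate(invalid="ignore", divide="ignore"):
        col_sums = cmat.sum(axis=0)[: len(classes)]
        row_sums = cmat.sum(axis=1)
        precision = np.where(col_sums > 0, diag / col_sums, 0.0)
        recall = np.where(row_sums > 0, diag / row_sums, 0.0)
        pr = precision + recall
        f1 = np.where(pr > 0, 2 * precision * recall / pr, 0.0)
    macro_accuracy = float(recall.mean())  # mean of per-class diagonal rates

    rmse = None
    if scores is not None:
        scores = np.atleast_2d(np.asarray(scores, float))
        sc = classes if score_classes is None else np.asarray(score_classes)
        T = np.where(true[:, None] == sc[None, :], 1.0, -1.0)
        mask = np.ones(len(true), bool) if partition is None else np.asarray(partition, bool)
        rmse = float(np.sqrt(np.mean((scores[mask] - T[mask]) ** 2)))

    return EvaluationReport(
        classes, cmat, accuracy, macro_accuracy, precision, recall, f1, rmse,
        extra_predicted=[str(e) for e in extra],
    )
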