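"""Weighted sparse representation based classification (WSRC).

A query vector y is represented as a sparse linear combination of the
column-normalized training samples X (the "dictionary"):

    min ||W a||_1   subject to   ||y - X a||_2 <= eps

where W is diagonal with the Gaussian similarity between y and each training
sample (``weight_mode="literal"``) or its reciprocal (``"inverse"``, which
realises the locality rationale that nearby samples should be penalised
less).  The query is then assigned to the class whose coefficients alone
reconstruct it with the smallest Euclidean residual.

The constrained problem reduces, via the substitution b_i = w_i a_i, to
basis-pursuit denoising in the column-rescaled dictionary.  It is solved
exactly on the lasso homotopy path (the residual norm is piecewise smooth in
the regularisation weight, so the constraint boundary is located by
interpolating between path knots), with a coordinate-descent bisection
fallback for numerically difficult instances.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.linear_model import Lasso, lars_path
from sklearn.utils.validation import check_is_fitted

__all__ = [
    "WsrcConfig",
    "Dictionary",
    "SparseSolution",
    "gaussian_similarity",
    "weight_matrix",
    "solve_weighted_l1",
    "classify",
    "WSRClassifier",
]


@dataclass(frozen=True)
class WsrcConfig:
    """Tunables of the classifier.

    ``epsilon`` is the reconstruction tolerance of the sparse representation
    (meaningful on the unit-norm scale, hence ``normalize_query``); ``sigma``
    is the Gaussian kernel width used for the sample weights.
    """

    epsilon: float = 0.005
    sigma: float = 1.5
    weight_mode: str = "literal"
    solver_tol: float = 1e-6
    normalize_query: bool = True

    def __post_init__(self) -> None:
        if self.epsilon <= 0:
            raise ValueError("epsilon must be > 0")
        if self.sigma <= 0:
            raise ValueError("sigma must be > 0")
        if self.weight_mode not in ("literal", "inverse"):
            raise ValueError("weight_mode must be 'literal' or 'inverse'")


@dataclass
class Dictionary:
    """Column-stacked training pair-vectors with class labels.

    ``columns`` is d x n with unit-norm columns; ``column_norms`` keeps the
    original norms for bookkeeping.
    """

    columns: np.ndarray
    labels: np.ndarray
    column_norms: np.ndarray

    @classmethod
    def from_samples(cls, X: np.ndarray, y) -> "Dictionary":
        """Build from an (n_samples, d) row matrix of training vectors."""
        X = np.asarray(X, dtype=float)
        if X.ndim != 2:
            raise ValueError("X must be 2-D (n_samples, d)")
        labels = np.asarray(y)
        if labels.shape[0] != X.shape[0]:
            raise ValueError("labels length must match sample count")
        cols = X.T.copy()
        norms = np.linalg.norm(cols, axis=0)
        if np.any(norms == 0):
            raise ValueError("zero training vector cannot be normalized")
        return cls(columns=cols / norms, labels=labels, column_norms=norms)

    @property
    def n_samples(self) -> int:
        return self.columns.shape[1]


@dataclass
class SparseSolution:
    """Result of classifying one query: coefficients, weights, residuals.

    ``score = r_non - r_int`` (residual of the non-interacting class minus
    residual of the interacting class): larger means more likely interacting.
    """

    alpha: np.ndarray
    weights: np.ndarray
    residuals: dict
    label: object
    score: float


def gaussian_similarity(a: np.ndarray, b: np.ndarray, sigma: float) -> float:
    """``exp(-||a - b||^2 / (2 sigma^2))``, in (0, 1]."""
    a = np.asarray(a, dtype=float)
    b = np.asarray(b, dtype=float)
    if a.shape != b.shape:
        raise ValueError("vectors must have equal length")
    if sigma <= 0:
        raise ValueError("sigma must be > 0")
    d2 = float(np.sum((a - b) ** 2))
    return float(np.exp(-d2 / (2.0 * sigma * sigma)))


def weight_matrix(y: np.ndarray, dictionary: Dictionary, config: WsrcConfig) -> np.ndarray:
    """Diagonal of W: per-column Gaussian similarity to y (or its reciprocal)."""
    diff = dictionary.columns - np.asarray(y, dtype=float)[:, None]
    sim = np.exp(-np.sum(diff * diff, axis=0) / (2.0 * config.sigma**2))
    return sim if config.weight_mode == "literal" else 1.0 / sim


def _bpdn_lars(A: np.ndarray, y: np.ndarray, eps: float):
    """Basis-pursuit denoising via the lasso homotopy path.

    Returns beta with ||y - A beta|| <= eps and minimal ||beta||_1, or None
    if the path is numerically unusable.  Between two consecutive path knots
    the coefficients are affine in the regularisation weight, so the point
    where the residual norm crosses eps is found from a scalar quadratic.
    """
    try:
        _, _, coefs = lars_path(A, y, method="lasso", alpha_min=0.0)
    except Exception:
        return None
    resid = y[:, None] - A @ coefs
    norms = np.linalg.norm(resid, axis=0)
    hits = np.nonzero(norms <= eps)[0]
    if hits.size == 0:
        return None
    k = int(hits[0])
    if k == 0:
        return coefs[:, 0]
    b0, b1 = coefs[:, k - 1], coefs[:, k]
    r0 = y - A @ b0
    u = A @ (b1 - b0)
    aa = float(u @ u)
    bb = -2.0 * float(r0 @ u)
    cc = float(r0 @ r0) - eps * eps
    if aa <= 0:
        return b1
    disc = bb * bb - 4 * aa * cc
    if disc < 0:
        return b1
    sq = np.sqrt(disc)
    roots = [(-bb - sq) / (2 * aa), (-bb + sq) / (2 * aa)]
    ts = [t for t in roots if -1e-12 <= t <= 1 + 1e-12]
    if not ts:
        return b1
    t = min(ts)  # smallest feasible point on the segment has smallest l1 norm
    return b0 + t * (b1 - b0)


def _bpdn_bisect(A: np.ndarray, y: np.ndarray, eps: float, tol: float):
    """Fallback: bisection on the lasso penalty to hit ||y - A beta|| = eps."""
    import warnings as _warnings

    from sklearn.exceptions import ConvergenceWarning

    d = A.shape[0]
    lam_hi = float(np.max(np.abs(A.T @ y))) / d  # beta = 0 above this
    lam_lo = 1e-14
    lasso = Lasso(alpha=lam_hi, fit_intercept=False, tol=1e-12, max_iter=200_000,
                  warm_start=True)
    best = None
    for _ in range(80):
        lam = np.sqrt(lam_lo * lam_hi)
        lasso.set_params(alpha=lam)
        with _warnings.catch_warnings():
            _warnings.simplefilter("ignore", ConvergenceWarning)
            _warnings.simplefilter("ignore", UserWarning)
            lasso.fit(A, y)
        beta = lasso.coef_.copy()
        r = float(np.linalg.norm(y - A @ beta))
        if r <= eps:
            best = beta
            lam_lo = lam
        else:
            lam_hi = lam
        if abs(r - eps) <= tol * max(eps, 1e-12):
            break
    if best is None:
        # even the least-squares end of the path misses eps
        raise ValueError(
            f"infeasible: no coefficient vector reaches residual {eps:g}"
        )
    return best


def solve_weighted_l1(
    y: np.ndarray,
    dictionary: Dictionary,
    w: np.ndarray,
    epsilon: float,
    solver_tol: float = 1e-6,
) -> np.ndarray:
    """Minimize ``sum_i w_i |a_i|`` subject to ``||y - X a||_2 <= epsilon``."""
    y = np.asarray(y, dtype=float)
    w = np.asarray(w, dtype=float)
    X = dictionary.columns
    if np.any(w <= 0):
        raise ValueError("weights must be strictly positive")
    if float(np.linalg.norm(y)) <= epsilon:
        return np.zeros(X.shape[1])
    # cheap infeasibility check: the least-squares residual is the tightest
    # reconstruction any coefficient vector can reach
    beta_ls, *_ = np.linalg.lstsq(X, y, rcond=None)
    if np.linalg.norm(y - X @ beta_ls) > epsilon:
        raise ValueError(
            f"infeasible: no coefficient vector reaches residual {epsilon:g}"
        )
    A = X / w  # substitution beta = w * alpha
    beta = _bpdn_lars(A, y, epsilon)
    if beta is None or np.linalg.norm(y - A @ beta) > epsilon + 10 * solver_tol:
        beta = _bpdn_bisect(A, y, epsilon, solver_tol)
    if np.linalg.norm(y - A @ beta) > epsilon + 10 * solver_tol:
        raise ValueError(
            f"infeasible: no coefficient vector reaches residual {epsilon:g}"
        )
    return beta / w


def classify(y: np.ndarray, dictionary: Dictionary, config: WsrcConfig | None = None) -> SparseSolution:
    """Full WSRC decision for one query vector.

    Residual of class c keeps only the coefficients of class-c columns:
    ``r_c = ||y - X delta_c(a)||``.  The label is the argmin; exact ties go
    to the smaller (non-interacting) class label.  For binary labels {0, 1}
    the continuous score is ``r_0 - r_1``.
    """
    config = config or WsrcConfig()
    y = np.asarray(y, dtype=float)
    if config.normalize_query:
        ny = float(np.linalg.norm(y))
        if ny == 0:
            raise ValueError("zero query vector cannot be normalized")
        y = y / ny
    w = weight_matrix(y, dictionary, config)
    # when the query lies outside the eps-reachable span (e.g. fewer
    # dictionary columns than dimensions) the tolerance is relaxed to the
    # least-squares residual, the tightest feasible reconstruction
    beta_ls, *_ = np.linalg.lstsq(dictionary.columns, y, rcond=None)
    r_min = float(np.linalg.norm(y - dictionary.columns @ beta_ls))
    eps_eff = max(config.epsilon, r_min * (1 + 1e-6) + 1e-9)
    alpha = solve_weighted_l1(y, dictionary, w, eps_eff, config.solver_tol)
    classes = np.unique(dictionary.labels)
    residuals = {}
    for c in classes:
        part = np.where(dictionary.labels == c, alpha, 0.0)
        residuals[c] = float(np.linalg.norm(y - dictionary.columns @ part))
    # ties broken toward the smallest label (non-interacting = 0)
    label = min(classes, key=lambda c: (residuals[c], c))
    if len(classes) == 2:
        lo, hi = classes
        score = residuals[lo] - residuals[hi]
    else:
        score = -residuals[label]
    return SparseSolution(alpha=alpha, weights=w, residuals=residuals,
                          label=label, score=score)


class WSRClassifier(BaseEstimator, ClassifierMixin):
    """Scikit-learn interface to WSRC.

    A lazy (instance-based) classifier: ``fit`` stores the column-normalized
    training matrix as the representation dictionary; each ``predict`` solves
    one weighted basis-pursuit-denoise problem per query.

    Parameters mirror :class:`WsrcConfig`.  For binary problems
    ``decision_function`` returns the residual difference
    ``r(classes_[0]) - r(classes_[1])``, so a positive value votes for
    ``classes_[1]`` (the interacting class when labels are {0, 1}).
    """

    def __init__(self, epsilon: float = 0.005, sigma: float = 1.5,
                 weight_mode: str = "literal", solver_tol: float = 1e-6,
                 normalize_query: bool = True):
        self.epsilon = epsilon
        self.sigma = sigma
        self.weight_mode = weight_mode
        self.solver_tol = solver_tol
        self.normalize_query = normalize_query

    def _config(self) -> WsrcConfig:
        return WsrcConfig(
            epsilon=self.epsilon, sigma=self.sigma, weight_mode=self.weight_mode,
            solver_tol=self.solver_tol, normalize_query=self.normalize_query,
        )

    def fit(self, X, y):
        X = np.asarray(X, dtype=float)
        y = np.asarray(y)
        if X.ndim != 2 or X.shape[0] != y.shape[0]:
            raise ValueError("X must be (n_samples, d) with matching y")
        self.classes_ = np.unique(y)
        if self.classes_.size < 2:
            raise ValueError("need at least one sample of each of >= 2 classes")
        self._config()  # validate parameters
        self.dictionary_ = Dictionary.from_samples(X, y)
        self.n_features_in_ = X.shape[1]
        return self

    def _solutions(self, X):
        check_is_fitted(self, "dictionary_")
        X = np.atleast_2d(np.asarray(X, dtype=float))
        if X.shape[1] != self.n_features_in_:
            raise ValueError(
                f"query dimension {X.shape[1]} != training dimension {self.n_features_in_}"
            )
        cfg = self._config()
        return [classify(row, self.dictionary_, cfg) for row in X]

    def predict(self, X):
        return np.array([s.label for s in self._solutions(X)])

    def decision_function(self, X):
        if self.classes_.size != 2:
            raise ValueError("decision_function requires a binary problem")
        return np.array([s.score for s in self._solutions(X)])

    def save(self, path) -> None:
        """Serialize the dictionary and configuration to a JSON artifact."""
        check_is_fitted(self, "dictionary_")
        payload = {
            "params": self.get_params(),
            "columns": self.dictionary_.columns.tolist(),
            "labels": self.dictionary_.labels.tolist(),
            "column_norms": self.dictionary_.column_norms.tolist(),
        }
        Path(path).write_text(json.dumps(payload))

    @classmethod
    def load(cls, path) -> "WSRClassifier":
        d = json.loads(Path(path).read_text())
        clf = cls(**d["params"])
        clf.dictionary_ = Dictionary(
            columns=np.asarray(d["columns"], dtype=float),
            labels=np.asarray(d["labels"]),
            column_norms=np.asarray(d["column_norms"], dtype=float),
        )
        clf.classes_ = np.unique(clf.dictionary_.labels)
        clf.n_features_in_ = clf.dictionary_.columns.shape[0]
        return clf
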