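"""Sparse partial robust M-regression discriminant analysis (SPRM-DA).

A PLS-type binary classifier made robust by iteratively reweighted case
weights (an M-estimation scheme with a bounded weight function) and made
sparse by soft-thresholding each latent direction vector.  The case
weights double as the method's inherent outlyingness measure: a sample
that is persistently downweighted is an outlier candidate.

The algorithm:

1. encode the binary response as centred two-group codes,
2. robustly standardize features (column median / MAD),
3. start from case weights derived from robust residual and leverage
   distances,
4. alternate weighted sparse NIPALS PLS with recomputation of residual
   weights (from the regression residuals) and leverage weights (from
   distances in latent-score space) until the coefficient vector is
   stable,
5. report coefficients, latent scores, case weights and the selected
   (nonzero-coefficient) features.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .io_prep import ClassLabels, ExpressionMatrix

__all__ = [
    "SprmConfig",
    "SprmModel",
    "fit_sprm",
    "predict_sprm",
    "sprm_outlier_scores",
]

_MAD_FLOOR = 1e-8
_MAD_SCALE = 1.4826  # consistency factor for the normal distribution


def _weight(z: np.ndarray, kind: str, c: float) -> np.ndarray:
    """Bounded M-estimation weight of standardized distances ``z``."""
    z = np.abs(np.asarray(z, dtype=float))
    if kind == "fair":
        return 1.0 / (1.0 + z / c) ** 2
    if kind == "huber":
        with np.errstate(divide="ignore"):
            return np.minimum(1.0, c / np.where(z == 0, np.inf, z))
    if kind == "unit":
        return np.ones_like(z)
    raise ValueError(f"unknown weight function {kind!r}")


def _mad(x: np.ndarray, axis=None) -> np.ndarray:
    med = np.median(x, axis=axis, keepdims=True)
    return np.maximum(
        _MAD_SCALE * np.median(np.abs(x - med), axis=axis), _MAD_FLOOR
    )


@dataclass(frozen=True)
class SprmConfig:
    """Hyperparameters of the SPRM-DA fit.

    eta in [0, 1) controls sparsity (0 = dense PLS directions); the Fair
    weight function with tuning constant 4 is the conventional default.
    """

    n_components: int = 2
    eta: float = 0.5
    weight_function: str = "fair"  # fair | huber | unit
    tuning_constant: float = 4.0
    max_iter: int = 150
    tol: float = 1e-4

    def __post_init__(self) -> None:
        if not (0 <= self.eta < 1):
            raise ValueError("eta must lie in [0, 1)")
        if self.tol <= 0 or self.max_iter <= 0 or self.n_components <= 0:
            raise ValueError("n_components, max_iter and tol must be positive")
        if self.tuning_constant <= 0:
            raise ValueError("tuning_constant must be positive")


@dataclass
class SprmModel:
    coefficients: np.ndarray  # on median/MAD-standardized features
    intercept: float
    scores: np.ndarray  # n x n_components latent scores
    case_weights: np.ndarray
    selected_features: set
    config_used: SprmConfig
    converged: bool
    # internals needed for prediction
    feature_ids: np.ndarray
    center_: np.ndarray
    scale_: np.ndarray
    rotation_: np.ndarray  # p x a, maps standardized X to scores
    score_center_: np.ndarray
    class_centroids_: np.ndarray  # 2 x a, rows = class 0, class 1


def _encode_response(y: np.ndarray) -> np.ndarray:
    """Centred two-group codes: class 1 -> n0/n, class 0 -> -n1/n."""
    n = len(y)
    n1 = int(y.sum())
    n0 = n - n1
    return np.where(y == 1, n0 / n, -n1 / n).astype(float)


def _sparse_weighted_pls(Zs, vs, n_components, eta):
    """Sparse NIPALS PLS1 on row-weighted, centred data.

    Each direction vector is soft-thresholded at eta * max|w| and
    normalized.  Returns (W, P, Q) with W, P of shape (p, a).
    """
    n, p = Zs.shape
    Xd = Zs.copy()
    yd = vs.copy()
    W = np.zeros((p, n_components))
    P = np.zeros((p, n_components))
    Q = np.zeros(n_components)
    for a in range(n_components):
        w = Xd.T @ yd
        wmax = np.abs(w).max()
        if wmax < 1e-12:
            raise np.linalg.LinAlgError(
                f"rank of weighted data is below {n_components} components"
            )
        thr = eta * wmax
        w = np.sign(w) * np.maximum(np.abs(w) - thr, 0.0)
        w /= np.linalg.norm(w)
        t = Xd @ w
        tt = t @ t
        if tt < 1e-12:
            raise np.linalg.LinAlgError(
                f"degenerate component {a + 1}: weighted data rank too low"
            )
        p_load = Xd.T @ t / tt
        q = yd @ t / tt
        Xd -= np.outer(t, p_load)
        yd -= q * t
        W[:, a], P[:, a], Q[a] = w, p_load, q
    return W, P, Q


def fit_sprm(
    X: ExpressionMatrix, y: ClassLabels, cfg: SprmConfig | None = None
) -> SprmModel:
    """Fit SPRM-DA by iteratively reweighted sparse PLS."""
    cfg = cfg or SprmConfig()
    if not y.both_classes_present:
        raise ValueError("both classes must be present for a supervised fit")
    n, p = X.values.shape
    if n < 2 * cfg.n_components:
        raise ValueError("need n >= 2 * n_components samples")
    if cfg.n_components > min(n - 1, p):
        raise ValueError(
            f"n_components={cfg.n_components} exceeds the data rank bound "
            f"min(n-1, p)={min(n - 1, p)}"
        )

    v = _encode_response(y.y)
    center = np.median(X.values, axis=0)
    scale = _mad(X.values, axis=0)
    Z = (X.values - center) / scale

    # initial case weights from robust leverage distances only: the encoded
    # two-valued response has a degenerate median/MAD, so residual-based
    # initialization is meaningless in the discriminant setting
    kind, c = cfg.weight_function, cfg.tuning_constant
    d_x = np.linalg.norm(Z - np.median(Z, axis=0), axis=1)
    d_x = d_x / max(np.median(d_x), _MAD_FLOOR)
    w = np.maximum(_weight(d_x, kind, c), 1e-6)
    sigma_floor = 1e-3 * max(v.max() - v.min(), 1e-8)

    b_prev = None
    converged = False
    for _ in range(cfg.max_iter):
        sw = w / w.sum()
        mu = sw @ Z
        vbar = sw @ v
        Zc = Z - mu
        vc = v - vbar
        sq = np.sqrt(w)
        W, P, Q = _sparse_weighted_pls(
            sq[:, None] * Zc, sq * vc, cfg.n_components, cfg.eta
        )
        R = W @ np.linalg.inv(P.T @ W)  # p x a rotation
        b = R @ Q
        T = Zc @ R

        resid = vc - Zc @ b
        sigma = max(_mad(resid), sigma_floor)  # guard against collapse
        w_r = _weight(resid / sigma, kind, c)
        d = np.linalg.norm((T - np.median(T, axis=0)) / _mad(T, axis=0), axis=1)
        d = d / max(np.median(d), _MAD_FLOOR)
        w_x = _weight(d, kind, c)
        # damped update: a plain update can lock into a support/weight
        # limit cycle with soft-thresholded directions
        w_new = 0.5 * w + 0.5 * np.maximum(w_r * w_x, 1e-6)

        if b_prev is not None:
            denom = max(np.linalg.norm(b_prev), 1e-12)
            if np.linalg.norm(b - b_prev) / denom < cfg.tol:
                converged = True
                w = w_new
                break
        b_prev = b
        w = w_new
    if not converged:
        warnings.warn(
            "SPRM did not converge within max_iter; returning last iterate",
            RuntimeWarning,
        )

    intercept = float(vbar - mu @ b)
    selected = set(X.feature_ids[np.flatnonzero(b != 0)])
    centroids = np.zeros((2, cfg.n_components))
    for cls in (0, 1):
        m = y.y == cls
        cw = w[m] / w[m].sum()
        centroids[cls] = cw @ T[m]
    return SprmModel(
        coefficients=b,
        intercept=intercept,
        scores=T,
        case_weights=w,
        selected_features=selected,
        config_used=cfg,
        converged=converged,
        feature_ids=X.feature_ids,
        center_=center,
        scale_=scale,
        rotation_=R,
        score_center_=mu @ R,
        class_centroids_=centroids,
    )


def _project(model: SprmModel, X: ExpressionMatrix) -> np.ndarray:
    if list(X.feature_ids) != list(model.feature_ids):
        raise ValueError("feature ids do not match the training features")
    Z = (X.values - model.center_) / model.scale_
    return Z @ model.rotation_ - model.score_center_


def predict_sprm(model: SprmModel, X: ExpressionMatrix) -> np.ndarray:
    """Assign each sample to the nearest weighted class centroid in score
    space; exact ties go to class 0."""
    T = _project(model, X)
    d0 = np.linalg.norm(T - model.class_centroids_[0], axis=1)
    d1 = np.linalg.norm(T - model.class_centroids_[1], axis=1)
    return (d1 < d0).astype(int)


def sprm_outlier_scores(model: SprmModel) -> np.ndarray:
    """Outlyingness = 1 - case weight (larger = more outlying)."""
    return 1.0 - model.case_weights
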