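"""Robust sparse logistic regression by least trimmed squares (enetLTS).

Elastic-net-penalized logistic regression fitted on the best h-subset of
cases: many small elemental starts are concentrated by C-steps (refit on
the h cases with smallest deviance, repeat) until the subset is stable,
after which an optional reweighting step refits on all cases whose
standardized Pearson residual is below a normal quantile.  Label-flipped
or otherwise ill-fitting samples end up outside the h-subset and carry
large residuals, which is the method's outlyingness measure.

The penalized fits themselves are ordinary convex solves and are
delegated to scikit-learn's SAGA elastic-net logistic solver.
"""

from __future__ import annotations

import math
import warnings
from dataclasses import dataclass

import numpy as np
from scipy.stats import norm
from sklearn.linear_model import LogisticRegression

from .io_prep import ClassLabels, ExpressionMatrix

__all__ = [
    "EnetltsConfig",
    "EnetltsModel",
    "fit_enetlts",
    "predict_enetlts",
    "enetlts_outlier_scores",
    "select_enetlts_hyperparameters",
]

_MAD_FLOOR = 1e-8


@dataclass(frozen=True)
class EnetltsConfig:
    """Hyperparameters of the trimmed elastic-net logistic fit.

    h_fraction is the subset fraction (0.75 keeps the best 75% of cases);
    lam is the elastic-net penalty level on the glmnet scale
    ((1/h) sum nll + lam * P_alpha); when None it defaults to
    ``lambda_frac`` times the smallest penalty that zeroes every
    coefficient.  The reweighting cutoff 0.9875 is the conventional
    normal quantile for flagging residual outliers.
    """

    h_fraction: float = 0.75
    alpha_mix: float = 0.5
    lam: float | None = None
    lambda_frac: float = 0.1
    n_starts: int = 20
    n_csteps_keep: int = 5
    max_csteps: int = 20
    reweight_quantile: float = 0.9875
    seed: int = 0
    solver_tol: float = 1e-4
    solver_max_iter: int = 300

    def __post_init__(self) -> None:
        if not (0.5 < self.h_fraction <= 1.0):
            raise ValueError("h_fraction must lie in (0.5, 1]")
        if not (0 < self.alpha_mix <= 1.0):
            raise ValueError("alpha_mix must lie in (0, 1]")
        if not (0.5 < self.reweight_quantile < 1.0):
            raise ValueError("reweight_quantile must lie in (0.5, 1)")


@dataclass
class EnetltsModel:
    coefficients: np.ndarray  # on robustly standardized features
    intercept: float
    h_subset: np.ndarray
    std_residuals: np.ndarray  # standardized Pearson residuals, all cases
    selected_features: set
    lambda_used: float
    alpha_used: float
    reweighted: bool
    objective_trace: list
    config_used: EnetltsConfig
    feature_ids: np.ndarray
    center_: np.ndarray
    scale_: np.ndarray


def _standardize(X: ExpressionMatrix):
    center = np.median(X.values, axis=0)
    mad = 1.4826 * np.median(np.abs(X.values - center), axis=0)
    scale = np.maximum(mad, _MAD_FLOOR)
    return (X.values - center) / scale, center, scale


def _penalized_logistic(Z, y, lam, alpha_mix, h, cfg):
    """Elastic-net logistic fit; lam on the (1/h)*nll + lam*P scale."""
    if lam <= 1e-7:
        est = LogisticRegression(
            penalty=None, solver="lbfgs", max_iter=2000, tol=1e-8
        )
    else:
        est = LogisticRegression(
            penalty="elasticnet",
            solver="saga",
            l1_ratio=alpha_mix,
            C=1.0 / (h * lam),
            max_iter=cfg.solver_max_iter,
            tol=cfg.solver_tol,
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        est.fit(Z, y)
    return est.coef_.ravel(), float(est.intercept_[0])


def _nll(Z, y, beta, b0):
    eta = Z @ beta + b0
    # stable -log-likelihood per case
    return np.logaddexp(0.0, eta) - y * eta


def _objective(Z, y, beta, b0, H, lam, alpha_mix, h):
    pen = alpha_mix * np.abs(beta).sum() + (1 - alpha_mix) / 2 * (beta @ beta)
    return float(_nll(Z[H], y[H], beta, b0).mean() + lam * pen)


def _best_h_subset(nll, y, h):
    """The h cases of smallest deviance, stratified to keep both classes."""
    n = len(y)
    n1 = int(y.sum())
    h1 = min(max(int(round(h * n1 / n)), 1), h - 1, n1)
    h0 = h - h1
    idx1 = np.flatnonzero(y == 1)
    idx0 = np.flatnonzero(y == 0)
    top1 = idx1[np.argsort(nll[idx1], kind="stable")[:h1]]
    top0 = idx0[np.argsort(nll[idx0], kind="stable")[:h0]]
    return np.sort(np.concatenate([top1, top0]))


def _default_lambda(Z, y, alpha_mix, frac):
    lam_max = np.abs(Z.T @ (y - y.mean())).max() / (len(y) * max(alpha_mix, 1e-3))
    return frac * lam_max


def fit_enetlts(
    X: ExpressionMatrix, y: ClassLabels, cfg: EnetltsConfig | None = None
) -> EnetltsModel:
    """Fit the trimmed elastic-net logistic regression."""
    cfg = cfg or EnetltsConfig()
    if not y.both_classes_present:
        raise ValueError("both classes must be present")
    Z, center, scale = _standardize(X)
    yv = y.y
    n, p = Z.shape
    h = math.ceil(cfg.h_fraction * n)
    lam = cfg.lam if cfg.lam is not None else _default_lambda(
        Z, yv, cfg.alpha_mix, cfg.lambda_frac
    )
    rng = np.random.default_rng(cfg.seed)

    def cstep(H):
        beta, b0 = _penalized_logistic(Z[H], yv[H], lam, cfg.alpha_mix, h, cfg)
        nll = _nll(Z, yv, beta, b0)
        return beta, b0, _best_h_subset(nll, yv, h)

    trace: list = []
    if h >= n:
        H = np.arange(n)
        beta, b0 = _penalized_logistic(Z, yv, lam, cfg.alpha_mix, h, cfg)
        trace.append(_objective(Z, yv, beta, b0, H, lam, cfg.alpha_mix, h))
    else:
        idx1 = np.flatnonzero(yv == 1)
        idx0 = np.flatnonzero(yv == 0)
        cands = []
        for _ in range(cfg.n_starts):
            elem = np.concatenate(
                [
                    rng.choice(idx1, size=min(3, len(idx1)), replace=False),
                    rng.choice(idx0, size=min(3, len(idx0)), replace=False),
                ]
            )
            beta, b0 = _penalized_logistic(
                Z[elem], yv[elem], lam, cfg.alpha_mix, h, cfg
            )
            H = _best_h_subset(_nll(Z, yv, beta, b0), yv, h)
            for _ in range(2):  # two concentration steps per start
                beta, b0, H = cstep(H)
            cands.append(
                (_objective(Z, yv, beta, b0, H, lam, cfg.alpha_mix, h), beta, b0, H)
            )
        cands.sort(key=lambda t: t[0])
        best = None
        for obj, beta, b0, H in cands[: cfg.n_csteps_keep]:
            local = [obj]
            for _ in range(cfg.max_csteps):
                beta, b0, H_new = cstep(H)
                obj_new = _objective(
                    Z, yv, beta, b0, H_new, lam, cfg.alpha_mix, h
                )
                local.append(obj_new)
                if np.array_equal(H_new, H):
                    H = H_new
                    break
                H = H_new
                obj = obj_new
            if best is None or local[-1] < best[0]:
                best = (local[-1], beta, b0, H, local)
        _, beta, b0, H, trace = best

    # reweighting step: refit on cases with moderate standardized residuals
    prob = 1.0 / (1.0 + np.exp(-(Z @ beta + b0)))
    prob = np.clip(prob, 1e-10, 1 - 1e-10)
    pearson = (yv - prob) / np.sqrt(prob * (1 - prob))
    cutoff = norm.ppf(cfg.reweight_quantile)
    keep = np.abs(pearson) <= cutoff
    reweighted = False
    if keep.sum() >= h and len(np.unique(yv[keep])) == 2 and h < n:
        beta, b0 = _penalized_logistic(
            Z[keep], yv[keep], lam, cfg.alpha_mix, int(keep.sum()), cfg
        )
        prob = 1.0 / (1.0 + np.exp(-(Z @ beta + b0)))
        prob = np.clip(prob, 1e-10, 1 - 1e-10)
        pearson = (yv - prob) / np.sqrt(prob * (1 - prob))
        reweighted = True

    return EnetltsModel(
        coefficients=beta,
        intercept=b0,
        h_subset=np.sort(H),
        std_residuals=pearson,
        selected_features=set(X.feature_ids[np.flatnonzero(beta != 0)]),
        lambda_used=lam,
        alpha_used=cfg.alpha_mix,
        reweighted=reweighted,
        objective_trace=list(trace),
        config_used=cfg,
        feature_ids=X.feature_ids,
        center_=center,
        scale_=scale,
    )


def predict_enetlts(model: EnetltsModel, X: ExpressionMatrix) -> np.ndarray:
    """Label 1 iff the fitted probability is at least 0.5."""
    if list(X.feature_ids) != list(model.feature_ids):
        raise ValueError("feature ids do not match the fitted model")
    Z = (X.values - model.center_) / model.scale_
    eta = Z @ model.coefficients + model.intercept
    return (eta >= 0).astype(int)


def enetlts_outlier_scores(model: EnetltsModel) -> np.ndarray:
    """Outlyingness = |standardized Pearson residual| under the final fit."""
    return np.abs(model.std_residuals)


def select_enetlts_hyperparameters(
    X: ExpressionMatrix,
    y: ClassLabels,
    alpha_grid=(0.5,),
    lambda_frac_grid=(0.05, 0.1, 0.2),
    cfg: EnetltsConfig | None = None,
    n_folds: int = 5,
):
    """Choose (alpha_mix, lambda) by stratified cross-validated deviance
    on the final consistent h-subset of a quick trimmed fit."""
    from sklearn.model_selection import StratifiedKFold

    cfg = cfg or EnetltsConfig()
    best = None
    for am in alpha_grid:
        for frac in lambda_frac_grid:
            quick = EnetltsConfig(
                h_fraction=cfg.h_fraction, alpha_mix=am, lambda_frac=frac,
                n_starts=max(5, cfg.n_starts // 4), n_csteps_keep=2,
                max_csteps=cfg.max_csteps, seed=cfg.seed,
                solver_tol=cfg.solver_tol, solver_max_iter=cfg.solver_max_iter,
            )
            model = fit_enetlts(X, y, quick)
            H = model.h_subset
            Z = (X.values - model.center_) / model.scale_
            ZH, yH = Z[H], y.y[H]
            skf = StratifiedKFold(
                n_splits=n_folds, shuffle=True, random_state=cfg.seed
            )
            devs = []
            for tr, te in skf.split(ZH, yH):
                if len(np.unique(yH[tr])) < 2:
                    continue
                beta, b0 = _penalized_logistic(
                    ZH[tr], yH[tr], model.lambda_used, am, len(tr), quick
                )
                devs.append(_nll(ZH[te], yH[te], beta, b0).mean())
            score = float(np.mean(devs))
            key = (score, -model.lambda_used)  # ties -> sparser (larger lam)
            if best is None or key < best[0]:
                best = (key, {"alpha_mix": am, "lam": model.lambda_used,
                              "lambda_frac": frac})
    return best[1]
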