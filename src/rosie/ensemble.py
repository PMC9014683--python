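"""Orchestration of the full ensemble run.

Three inherently different robust sparse classifiers -- SPRM-DA
(supervised, PLS-type M-estimation), RSKC (unsupervised trimmed sparse
K-means) and enetLTS (trimmed elastic-net logistic regression) -- are
fitted independently to the same data.  Each contributes an
outlyingness ranking of the samples and a selected feature set.  The
rankings are fused by the rank-product consensus test; the features by
three-way intersection.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace

import numpy as np
from sklearn.model_selection import StratifiedKFold

from . import enetlts as _enet
from . import rskc as _rskc
from . import sprm as _sprm
from .enetlts import EnetltsConfig
from .io_prep import ClassLabels, ExpressionMatrix
from .rankprod import ConsensusResult, consensus_from_scores
from .rskc import RskcConfig
from .sprm import SprmConfig

logger = logging.getLogger("rosie")

__all__ = [
    "RosieConfig",
    "MethodResult",
    "RosieResult",
    "optimize_hyperparameters",
    "run_rosie",
]

METHODS = ("sprm", "rskc", "enetlts")


@dataclass(frozen=True)
class RosieConfig:
    """Configuration of a full ensemble run.

    With ``optimize=True`` each method's hyperparameters are tuned on
    the data (cross-validation for the supervised methods, permutation
    gap statistic for RSKC) before the final fits; otherwise the
    per-method configs are used as given.
    """

    sprm: SprmConfig = field(default_factory=SprmConfig)
    rskc: RskcConfig = field(default_factory=RskcConfig)
    enetlts: EnetltsConfig = field(default_factory=EnetltsConfig)
    q_threshold: float = 0.05
    optimize: bool = True
    sprm_components_grid: tuple = (1, 2)
    sprm_eta_grid: tuple = (0.0, 0.5, 0.9)
    enet_alpha_grid: tuple = (0.5,)
    enet_lambda_frac_grid: tuple = (0.05, 0.1, 0.2)
    rskc_l1_grid: tuple | None = None  # default derived from sqrt(p)
    rskc_alpha_grid: tuple = (0.05, 0.1, 0.15)
    rskc_gap_permutations: int = 25


@dataclass
class MethodResult:
    method_id: str
    selected_features: set
    outlier_scores: np.ndarray
    predicted_labels: np.ndarray
    misclassified: set
    hyperparameters_chosen: dict
    model: object = None


@dataclass
class RosieResult:
    per_method: dict  # method_id -> MethodResult
    consensus: ConsensusResult
    common_features: set
    commonly_misclassified: set
    sample_ids: np.ndarray
    config_used: RosieConfig = None


def _cv_misclassification_sprm(X, y, cfg, n_folds=5, seed=0):
    skf = StratifiedKFold(n_splits=n_folds, shuffle=True, random_state=seed)
    errs = 0
    for tr, te in skf.split(X.values, y.y):
        Xtr = X.subset_samples(tr)
        Xte = X.subset_samples(te)
        try:
            model = _sprm.fit_sprm(Xtr, y.subset(tr), cfg)
        except (np.linalg.LinAlgError, ValueError):
            return np.inf
        errs += int((_sprm.predict_sprm(model, Xte) != y.y[te]).sum())
    return errs


def optimize_hyperparameters(
    X: ExpressionMatrix,
    y: ClassLabels,
    method_id: str,
    config: RosieConfig | None = None,
    seed: int = 0,
    reference_labels: np.ndarray | None = None,
) -> dict:
    """Tune one method's hyperparameters on the data, deterministically.

    SPRM: grid over (n_components, eta) minimizing stratified 5-fold CV
    misclassification, ties resolved toward the sparser model.  enetLTS:
    its internal cross-validated trimmed deviance.  RSKC: L1 bound by
    the permutation gap statistic; trimming level alpha by agreement of
    the mapped cluster labels with ``reference_labels`` (the observed
    labels by default, or another method's predictions).
    """
    config = config or RosieConfig()
    if method_id == "sprm":
        best = None
        for a in config.sprm_components_grid:
            for eta in config.sprm_eta_grid:
                cfg = replace(config.sprm, n_components=a, eta=eta)
                err = _cv_misclassification_sprm(X, y, cfg, seed=seed)
                key = (err, -eta, a)  # ties -> sparser: larger eta, fewer comps
                if best is None or key < best[0]:
                    best = (key, {"n_components": a, "eta": eta})
        if not np.isfinite(best[0][0]):
            raise RuntimeError("all SPRM grid points produced degenerate fits")
        return best[1]
    if method_id == "enetlts":
        base = replace(config.enetlts, seed=seed)
        return _enet.select_enetlts_hyperparameters(
            X, y, alpha_grid=config.enet_alpha_grid,
            lambda_frac_grid=config.enet_lambda_frac_grid, cfg=base,
        )
    if method_id == "rskc":
        p = X.n_features
        grid = config.rskc_l1_grid or tuple(
            sorted({max(1.1, f * np.sqrt(p)) for f in (0.2, 0.5, 0.9)})
        )
        s = _rskc.tune_l1_bound(
            X, grid, cfg=replace(config.rskc, seed=seed),
            n_permutations=config.rskc_gap_permutations, seed=seed,
        )
        ref = y.y if reference_labels is None else np.asarray(reference_labels)
        best = None
        for alpha in config.rskc_alpha_grid:
            cfg = replace(config.rskc, alpha=alpha, l1_bound=s, seed=seed)
            try:
                model = _rskc.fit_rskc(X, cfg)
            except RuntimeError:
                continue
            mapped = _rskc.map_clusters_to_labels(
                model.assignments, ClassLabels(ref)
            )
            agree = int((mapped == ref).sum())
            if best is None or agree > best[0]:
                best = (agree, {"alpha": alpha, "l1_bound": s})
        if best is None:
            raise RuntimeError("all RSKC grid points produced degenerate fits")
        return best[1]
    raise ValueError(f"unknown method {method_id!r}")


def _fit_method(method_id, X, y, config, seed):
    if method_id == "sprm":
        model = _sprm.fit_sprm(X, y, config.sprm)
        pred = _sprm.predict_sprm(model, X)
        scores = _sprm.sprm_outlier_scores(model)
        hp = {"n_components": config.sprm.n_components, "eta": config.sprm.eta}
    elif method_id == "rskc":
        model = _rskc.fit_rskc(X, replace(config.rskc, seed=seed))
        pred = _rskc.map_clusters_to_labels(model.assignments, y)
        scores = _rskc.rskc_outlier_scores(model, X)
        hp = {
            "alpha": config.rskc.alpha,
            "l1_bound": config.rskc.l1_bound,
        }
    elif method_id == "enetlts":
        model = _enet.fit_enetlts(X, y, replace(config.enetlts, seed=seed))
        pred = _enet.predict_enetlts(model, X)
        scores = _enet.enetlts_outlier_scores(model)
        hp = {
            "h_fraction": config.enetlts.h_fraction,
            "alpha_mix": model.alpha_used,
            "lambda": model.lambda_used,
        }
    else:
        raise ValueError(f"unknown method {method_id!r}")
    mis = set(np.asarray(X.sample_ids)[pred != y.y])
    return MethodResult(
        method_id=method_id,
        selected_features=model.selected_features,
        outlier_scores=np.asarray(scores, dtype=float),
        predicted_labels=pred,
        misclassified=mis,
        hyperparameters_chosen=hp,
        model=model,
    )


def run_rosie(
    X: ExpressionMatrix,
    y: ClassLabels,
    config: RosieConfig | None = None,
    seed: int = 0,
) -> RosieResult:
    """Run the full ensemble: three fits, consensus, feature intersection.

    Any method failure aborts the run with an error naming the method --
    the consensus is defined for exactly three rankings, so there is no
    silent two-method fallback.
    """
    config = config or RosieConfig()
    if not y.both_classes_present:
        raise ValueError("both classes must be present")

    if config.optimize:
        sprm_hp = optimize_hyperparameters(X, y, "sprm", config, seed)
        config = replace(config, sprm=replace(config.sprm, **sprm_hp))
        enet_hp = optimize_hyperparameters(X, y, "enetlts", config, seed)
        config = replace(
            config,
            enetlts=replace(
                config.enetlts,
                alpha_mix=enet_hp["alpha_mix"],
                lam=enet_hp["lam"],
            ),
        )
        rskc_hp = optimize_hyperparameters(X, y, "rskc", config, seed)
        config = replace(config, rskc=replace(config.rskc, **rskc_hp))

    per_method = {}
    for mid in METHODS:
        try:
            per_method[mid] = _fit_method(mid, X, y, config, seed)
        except Exception as exc:  # noqa: BLE001 - re-raise with method name
            raise RuntimeError(f"method {mid!r} failed to fit: {exc}") from exc
        if not per_method[mid].selected_features:
            raise RuntimeError(f"method {mid!r} selected no features")

    consensus = consensus_from_scores(
        [per_method[mid].outlier_scores for mid in METHODS],
        X.sample_ids,
        q_threshold=config.q_threshold,
    )
    common = set.intersection(*(per_method[m].selected_features for m in METHODS))
    consensus.intersected_features = common
    commonly_mis = set.intersection(
        *(per_method[m].misclassified for m in METHODS)
    )
    logger.info(
        "ensemble run: %d influential samples, %d common features",
        len(consensus.influential), len(common),
    )
    return RosieResult(
        per_method=per_method,
        consensus=consensus,
        common_features=common,
        commonly_misclassified=commonly_mis,
        sample_ids=X.sample_ids,
        config_used=config,
    )
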