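"""Robust sparse K-means clustering (RSKC).

Trimmed K-means with lasso-type nonnegative feature weights: the
unsupervised member of the ensemble.  Cases are trimmed twice per
iteration -- once in the weighted-feature space (O_W) and once in the
unweighted space (O_E) -- so that both spurious cluster members and
gross coordinate outliers lose their influence on the centers and on
the feature-weight update.  Feature weights maximize the weighted
between-cluster sum of squares subject to an L2 ball and an L1 bound,
which zeroes uninformative features (the sparse K-means construction).
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

from .io_prep import ClassLabels, ExpressionMatrix

__all__ = [
    "RskcConfig",
    "RskcModel",
    "fit_rskc",
    "rskc_outlier_scores",
    "map_clusters_to_labels",
    "tune_l1_bound",
]


@dataclass(frozen=True)
class RskcConfig:
    """Hyperparameters: K clusters, trimming proportion alpha, L1 bound s
    on the feature weights (1 <= s <= sqrt(p)), random restarts."""

    K: int = 2
    alpha: float = 0.1
    l1_bound: float | None = None  # default sqrt(p)/2, resolved at fit time
    n_init: int = 5
    max_iter: int = 50
    seed: int = 0
    update_feature_weights: bool = True  # False freezes uniform weights

    def __post_init__(self) -> None:
        if not (0 <= self.alpha < 0.5):
            raise ValueError("alpha must lie in [0, 0.5)")
        if self.K < 2:
            raise ValueError("K must be at least 2")
        if self.n_init <= 0 or self.max_iter <= 0:
            raise ValueError("n_init and max_iter must be positive")


@dataclass
class RskcModel:
    centers: np.ndarray  # K x p
    feature_weights: np.ndarray  # p, nonnegative, ||w||2<=1, ||w||1<=s
    assignments: np.ndarray  # n, values in 1..K
    trimmed_weighted: np.ndarray  # O_W index set
    trimmed_unweighted: np.ndarray  # O_E index set
    selected_features: set
    objective: float  # weighted between-cluster sum of squares
    objective_trace: list
    config_used: RskcConfig
    feature_ids: np.ndarray


def _soft(b: np.ndarray, delta: float) -> np.ndarray:
    return np.maximum(b - delta, 0.0)


def _weights_from_bss(b: np.ndarray, s: float) -> np.ndarray:
    """argmax w.b  s.t. ||w||2 <= 1, ||w||1 <= s, w >= 0.

    Closed form: w = soft(b, delta)/||soft(b, delta)||2 with delta = 0 if
    that already satisfies the L1 bound, else found by bisection.
    """
    b = np.maximum(b, 0.0)
    if not b.any():
        # no between-cluster signal anywhere: fall back to uniform
        p = len(b)
        return np.full(p, 1.0 / math.sqrt(p))

    def w_of(delta):
        v = _soft(b, delta)
        nrm = np.linalg.norm(v)
        return v / nrm if nrm > 0 else v

    w = w_of(0.0)
    if w.sum() <= s + 1e-12:
        return w
    lo, hi = 0.0, b.max()
    for _ in range(100):
        mid = (lo + hi) / 2
        if w_of(mid).sum() > s:
            lo = mid
        else:
            hi = mid
    w = w_of(hi)
    if not w.any() or w.sum() > s + 1e-9:
        # exactly tied b values make ||w||1 jump across s on the unit
        # L2 sphere; back off to the L1 boundary inside the L2 ball
        v = _soft(b, lo)
        if v.any():
            w = v / np.linalg.norm(v)
            if w.sum() > s:
                w = w * (s / w.sum())
    return w


def _assign(Xw: np.ndarray, centers_w: np.ndarray):
    """Squared distances in (already weighted) feature space and argmin."""
    d2 = ((Xw[:, None, :] - centers_w[None, :, :]) ** 2).sum(axis=2)
    lab = d2.argmin(axis=1)
    return lab, d2[np.arange(len(lab)), lab]


def _per_feature_bss(X, labels, keep_mask):
    """Between-cluster sum of squares per feature over the kept cases."""
    Xk = X[keep_mask]
    lk = labels[keep_mask]
    grand = Xk.mean(axis=0)
    tss = ((Xk - grand) ** 2).sum(axis=0)
    wss = np.zeros(X.shape[1])
    for k in np.unique(lk):
        sub = Xk[lk == k]
        wss += ((sub - sub.mean(axis=0)) ** 2).sum(axis=0)
    return np.maximum(tss - wss, 0.0)


def _fit_once(X, cfg, s, init_idx=None, initial_centers=None, rng=None):
    n, p = X.shape
    K = cfg.K
    q = math.ceil(cfg.alpha * n)
    w = np.full(p, 1.0 / math.sqrt(p))
    if initial_centers is not None:
        centers = np.asarray(initial_centers, dtype=float).copy()
    else:
        centers = X[init_idx].copy()

    obj_trace = []
    prev_obj = -np.inf
    labels = np.zeros(n, dtype=int)
    O_W = np.array([], dtype=int)
    O_E = np.array([], dtype=int)
    for _ in range(cfg.max_iter):
        # (a) trimmed Lloyd in weighted feature space
        sw = np.sqrt(w)
        for _ in range(cfg.max_iter):
            labels, d2 = _assign(X * sw, centers * sw)
            O_W = (
                np.argsort(-d2, kind="stable")[:q] if q else np.array([], dtype=int)
            )
            keep = np.ones(n, dtype=bool)
            keep[O_W] = False
            new_centers = centers.copy()
            for k in range(K):
                m = keep & (labels == k)
                if not m.any():
                    raise _EmptyCluster()
                new_centers[k] = X[m].mean(axis=0)
            if np.allclose(new_centers, centers, atol=1e-12):
                centers = new_centers
                break
            centers = new_centers
        # (b) re-trim in unweighted space, update centers on untrimmed cases
        _, d2u = _assign(X, centers)
        O_E = np.argsort(-d2u, kind="stable")[:q] if q else np.array([], dtype=int)
        keep = np.ones(n, dtype=bool)
        keep[O_E] = False
        for k in range(K):
            m = keep & (labels == k)
            if not m.any():
                raise _EmptyCluster()
            centers[k] = X[m].mean(axis=0)
        # (c) feature-weight update
        if cfg.update_feature_weights:
            bss = _per_feature_bss(X, labels, keep)
            w = _weights_from_bss(bss, s)
        obj = float(_per_feature_bss(X, labels, keep) @ w)
        obj_trace.append(obj)
        if prev_obj > -np.inf and abs(obj - prev_obj) <= 1e-8 * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    # trimmed weighted within-cluster SS: the restart-selection criterion
    # (selecting on between-cluster SS would reward splitting a gross
    # outlier into its own cluster)
    sw = np.sqrt(w)
    _, d2 = _assign(X * sw, centers * sw)
    keep_w = np.ones(n, dtype=bool)
    keep_w[O_W] = False
    wcss = float(d2[keep_w].sum())
    return centers, w, labels, O_W, O_E, obj_trace, wcss


class _EmptyCluster(RuntimeError):
    pass


def fit_rskc(
    X: ExpressionMatrix, cfg: RskcConfig | None = None, initial_centers=None
) -> RskcModel:
    """Fit RSKC by alternating trimmed K-means and feature-weight updates.

    The best of ``n_init`` restarts (by weighted between-cluster sum of
    squares) is kept.  Restart initialization draws K distinct samples by
    identifier order, so a permutation of the rows changes nothing but
    the order of the outputs.
    """
    cfg = cfg or RskcConfig()
    n, p = X.values.shape
    if n <= cfg.K / (1 - cfg.alpha):
        raise ValueError("too few samples for this K and trimming level")
    s = cfg.l1_bound if cfg.l1_bound is not None else max(1.0, math.sqrt(p) / 2)
    if not (1 <= s <= math.sqrt(p) + 1e-9):
        raise ValueError(f"l1_bound must lie in [1, sqrt(p)]; got {s}")

    # order-independent initialization: draw sample *identifiers*
    id_order = np.argsort(np.asarray(X.sample_ids, dtype=str), kind="stable")
    rng = np.random.default_rng(cfg.seed)

    best = None
    failures = 0
    n_runs = 1 if initial_centers is not None else cfg.n_init
    for _ in range(n_runs):
        try:
            if initial_centers is not None:
                out = _fit_once(X.values, cfg, s, initial_centers=initial_centers)
            else:
                # redraw if the drawn samples coincide (duplicated rows)
                for _ in range(50):
                    init_idx = id_order[rng.choice(n, size=cfg.K, replace=False)]
                    if len(np.unique(X.values[init_idx], axis=0)) == cfg.K:
                        break
                out = _fit_once(X.values, cfg, s, init_idx=init_idx)
        except _EmptyCluster:
            failures += 1
            if failures >= cfg.n_init:
                raise RuntimeError(
                    "empty cluster after trimming in every restart; "
                    "reduce alpha or K"
                )
            continue
        if best is None or out[6] < best[6]:
            best = out
    if best is None:
        raise RuntimeError("all RSKC restarts failed")
    centers, w, labels, O_W, O_E, trace, _ = best
    return RskcModel(
        centers=centers,
        feature_weights=w,
        assignments=labels + 1,
        trimmed_weighted=np.sort(O_W),
        trimmed_unweighted=np.sort(O_E),
        selected_features=set(X.feature_ids[np.flatnonzero(w > 0)]),
        objective=trace[-1],
        objective_trace=trace,
        config_used=cfg,
        feature_ids=X.feature_ids,
    )


def rskc_outlier_scores(model: RskcModel, X: ExpressionMatrix) -> np.ndarray:
    """Unweighted squared distance to the nearest center, for every sample
    (trimmed ones included).

    This is the second-stage trimming criterion (the one that defines
    O_E).  It is preferred over the weighted distance for ranking
    because sparse feature weights make the weighted distance blind to
    gross shifts on zero-weight features -- exactly the coordinate
    outliers the second trimming stage exists to catch.
    """
    if list(X.feature_ids) != list(model.feature_ids):
        raise ValueError("feature ids do not match the fitted model")
    _, d2 = _assign(X.values, model.centers)
    return d2


def map_clusters_to_labels(assignments: np.ndarray, y: ClassLabels) -> np.ndarray:
    """Relabel two clusters as classes to minimize misclassifications.

    Ties between the two possible mappings keep the identity mapping
    (cluster 1 -> class 0, cluster 2 -> class 1).
    """
    a = np.asarray(assignments)
    ks = np.unique(a)
    if len(ks) > 2 or not set(ks) <= {1, 2}:
        raise ValueError("cluster-to-label mapping requires K = 2")
    identity = (a - 1 != y.y).sum()
    swapped = (2 - a != y.y).sum()
    return (a - 1) if identity <= swapped else (2 - a)


def tune_l1_bound(
    X: ExpressionMatrix,
    grid,
    cfg: RskcConfig | None = None,
    n_permutations: int = 25,
    seed: int = 0,
) -> float:
    """Choose the L1 bound by the permutation gap statistic.

    For each candidate bound the weighted between-cluster sum of squares
    of the real data is compared with its average over datasets whose
    feature columns are independently permuted (destroying cluster
    structure while keeping marginals); the bound with the largest gap
    in log objective wins.
    """
    cfg = cfg or RskcConfig()
    rng = np.random.default_rng(seed)
    perms = []
    for _ in range(n_permutations):
        V = np.column_stack(
            [rng.permutation(X.values[:, j]) for j in range(X.n_features)]
        )
        perms.append(
            ExpressionMatrix(V, X.sample_ids, X.feature_ids, X.log_scale)
        )
    light = RskcConfig(
        K=cfg.K, alpha=cfg.alpha, n_init=1, max_iter=cfg.max_iter, seed=cfg.seed
    )
    best_s, best_gap = None, -np.inf
    for s in grid:
        cs = RskcConfig(
            K=cfg.K, alpha=cfg.alpha, l1_bound=s, n_init=cfg.n_init,
            max_iter=cfg.max_iter, seed=cfg.seed,
        )
        obs = math.log(max(fit_rskc(X, cs).objective, 1e-300))
        cl = RskcConfig(
            K=light.K, alpha=light.alpha, l1_bound=s, n_init=1,
            max_iter=light.max_iter, seed=light.seed,
        )
        null = [
            math.log(max(fit_rskc(P, cl).objective, 1e-300)) for P in perms
        ]
        gap = obs - float(np.mean(null))
        if gap > best_gap:
            best_s, best_gap = s, gap
    return best_s
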