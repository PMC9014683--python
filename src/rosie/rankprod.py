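"""Rank-product consensus test for influential samples.

Each classifier ranks the n samples by outlyingness (rank 1 = most
outlying, ties averaged).  The rank product RP(i) = prod_l R_l(i) fuses
the k rankings; a sample consistently near the top of all rankings gets
a small RP.  Significance comes from the exact discrete null in which
the k ranks are independent uniforms on {1, ..., n}: the tail
probability P(prod U_l <= rp) is obtained by counting the k-tuples with
bounded product via a capped divisor-sum recursion, which is exact and
cheap even for n ~ 1000, k = 3.  Multiple testing across samples is
handled by Benjamini-Hochberg q-values (Storey's estimator available as
an option), and samples with q below a threshold are called influential.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from functools import lru_cache

import numpy as np
from scipy.special import gammaincc
from scipy.stats import rankdata
from statsmodels.stats.multitest import multipletests

__all__ = [
    "OutlierRanking",
    "ConsensusResult",
    "rank_with_ties",
    "rank_product",
    "rp_pvalue",
    "bh_qvalues",
    "storey_qvalues",
    "call_influential",
    "consensus_from_scores",
]


@dataclass(frozen=True)
class OutlierRanking:
    """One method's outlyingness scores and the derived ranks."""

    method_id: str
    scores: np.ndarray
    ranks: np.ndarray = field(init=False)

    def __post_init__(self) -> None:
        scores = np.asarray(self.scores, dtype=float)
        object.__setattr__(self, "scores", scores)
        object.__setattr__(self, "ranks", rank_with_ties(scores))


@dataclass
class ConsensusResult:
    sample_ids: np.ndarray
    ranks: np.ndarray  # n x k matrix of per-method ranks
    rp: np.ndarray
    p_values: np.ndarray
    q_values: np.ndarray
    influential: list  # sample ids, sorted by (q, rp)
    q_threshold: float = 0.05
    intersected_features: set = field(default_factory=set)

    def to_frame(self):
        import pandas as pd

        k = self.ranks.shape[1]
        df = pd.DataFrame(
            self.ranks, columns=[f"rank_{l + 1}" for l in range(k)]
        )
        df.insert(0, "sample_id", self.sample_ids)
        df["RP"] = self.rp
        df["p_value"] = self.p_values
        df["q_value"] = self.q_values
        df["influential"] = df["q_value"] < self.q_threshold
        return df


def rank_with_ties(scores: np.ndarray) -> np.ndarray:
    """Descending-score ranks with average tie handling (rank 1 = most
    outlying)."""
    scores = np.asarray(scores, dtype=float)
    if not np.all(np.isfinite(scores)):
        raise ValueError("scores must be finite")
    return rankdata(-scores, method="average")


def rank_product(rankings) -> np.ndarray:
    """Elementwise product of k >= 2 rank vectors."""
    arrs = [np.asarray(r, dtype=float) for r in rankings]
    if len(arrs) < 2:
        raise ValueError("need at least two rankings")
    n = len(arrs[0])
    if any(len(a) != n for a in arrs):
        raise ValueError("rank vectors differ in length")
    out = np.ones(n)
    for a in arrs:
        out *= a
    return out


def _count_tuples_leq(m: int, n: int, k: int) -> int:
    """Number of k-tuples (u_1..u_k), each in {1..n}, with product <= m.

    Capped divisor-sum recursion; for k = 3 and n ~ 1000 this is on the
    order of 1e5 integer operations.
    """
    if m <= 0:
        return 0
    if k == 1:
        return min(n, m)
    if k == 2:
        u = np.arange(1, min(n, m) + 1)
        return int(np.minimum(n, m // u).sum())
    u = np.arange(1, min(n, m) + 1)
    quots, counts = np.unique(m // u, return_counts=True)
    return int(
        sum(c * _count_tuples_leq(int(q), n, k - 1) for q, c in zip(quots, counts))
    )


@lru_cache(maxsize=100_000)
def _cached_count(m: int, n: int, k: int) -> int:
    return _count_tuples_leq(m, n, k)


def rp_pvalue(rp: float, n: int, k: int, method: str = "exact") -> float:
    """Exact tail probability of a rank product under the discrete null.

    P(prod_{l=1..k} U_l <= rp) with U_l independent uniform on {1..n}.
    Tie-averaged (non-integer) rank products are handled by counting
    integer-product tuples up to floor(rp).  ``method='gamma'`` switches
    to the continuous gamma-tail approximation (useful for large k).
    """
    if not (1 <= rp <= float(n) ** k):
        raise ValueError(f"rank product {rp} outside [1, n^k]")
    if method == "gamma":
        # -log(prod U/n) ~ Gamma(k, 1) for continuous uniforms
        return float(gammaincc(k, -np.log(rp / float(n) ** k)))
    if method != "exact":
        raise ValueError(f"unknown method {method!r}")
    m = int(np.floor(rp + 1e-9))
    return _cached_count(m, n, k) / float(n) ** k


def bh_qvalues(p_values: np.ndarray) -> np.ndarray:
    """Benjamini-Hochberg step-up q-values (monotone in p)."""
    p = np.asarray(p_values, dtype=float)
    if ((p < 0) | (p > 1)).any():
        raise ValueError("p-values must lie in [0, 1]")
    return multipletests(p, method="fdr_bh")[1]


def storey_qvalues(p_values: np.ndarray, lam: float = 0.5) -> np.ndarray:
    """Storey q-values with the plug-in null-proportion estimate
    pi0 = #{p > lam} / ((1 - lam) n), capped at 1."""
    p = np.asarray(p_values, dtype=float)
    n = len(p)
    pi0 = min(1.0, (p > lam).sum() / ((1.0 - lam) * n)) if n else 1.0
    pi0 = max(pi0, 1.0 / n) if n else 1.0
    order = np.argsort(p, kind="stable")
    q = np.empty(n)
    prev = 1.0
    for rank_idx in range(n - 1, -1, -1):
        i = order[rank_idx]
        val = pi0 * p[i] * n / (rank_idx + 1)
        prev = min(prev, val)
        q[i] = prev
    return q


def call_influential(q_values, sample_ids, rp=None, q_threshold: float = 0.05):
    """Sample ids with q below threshold, ordered by ascending q then RP."""
    q = np.asarray(q_values, dtype=float)
    ids = np.asarray(sample_ids)
    rp = np.asarray(rp, dtype=float) if rp is not None else np.zeros(len(q))
    hits = np.flatnonzero(q < q_threshold)
    hits = hits[np.lexsort((rp[hits], q[hits]))]
    return [ids[i] for i in hits]


def consensus_from_scores(
    score_vectors,
    sample_ids,
    q_threshold: float = 0.05,
    q_method: str = "bh",
    p_method: str = "exact",
) -> ConsensusResult:
    """Full consensus pipeline from k per-method outlyingness score vectors."""
    rankings = [rank_with_ties(s) for s in score_vectors]
    k = len(rankings)
    n = len(rankings[0])
    rp = rank_product(rankings)
    p = np.array([rp_pvalue(v, n, k, method=p_method) for v in rp])
    if q_method == "bh":
        q = bh_qvalues(p)
    elif q_method == "storey":
        q = storey_qvalues(p)
    else:
        raise ValueError(f"unknown q-value method {q_method!r}")
    return ConsensusResult(
        sample_ids=np.asarray(sample_ids),
        ranks=np.column_stack(rankings),
        rp=rp,
        p_values=p,
        q_values=q,
        influential=call_influential(q, sample_ids, rp, q_threshold),
        q_threshold=q_threshold,
    )
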