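"""Stratified block-bootstrap validity check.

The sample set is partitioned (stratified by class) into m near-equal
blocks; each block is then filled back to the original size n by
class-stratified sampling with replacement from the complete dataset, so
every sample appears in at least one block and each block keeps the
original class proportion.  The three classifiers are refitted on every
block with the hyperparameters of the main run (no re-optimization) and
the stability of the influential-sample and common-feature calls is
tallied against the main result.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np

from .ensemble import RosieConfig, RosieResult, run_rosie
from .io_prep import ClassLabels, ExpressionMatrix

__all__ = ["BootstrapReport", "make_bootstrap_blocks", "run_validity_check"]


@dataclass
class BootstrapReport:
    m: int
    blocks: list  # m integer index arrays of length n (multisets)
    partition: list  # m disjoint index arrays covering all samples
    per_block: list  # per block: dict with influential ids / common features, or None
    failed_blocks: list  # indices of blocks whose fit failed, with messages
    influential_redetection: dict  # sample id -> (blocks containing, re-influential)
    feature_support: dict  # feature id -> blocks where commonly selected again


def make_bootstrap_blocks(sample_ids, y: ClassLabels, m: int, seed: int = 0):
    """Build m stratified bootstrap blocks of size n.

    Each class is shuffled and split into m parts differing by at most
    one in size (the partition), and each block is topped up to the
    original per-class counts by drawing with replacement from all
    samples of that class.  Deterministic given the seed.

    Returns
    -------
    (blocks, partition) : two lists of m integer index arrays; blocks
        are multisets of size n, partition parts are disjoint and cover
        every sample.
    """
    if m < 2:
        raise ValueError("need at least two blocks")
    y_arr = y.y
    n = len(y_arr)
    rng = np.random.default_rng(seed)
    parts = [[] for _ in range(m)]
    fills = [[] for _ in range(m)]
    for cls in (0, 1):
        idx = np.flatnonzero(y_arr == cls)
        if len(idx) < m:
            raise ValueError(
                f"class {cls} has only {len(idx)} samples, fewer than m={m}"
            )
        idx = rng.permutation(idx)
        # near-equal split: block sizes differ by at most 1; which blocks
        # receive the remainder is a seeded draw
        base, rem = divmod(len(idx), m)
        sizes = np.full(m, base)
        sizes[rng.choice(m, size=rem, replace=False)] += 1
        stops = np.cumsum(sizes)
        starts = stops - sizes
        for b in range(m):
            part = idx[starts[b]:stops[b]]
            parts[b].append(part)
            need = len(idx) - len(part)
            fills[b].append(rng.choice(np.sort(idx), size=need, replace=True))
    partition = [np.sort(np.concatenate(p)) for p in parts]
    blocks = [
        np.sort(np.concatenate(parts[b] + fills[b])) for b in range(m)
    ]
    assert all(len(b) == n for b in blocks)
    return blocks, partition


def run_validity_check(
    X: ExpressionMatrix,
    y: ClassLabels,
    main_result: RosieResult,
    m: int = 5,
    seed: int = 0,
    config: RosieConfig | None = None,
) -> BootstrapReport:
    """Refit the ensemble on m bootstrap blocks with the main run's
    hyperparameters and tally redetection of its calls.

    A block whose fit fails is recorded and skipped, not fatal.  Inside
    a block, duplicated samples are genuine multiset duplicates and the
    consensus null uses n = block size with duplicates counted
    individually.
    """
    config = config or main_result.config_used or RosieConfig()
    config = replace(config, optimize=False)  # hyperparameters stay fixed
    blocks, partition = make_bootstrap_blocks(X.sample_ids, y, m, seed)

    main_influential = set(map(str, main_result.consensus.influential))
    main_common = set(main_result.common_features)
    per_block = []
    failed = []
    for b, idx in enumerate(blocks):
        ids = np.array(
            [f"{X.sample_ids[i]}::b{b}r{j}" for j, i in enumerate(idx)],
            dtype=object,
        )
        Xb = X.subset_samples(idx, sample_ids=ids)
        yb = y.subset(idx)
        try:
            res = run_rosie(Xb, yb, config, seed=seed + b + 1)
        except RuntimeError as exc:
            per_block.append(None)
            failed.append((b, str(exc)))
            continue
        # map flagged block rows back to original sample ids
        flagged = {str(s).split("::")[0] for s in res.consensus.influential}
        per_block.append(
            {
                "influential": flagged,
                "common_features": set(res.common_features),
                "block_members": {str(X.sample_ids[i]) for i in idx},
            }
        )

    redetect = {}
    for sid in main_influential:
        containing = 0
        re_flagged = 0
        for b, idx in enumerate(blocks):
            if per_block[b] is None:
                continue
            if sid in per_block[b]["block_members"]:
                containing += 1
                if sid in per_block[b]["influential"]:
                    re_flagged += 1
        redetect[sid] = (containing, re_flagged)
    support = {
        f: sum(
            1
            for pb in per_block
            if pb is not None and f in pb["common_features"]
        )
        for f in main_common
    }
    return BootstrapReport(
        m=m,
        blocks=blocks,
        partition=partition,
        per_block=per_block,
        failed_blocks=failed,
        influential_redetection=redetect,
        feature_support=support,
    )
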