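"""Expression-matrix containers, file I/O and pre-processing filters.

The pipeline consumes a samples x features numeric matrix together with a
binary class label per sample.  Pre-processing mirrors the standard
RNA-Seq preparation for a robust classifier: drop features that never
vary, keep the features most predictive of the class by a univariate
ROC-AUC importance screen, and move to log scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.stats import rankdata

__all__ = [
    "ExpressionMatrix",
    "ClassLabels",
    "read_expression",
    "write_expression",
    "drop_constant_features",
    "auc_importance_filter",
    "log_transform",
    "feature_auc",
]


@dataclass(frozen=True)
class ExpressionMatrix:
    """An n x p expression matrix with sample and feature identifiers.

    Parameters
    ----------
    values : ndarray of shape (n_samples, n_features)
        Expression values (arbitrary units, log or linear scale).
    sample_ids : ndarray of str
        Unique sample identifiers, one per row.
    feature_ids : ndarray of str
        Unique feature identifiers, one per column.
    log_scale : bool
        Whether ``values`` are already on log scale.
    """

    values: np.ndarray
    sample_ids: np.ndarray
    feature_ids: np.ndarray
    log_scale: bool = False

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        sample_ids = np.asarray(self.sample_ids, dtype=object)
        feature_ids = np.asarray(self.feature_ids, dtype=object)
        object.__setattr__(self, "values", values)
        object.__setattr__(self, "sample_ids", sample_ids)
        object.__setattr__(self, "feature_ids", feature_ids)
        if values.ndim != 2:
            raise ValueError("expression values must be a 2-D array")
        if values.shape != (len(sample_ids), len(feature_ids)):
            raise ValueError(
                f"matrix shape {values.shape} does not match "
                f"{len(sample_ids)} sample ids x {len(feature_ids)} feature ids"
            )
        if not np.all(np.isfinite(values)):
            i, j = np.argwhere(~np.isfinite(values))[0]
            raise ValueError(
                f"non-finite value at sample {sample_ids[i]!r}, "
                f"feature {feature_ids[j]!r}"
            )
        for name, ids in (("sample", sample_ids), ("feature", feature_ids)):
            uniq, counts = np.unique(ids.astype(str), return_counts=True)
            if (counts > 1).any():
                dup = uniq[counts > 1].tolist()
                raise ValueError(f"duplicate {name} ids: {dup}")

    @property
    def n_samples(self) -> int:
        return self.values.shape[0]

    @property
    def n_features(self) -> int:
        return self.values.shape[1]

    def subset_features(self, mask: np.ndarray) -> "ExpressionMatrix":
        """Return a copy restricted to the feature columns selected by ``mask``."""
        mask = np.asarray(mask)
        return replace(
            self, values=self.values[:, mask], feature_ids=self.feature_ids[mask]
        )

    def subset_samples(self, idx: np.ndarray, sample_ids=None) -> "ExpressionMatrix":
        """Return a copy restricted to rows ``idx`` (duplicates allowed).

        When ``idx`` carries duplicates (bootstrap blocks) the caller must
        supply fresh unique ``sample_ids``.
        """
        idx = np.asarray(idx)
        ids = self.sample_ids[idx] if sample_ids is None else np.asarray(sample_ids)
        return replace(self, values=self.values[idx], sample_ids=ids)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            self.values,
            index=pd.Index(self.sample_ids, name="sample_id"),
            columns=self.feature_ids,
        )


@dataclass(frozen=True)
class ClassLabels:
    """Binary class membership for the samples of a paired matrix."""

    y: np.ndarray
    positive_class_name: str = "1"

    def __post_init__(self) -> None:
        y = np.asarray(self.y, dtype=int)
        object.__setattr__(self, "y", y)
        if y.ndim != 1:
            raise ValueError("labels must be a 1-D vector")
        bad = set(np.unique(y)) - {0, 1}
        if bad:
            raise ValueError(f"labels must be in {{0,1}}, found {sorted(bad)}")

    def __len__(self) -> int:
        return len(self.y)

    @property
    def both_classes_present(self) -> bool:
        return len(np.unique(self.y)) == 2

    def subset(self, idx: np.ndarray) -> "ClassLabels":
        return replace(self, y=self.y[np.asarray(idx)])


def read_expression(path, labels_path, sep: str = "\t"):
    """Read a delimited expression matrix and its paired label file.

    The matrix file has a header row of feature ids and sample ids in the
    first column; the label file has two columns (sample id, class in
    {0,1}) with or without a header.

    Returns
    -------
    (ExpressionMatrix, ClassLabels)
        Labels re-ordered to match the matrix's sample order.
    """
    header = pd.read_csv(path, sep=sep, header=None, nrows=1).iloc[0, 1:]
    dup_feats = sorted(set(header[header.duplicated()].astype(str)))
    if dup_feats:
        raise ValueError(f"duplicate feature ids in {path}: {dup_feats}")
    df = pd.read_csv(path, sep=sep, index_col=0)
    dup_samples = df.index[df.index.duplicated()].unique().tolist()
    if dup_samples:
        raise ValueError(f"duplicate sample ids in {path}: {dup_samples}")
    non_num = df.columns[
        [not np.issubdtype(dt, np.number) for dt in df.dtypes]
    ].tolist()
    if non_num:
        col = non_num[0]
        bad = df[col][pd.to_numeric(df[col], errors="coerce").isna()]
        raise ValueError(
            f"non-numeric value {bad.iloc[0]!r} at sample {bad.index[0]!r}, "
            f"feature {col!r}"
        )

    lab = pd.read_csv(labels_path, sep=sep, header=None, comment="#")
    if lab.shape[1] != 2:
        raise ValueError("label file must have exactly two columns")
    # tolerate a header row
    if not str(lab.iloc[0, 1]).strip() in {"0", "1"}:
        lab = lab.iloc[1:]
    lab_map = dict(zip(lab.iloc[:, 0].astype(str), lab.iloc[:, 1].astype(int)))
    missing = [s for s in df.index.astype(str) if s not in lab_map]
    if missing:
        raise ValueError(f"samples missing from label file: {missing}")

    X = ExpressionMatrix(
        values=df.to_numpy(dtype=float),
        sample_ids=df.index.astype(str).to_numpy(dtype=object),
        feature_ids=df.columns.astype(str).to_numpy(dtype=object),
    )
    y = ClassLabels(np.array([lab_map[s] for s in X.sample_ids], dtype=int))
    return X, y


def write_expression(X: ExpressionMatrix, path, sep: str = "\t") -> None:
    X.to_frame().to_csv(path, sep=sep)


def drop_constant_features(X: ExpressionMatrix) -> ExpressionMatrix:
    """Remove features whose value is identical across all samples.

    Idempotent; preserves feature order. Raises if nothing would remain.
    """
    varying = (X.values != X.values[0]).any(axis=0)
    if not varying.any():
        raise ValueError("all features are constant; nothing left to classify")
    if varying.all():
        return X
    return X.subset_features(varying)


def feature_auc(x: np.ndarray, y: np.ndarray) -> float:
    """Rank-based ROC AUC of a single feature as a score for class 1.

    Uses the Mann-Whitney identity with average ranks, so tied values
    contribute half a concordance.
    """
    y = np.asarray(y)
    n1 = int(y.sum())
    n0 = len(y) - n1
    if n0 == 0 or n1 == 0:
        raise ValueError("both classes must be present")
    r = rankdata(x)
    u = r[y == 1].sum() - n1 * (n1 + 1) / 2.0
    return float(u / (n1 * n0))


def auc_importance_filter(
    X: ExpressionMatrix, y: ClassLabels, keep: int
) -> ExpressionMatrix:
    """Keep the ``keep`` features with the highest univariate AUC importance.

    Importance of a feature is max(AUC, 1 - AUC) of its values as a
    classifier score for class 1, so both up- and down-regulated features
    rank high.  Ties at the cut are broken by original feature order.
    """
    if keep <= 0:
        raise ValueError("keep must be a positive integer")
    if keep > X.n_features:
        raise ValueError(f"keep={keep} exceeds available features ({X.n_features})")
    if not y.both_classes_present:
        raise ValueError("both classes must be present")
    auc = np.array([feature_auc(X.values[:, j], y.y) for j in range(X.n_features)])
    importance = np.maximum(auc, 1.0 - auc)
    # stable sort on negated importance keeps original order among ties
    order = np.argsort(-importance, kind="stable")[:keep]
    mask = np.zeros(X.n_features, dtype=bool)
    mask[order] = True
    return X.subset_features(mask)


def log_transform(
    X: ExpressionMatrix, base: float = 2.0, offset: float = 1.0
) -> ExpressionMatrix:
    """Replace values by log_base(x + offset) and set the log-scale flag.

    log2(x+1) by default, the usual convention for FPKM-type data.
    """
    if (X.values < 0).any():
        i, j = np.argwhere(X.values < 0)[0]
        raise ValueError(
            f"negative value at sample {X.sample_ids[i]!r}, "
            f"feature {X.feature_ids[j]!r}: cannot log transform"
        )
    vals = np.log(X.values + offset) / np.log(base)
    return replace(X, values=vals, log_scale=True)
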