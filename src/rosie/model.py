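"""Model/Results interface over the ensemble pipeline.

``ROSIE`` is constructed from data (arrays, an :class:`ExpressionMatrix`
or a DataFrame), ``fit()`` runs the three classifiers and the consensus,
and the returned :class:`ROSIEResults` carries the outlier table,
selected features and diagnostics, with ``summary()``, ``bootstrap()``
and plotting helpers hanging off it.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .bootstrap import BootstrapReport, run_validity_check
from .ensemble import METHODS, RosieConfig, RosieResult, run_rosie
from .io_prep import ClassLabels, ExpressionMatrix

__all__ = ["ROSIE", "ROSIEResults"]


class ROSIE:
    """Robust sparse ensemble for outlier detection and feature selection.

    Parameters
    ----------
    X : ExpressionMatrix, DataFrame or ndarray
        Samples x features expression data.
    y : ClassLabels or array-like of {0, 1}
        Binary class membership, aligned with the rows of ``X``.
    config : RosieConfig, optional
        Per-method hyperparameters and orchestration options.

    Examples
    --------
    >>> model = ROSIE(X, y)
    >>> res = model.fit(seed=1)
    >>> res.outlier_table.head()
    >>> res.common_features
    """

    def __init__(self, X, y, config: RosieConfig | None = None):
        if isinstance(X, pd.DataFrame):
            X = ExpressionMatrix(
                X.to_numpy(dtype=float),
                X.index.astype(str).to_numpy(dtype=object),
                X.columns.astype(str).to_numpy(dtype=object),
            )
        elif not isinstance(X, ExpressionMatrix):
            X = np.asarray(X, dtype=float)
            X = ExpressionMatrix(
                X,
                np.array([f"S{i}" for i in range(X.shape[0])], dtype=object),
                np.array([f"F{j}" for j in range(X.shape[1])], dtype=object),
            )
        if not isinstance(y, ClassLabels):
            y = ClassLabels(np.asarray(y))
        if len(y) != X.n_samples:
            raise ValueError("labels and matrix disagree on sample count")
        self.X = X
        self.y = y
        self.config = config or RosieConfig()

    @classmethod
    def from_dataframe(cls, df: pd.DataFrame, label_column: str, config=None):
        """Build from a single DataFrame holding features plus a label column."""
        y = df[label_column].to_numpy()
        return cls(df.drop(columns=[label_column]), y, config=config)

    def fit(self, seed: int = 0) -> "ROSIEResults":
        result = run_rosie(self.X, self.y, self.config, seed=seed)
        return ROSIEResults(self, result, seed)


class ROSIEResults:
    """Fitted ensemble: consensus outlier calls, selected features and
    per-method diagnostics."""

    def __init__(self, model: ROSIE, result: RosieResult, seed: int):
        self.model = model
        self.result = result
        self.seed = seed

    @property
    def consensus(self):
        return self.result.consensus

    @property
    def outlier_table(self) -> pd.DataFrame:
        """Per-sample consensus table: per-method ranks, RP, p, q, flag."""
        df = self.result.consensus.to_frame()
        df.columns = ["sample_id", *METHODS, "RP", "p_value", "q_value",
                      "influential"]
        return df

    @property
    def influential_samples(self) -> list:
        return list(self.result.consensus.influential)

    @property
    def common_features(self) -> set:
        return set(self.result.common_features)

    @property
    def commonly_misclassified(self) -> set:
        return set(self.result.commonly_misclassified)

    def selected_features(self, method: str) -> set:
        return set(self.result.per_method[method].selected_features)

    def misclassification_counts(self) -> dict:
        return {
            m: len(self.result.per_method[m].misclassified) for m in METHODS
        }

    def bootstrap(self, m: int = 5, seed: int = 0) -> BootstrapReport:
        """Stratified block-bootstrap validity check with the fitted
        hyperparameters."""
        return run_validity_check(
            self.model.X, self.model.y, self.result, m=m, seed=seed,
            config=self.result.config_used,
        )

    def summary(self) -> str:
        res = self.result
        lines = [
            "ROSIE ensemble results",
            "=" * 60,
            f"samples: {self.model.X.n_samples}   "
            f"features: {self.model.X.n_features}",
            "",
            "method    selected  misclassified  hyperparameters",
        ]
        for m in METHODS:
            mr = res.per_method[m]
            hp = ", ".join(f"{k}={v:.4g}" if isinstance(v, float) else f"{k}={v}"
                           for k, v in mr.hyperparameters_chosen.items())
            lines.append(
                f"{m:<9} {len(mr.selected_features):>8}  "
                f"{len(mr.misclassified):>13}  {hp}"
            )
        lines += [
            "",
            f"common features (3-way intersection): {len(res.common_features)}",
            f"commonly misclassified samples:       "
            f"{len(res.commonly_misclassified)}",
            f"influential samples (q < "
            f"{res.consensus.q_threshold:g}): {len(res.consensus.influential)}",
        ]
        if res.consensus.influential:
            df = self.outlier_table
            flagged = df[df["influential"]].sort_values(["q_value", "RP"])
            lines.append("")
            lines.append(flagged.to_string(index=False))
        return "\n".join(lines)

    def __repr__(self) -> str:  # pragma: no cover - cosmetic
        return (
            f"<ROSIEResults: {len(self.influential_samples)} influential, "
            f"{len(self.common_features)} common features>"
        )
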