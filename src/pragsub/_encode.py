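"""Numeric design-matrix encoding of mixed-type covariate tables.

Continuous and binary columns pass through as floats; categorical columns
are expanded to one-hot indicators with the level order frozen at fit time
so train/predict matrices stay column-compatible.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .exceptions import SchemaMismatchError


class ColumnEncoder:
    """Freeze a covariate schema and map frames to float matrices."""

    def __init__(self) -> None:
        self.columns_: list[str] | None = None
        self.kinds_: dict[str, str] | None = None
        self.levels_: dict[str, list] = {}

    def fit(self, covariates: pd.DataFrame, kinds: dict[str, str]) -> "ColumnEncoder":
        self.columns_ = list(covariates.columns)
        self.kinds_ = {c: kinds[c] for c in self.columns_}
        self.levels_ = {}
        for col in self.columns_:
            if self.kinds_[col] == "categorical":
                s = covariates[col]
                if isinstance(s.dtype, pd.CategoricalDtype):
                    self.levels_[col] = list(s.cat.categories)
                else:
                    self.levels_[col] = sorted(s.dropna().astype(str).unique())
        return self

    def transform(self, covariates: pd.DataFrame) -> np.ndarray:
        if self.columns_ is None:
            raise RuntimeError("encoder is not fitted")
        missing = [c for c in self.columns_ if c not in covariates.columns]
        extra = [c for c in covariates.columns if c not in self.columns_]
        if missing or extra:
            raise SchemaMismatchError(missing=missing, extra=extra)
        blocks: list[np.ndarray] = []
        for col in self.columns_:
            if self.kinds_[col] == "categorical":
                codes = pd.Categorical(
                    covariates[col].astype(str), categories=self.levels_[col]
                ).codes
                # one-hot, first level dropped as reference; unseen -> all zero
                levels = self.levels_[col]
                onehot = np.zeros((len(covariates), max(len(levels) - 1, 0)))
                for j in range(1, len(levels)):
                    onehot[:, j - 1] = codes == j
                blocks.append(onehot)
            else:
                blocks.append(
                    covariates[col].to_numpy(dtype=float).reshape(-1, 1)
                )
        if not blocks:
            return np.empty((len(covariates), 0))
        return np.hstack(blocks)

    def fit_transform(self, covariates: pd.DataFrame, kinds: dict[str, str]) -> np.ndarray:
        return self.fit(covariates, kinds).transform(covariates)
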