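"""Two-arm trial dataset container and delimited-file round-trip.

A :class:`TrialDataset` holds one row per subject with columns
``subject_id, treatment, outcome, retained`` followed by named covariates.
The outcome is reverse-coded: 1 means event-free at the horizon, so a larger
treatment effect means larger benefit. Outcome is missing (NaN) for subjects
not followed to the horizon. Datasets are written as plain CSV with a YAML
sidecar schema declaring each covariate's kind (continuous / binary /
categorical, with level order for the latter).
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .exceptions import UnsupportedInputError, ValidationError

CORE_COLUMNS = ("subject_id", "treatment", "outcome", "retained")
COVARIATE_KINDS = ("continuous", "binary", "categorical")


@dataclasses.dataclass
class TrialDataset:
    """Per-subject treatment, outcome, retention and covariates.

    Parameters
    ----------
    frame:
        DataFrame with the core columns followed by covariates.
    covariate_kinds:
        Mapping of covariate column name to kind.
    oracle_effect:
        Planted per-subject risk difference (simulated data only), aligned
        with ``frame``.
    oracle_control_risk:
        Event-free probability in the control arm used by the simulator;
        lets the oracle expose arm-specific outcome probabilities.
    """

    frame: pd.DataFrame
    covariate_kinds: dict[str, str]
    oracle_effect: pd.Series | None = None
    oracle_control_risk: float | None = None

    def __post_init__(self) -> None:
        self.validate()

    # -- accessors -------------------------------------------------------
    @property
    def n(self) -> int:
        return len(self.frame)

    @property
    def covariate_names(self) -> list[str]:
        return list(self.covariate_kinds)

    @property
    def covariates(self) -> pd.DataFrame:
        return self.frame[self.covariate_names]

    @property
    def subject_id(self) -> pd.Series:
        return self.frame["subject_id"]

    @property
    def treatment(self) -> pd.Series:
        return self.frame["treatment"]

    @property
    def outcome(self) -> pd.Series:
        return self.frame["outcome"]

    @property
    def retained(self) -> pd.Series:
        return self.frame["retained"]

    def retained_subset(self) -> "TrialDataset":
        """Dataset restricted to subjects followed to the horizon."""
        mask = self.frame["retained"] == 1
        oracle = self.oracle_effect[mask.to_numpy()] if self.oracle_effect is not None else None
        return TrialDataset(
            frame=self.frame.loc[mask].reset_index(drop=True),
            covariate_kinds=dict(self.covariate_kinds),
            oracle_effect=None if oracle is None else oracle.reset_index(drop=True),
            oracle_control_risk=self.oracle_control_risk,
        )

    # -- validation ------------------------------------------------------
    def validate(self) -> None:
        for col in CORE_COLUMNS:
            if col not in self.frame.columns:
                raise ValidationError(f"dataset is missing required column {col!r}")
        if self.frame["subject_id"].duplicated().any():
            raise ValidationError("subject_id values are not unique")
        for col, kind in self.covariate_kinds.items():
            if kind not in COVARIATE_KINDS:
                raise ValidationError(f"unknown covariate kind {kind!r} for {col!r}")
            if col not in self.frame.columns:
                raise ValidationError(f"declared covariate {col!r} absent from data")
        undeclared = [
            c for c in self.frame.columns
            if c not in CORE_COLUMNS and c not in self.covariate_kinds
        ]
        if undeclared:
            raise ValidationError(f"columns without a declared kind: {undeclared}")
        if self.n:
            retained = self.frame["retained"].to_numpy()
            outcome = self.frame["outcome"].to_numpy(dtype=float)
            if np.isnan(outcome[retained == 1]).any():
                raise ValidationError("outcome missing for a retained subject")
            treat = self.frame["treatment"].to_numpy()
            if not np.isin(treat, (0, 1)).all():
                raise ValidationError("treatment must be 0/1")
        if self.oracle_effect is not None and len(self.oracle_effect) != self.n:
            raise ValidationError("oracle_effect length differs from dataset size")


def _schema_path(path: Path) -> Path:
    return path.with_suffix(".schema.yaml")


def write_dataset(dataset: TrialDataset, path: str | Path) -> Path:
    """Write the dataset as CSV plus a YAML sidecar schema; returns the CSV path."""
    path = Path(path)
    out = dataset.frame.copy()
    if dataset.oracle_effect is not None:
        out["_oracle_effect"] = dataset.oracle_effect.to_numpy()
    out.to_csv(path, index=False, na_rep="")
    schema: dict = {"covariates": {}}
    for col, kind in dataset.covariate_kinds.items():
        entry: dict = {"kind": kind}
        if kind == "categorical":
            s = dataset.frame[col]
            if isinstance(s.dtype, pd.CategoricalDtype):
                entry["levels"] = [str(v) for v in s.cat.categories]
            else:
                entry["levels"] = sorted(s.dropna().astype(str).unique())
        schema["covariates"][col] = entry
    if dataset.oracle_effect is not None:
        schema["oracle"] = {"effect_column": "_oracle_effect"}
        if dataset.oracle_control_risk is not None:
            schema["oracle"]["control_risk"] = float(dataset.oracle_control_risk)
    with open(_schema_path(path), "w") as fh:
        yaml.safe_dump(schema, fh, allow_unicode=True, sort_keys=False)
    return path


def read_dataset(path: str | Path, roles: dict[str, str] | None = None) -> TrialDataset:
    """Read a dataset written by :func:`write_dataset`.

    ``roles`` optionally maps the canonical roles (id, treatment, outcome,
    retained) to the column names used in the file.
    """
    path = Path(path)
    schema_file = _schema_path(path)
    if not schema_file.exists():
        raise UnsupportedInputError(f"sidecar schema not found: {schema_file}")
    with open(schema_file) as fh:
        schema = yaml.safe_load(fh) or {}
    cov_schema: dict = schema.get("covariates", {})
    kinds = {col: spec["kind"] for col, spec in cov_schema.items()}

    rename = {}
    if roles:
        canonical = {"id": "subject_id", "treatment": "treatment",
                     "outcome": "outcome", "retained": "retained"}
        rename = {roles[k]: v for k, v in canonical.items()
                  if k in roles and roles[k] != v}
    id_col = rename and next(
        (src for src, dst in rename.items() if dst == "subject_id"), "subject_id"
    ) or "subject_id"
    dtypes: dict[str, object] = {id_col: str}
    for col, spec in cov_schema.items():
        if spec["kind"] == "categorical":
            dtypes[col] = str
    frame = pd.read_csv(path, dtype=dtypes, keep_default_na=True)
    if rename:
        missing = [c for c in rename if c not in frame.columns]
        if missing:
            raise UnsupportedInputError(
                f"role columns absent from {path.name}: {missing}"
            )
        frame = frame.rename(columns=rename)
    if frame.empty and "subject_id" not in frame.columns:
        raise UnsupportedInputError(f"{path} has no header row")
    for col in ("treatment", "retained"):
        frame[col] = frame[col].astype("int64")
    frame["outcome"] = frame["outcome"].astype(float)
    for col, spec in cov_schema.items():
        if spec["kind"] == "categorical":
            frame[col] = pd.Categorical(frame[col], categories=spec.get("levels"))
        elif spec["kind"] == "binary":
            frame[col] = frame[col].astype(float)
        else:
            frame[col] = frame[col].astype(float)

    oracle = None
    control_risk = None
    if "oracle" in schema and schema["oracle"]:
        col = schema["oracle"].get("effect_column", "_oracle_effect")
        if col in frame.columns:
            oracle = frame.pop(col).astype(float)
        control_risk = schema["oracle"].get("control_risk")
    elif "_oracle_effect" in frame.columns:
        oracle = frame.pop("_oracle_effect").astype(float)

    return TrialDataset(
        frame=frame,
        covariate_kinds=kinds,
        oracle_effect=oracle,
        oracle_control_risk=control_risk,
    )
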