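"""Config-driven end-to-end pipeline.

Stages: simulate/ingest -> impute -> censoring weights -> CATE estimation
(or import) -> calibration -> recoding -> subgroup tree -> AIPW group
effects -> report. Every stage writes its artifact so any stage can be
re-run from disk, and all randomness derives from one master seed.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import __version__
from .calibration import c_for_benefit, qini_coefficient, qini_curve
from .datasets import TrialDataset, read_dataset, write_dataset
from .effects import aipw_scores, format_effects, group_ate_table
from .estimation import (
    EstimatorSettings,
    estimate_cate,
    fit_censoring_weights,
    read_estimate,
    write_estimate,
)
from .exceptions import ConfigurationError, PragsubError
from .recoding import apply_recoding, default_ruleset, load_rules
from .synthesis import SimulationConfig, lookahead_like_config, simulate_trial
from .tree import assign_groups, fit_tree, format_rules, rules_text, write_tree

log = logging.getLogger("pragsub")


class PipelineStageError(PragsubError):
    """A stage failed; the artifact trail up to that stage is preserved."""

    def __init__(self, stage: str, cause: Exception):
        self.stage = stage
        super().__init__(f"pipeline stage {stage!r} failed: {cause}")

ARTIFACTS = (
    "cate.csv",
    "calib.json",
    "qini_curve.csv",
    "recoded.csv",
    "tree.json",
    "rules.txt",
    "effects.csv",
    "report.json",
)


@dataclasses.dataclass
class PipelineConfig:
    """Validated pipeline settings with documented defaults."""

    data_path: str | None = None
    simulation: dict | None = None  # kwargs for lookahead_like_config, or "default"
    column_roles: dict = dataclasses.field(
        default_factory=lambda: {
            "id": "subject_id",
            "treatment": "treatment",
            "outcome": "outcome",
            "retained": "retained",
        }
    )
    impute: bool = True
    external_cate_path: str | None = None
    estimator: dict = dataclasses.field(default_factory=dict)
    recoding_rules_path: str | None = None  # None -> shipped default ruleset
    max_depth: int = 2
    min_leaf: int = 50
    qini_grid: int = 100
    qini_scale: str = "counts"
    n_boot: int = 200
    ci_level: float = 0.95
    propensity: float = 0.5
    truncation_quantile: float = 0.99
    seed: int = 0
    output_dir: str = "pragsub_output"

    def validate(self) -> None:
        if (self.data_path is None) == (self.simulation is None):
            raise ConfigurationError(
                "exactly one of data_path and simulation must be set"
            )
        for role in ("id", "treatment", "outcome", "retained"):
            if not self.column_roles.get(role):
                raise ConfigurationError(f"column role {role!r} is not mapped")
        if self.external_cate_path is not None and self.estimator:
            raise ConfigurationError(
                "exactly one of estimator settings and external_cate_path may be set"
            )
        if not 0 < self.propensity < 1:
            raise ConfigurationError("propensity must lie in (0, 1)")
        if self.max_depth < 0 or self.min_leaf < 1:
            raise ConfigurationError("max_depth must be >= 0 and min_leaf >= 1")
        if self.qini_scale not in ("counts", "per-subject"):
            raise ConfigurationError(f"unknown qini_scale {self.qini_scale!r}")

    def to_dict(self) -> dict:
        return dataclasses.asdict(self)


_KNOWN_FIELDS = {f.name for f in dataclasses.fields(PipelineConfig)}


def load_config(path: str | Path) -> PipelineConfig:
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    unknown = set(payload) - _KNOWN_FIELDS
    if unknown:
        raise ConfigurationError(f"unknown config fields: {sorted(unknown)}")
    config = PipelineConfig(**payload)
    config.validate()
    return config


def save_config(config: PipelineConfig, path: str | Path) -> Path:
    path = Path(path)
    with open(path, "w") as fh:
        yaml.safe_dump(config.to_dict(), fh, sort_keys=False, allow_unicode=True)
    return path


def config_hash(config: PipelineConfig) -> str:
    blob = json.dumps(config.to_dict(), sort_keys=True).encode()
    return hashlib.sha256(blob).hexdigest()[:16]


# ---------------------------------------------------------------------------
# Imputation
# ---------------------------------------------------------------------------


def impute_simple(dataset: TrialDataset) -> tuple[TrialDataset, dict[str, int]]:
    """Median/mode imputation of covariates; core columns are never touched.

    Returns the imputed dataset and a per-column count of imputed values.
    """
    frame = dataset.frame.copy()
    for col in ("treatment", "retained"):
        if frame[col].isna().any():
            raise ConfigurationError(f"core column {col!r} has missing values")
    counts: dict[str, int] = {}
    for col, kind in dataset.covariate_kinds.items():
        missing = frame[col].isna()
        n_missing = int(missing.sum())
        if n_missing == 0:
            continue
        if n_missing == len(frame):
            raise ConfigurationError(f"covariate {col!r} is entirely missing")
        if kind == "continuous":
            fill = frame[col].median()
        else:
            fill = frame[col].mode(dropna=True).iloc[0]
        frame[col] = frame[col].fillna(fill)
        counts[col] = n_missing
    return (
        TrialDataset(
            frame=frame,
            covariate_kinds=dict(dataset.covariate_kinds),
            oracle_effect=dataset.oracle_effect,
            oracle_control_risk=dataset.oracle_control_risk,
        ),
        counts,
    )


# ---------------------------------------------------------------------------
# Pipeline
# ---------------------------------------------------------------------------


def _child_seeds(master: int, n: int = 4) -> list[int]:
    ss = np.random.SeedSequence(master)
    return [int(s.generate_state(1)[0]) for s in ss.spawn(n)]


def _load_or_simulate(config: PipelineConfig, sim_seed: int) -> TrialDataset:
    if config.data_path is not None:
        return read_dataset(config.data_path, roles=config.column_roles)
    sim = config.simulation if isinstance(config.simulation, dict) else {}
    sim = dict(sim)
    sim.setdefault("seed", sim_seed)
    return simulate_trial(lookahead_like_config(**sim))


def run_pipeline(config: PipelineConfig) -> dict:
    """Execute all stages, write the artifacts, and return the report bundle."""
    config.validate()
    out = Path(config.output_dir)
    out.mkdir(parents=True, exist_ok=True)
    sim_seed, est_seed, boot_seed, _ = _child_seeds(config.seed)
    stage = "ingest"
    try:
        dataset = _load_or_simulate(config, sim_seed)
        write_dataset(dataset, out / "data.csv")

        stage = "impute"
        imputed_counts: dict[str, int] = {}
        if config.impute:
            dataset, imputed_counts = impute_simple(dataset)

        stage = "censoring-weights"
        weights = fit_censoring_weights(
            dataset, truncation_quantile=config.truncation_quantile
        )

        stage = "estimate"
        analytic = dataset.retained_subset()
        if config.external_cate_path is not None:
            estimate = read_estimate(config.external_cate_path)
            estimate = estimate.aligned_to(analytic.subject_id.to_numpy())
        else:
            estimate = estimate_cate(
                dataset,
                weights=weights,
                settings=EstimatorSettings(**config.estimator),
                seed=est_seed,
            )
        write_estimate(estimate, out / "cate.csv")

        stage = "calibrate"
        qini = qini_curve(
            estimate, dataset, weights=weights,
            grid=config.qini_grid, scale=config.qini_scale,
        )
        coefficient = qini_coefficient(qini)
        cfb = c_for_benefit(
            estimate, dataset,
            n_boot=config.n_boot, level=config.ci_level, seed=boot_seed,
        )
        curve = qini.curve.copy()
        curve["baseline"] = qini.baseline["uplift"]
        curve.to_csv(out / "qini_curve.csv", index=False)
        calib = {
            "qini_coefficient": coefficient,
            "qini_scale": config.qini_scale,
            "c_for_benefit": cfb.statistic,
            "c_for_benefit_ci": list(cfb.ci) if cfb.ci else None,
            "ci_level": config.ci_level,
            "n_boot": config.n_boot,
            "degenerate": cfb.degenerate,
        }
        (out / "calib.json").write_text(json.dumps(calib, indent=2))

        stage = "recode"
        rules = (
            load_rules(config.recoding_rules_path)
            if config.recoding_rules_path
            else default_ruleset()
        )
        recoded = apply_recoding(analytic, rules)
        recoded.index = analytic.subject_id.astype(str).to_numpy()
        recoded.to_csv(out / "recoded.csv", index_label="subject_id")

        stage = "discover"
        tree = fit_tree(
            estimate, recoded,
            max_depth=config.max_depth, min_leaf=config.min_leaf,
            weights=weights.for_subjects(analytic.subject_id),
        )
        write_tree(tree, out / "tree.json")
        (out / "rules.txt").write_text(format_rules(tree))
        groups, _ = assign_groups(tree, recoded)

        stage = "effects"
        scores = aipw_scores(
            dataset, estimate, propensity=config.propensity, weights=weights
        )
        effects = group_ate_table(scores, groups.to_numpy())
        format_effects(effects).to_csv(out / "effects.csv", index=False)

        stage = "report"
        report = {
            "analytic_n": int(analytic.n),
            "total_n": int(dataset.n),
            "events": int((analytic.outcome == 0).sum()),
            "imputed_counts": imputed_counts,
            "censoring_weights": weights.metadata,
            "calibration": calib,
            "rules": rules_text(tree).to_dict(orient="records"),
            "group_effects": format_effects(effects).to_dict(orient="records"),
            "provenance": {
                "package_version": __version__,
                "config_hash": config_hash(config),
                "master_seed": config.seed,
                "child_seeds": {
                    "simulate": sim_seed, "estimate": est_seed, "bootstrap": boot_seed,
                },
                "cate_provenance": estimate.provenance,
            },
        }
        (out / "report.json").write_text(
            json.dumps(report, indent=2, ensure_ascii=False)
        )
        return report
    except Exception as exc:
        raise PipelineStageError(stage, exc) from exc
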