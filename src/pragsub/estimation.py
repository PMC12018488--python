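"""Per-subject treatment-effect estimation on the risk-difference scale.

The reference estimator is an honest T-learner: one ensemble of weighted
regression trees per arm, where each tree is grown on a bootstrap draw whose
first half chooses the splits and whose second half supplies the leaf means
(honesty). Predicted effects are the difference of the two arm-specific
event-free probabilities, so they live in [-1, 1].

Loss to follow-up is handled with inverse-probability-of-censoring weights
(IPCW): a main-effects logistic model of retention on treatment and all raw
covariates, inverted and truncated at an upper quantile.

Any alternative estimator can replace the reference one as long as it
produces a :class:`CateEstimate`; externally computed estimates can be
imported from CSV.
"""

from __future__ import annotations

import dataclasses
from pathlib import Path

import numpy as np
import pandas as pd
from sklearn.exceptions import ConvergenceWarning
from sklearn.linear_model import LogisticRegression
from sklearn.tree import DecisionTreeRegressor

from ._encode import ColumnEncoder
from .datasets import TrialDataset
from .exceptions import (
    ConfigurationError,
    InsufficientDataError,
    UnsupportedInputError,
)

# ---------------------------------------------------------------------------
# CateEstimate
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CateEstimate:
    """Per-subject estimated (or oracle) risk difference with arm predictions."""

    table: pd.DataFrame  # columns: subject_id, tau_hat [, mu0_hat, mu1_hat]
    provenance: str = "model"
    metadata: dict = dataclasses.field(default_factory=dict)

    def __post_init__(self) -> None:
        required = {"subject_id", "tau_hat"}
        if not required.issubset(self.table.columns):
            raise UnsupportedInputError(
                f"estimate table needs columns {sorted(required)}"
            )
        tau = self.table["tau_hat"].to_numpy(dtype=float)
        if not np.all(np.isfinite(tau)):
            raise UnsupportedInputError("tau_hat contains non-finite values")

    @classmethod
    def from_arrays(cls, subject_id, tau, mu0=None, mu1=None,
                    provenance="model", metadata=None) -> "CateEstimate":
        table = pd.DataFrame({"subject_id": np.asarray(subject_id).astype(str),
                              "tau_hat": np.asarray(tau, dtype=float)})
        if mu0 is not None:
            table["mu0_hat"] = np.asarray(mu0, dtype=float)
        if mu1 is not None:
            table["mu1_hat"] = np.asarray(mu1, dtype=float)
        return cls(table=table, provenance=provenance, metadata=metadata or {})

    @property
    def subject_id(self) -> pd.Series:
        return self.table["subject_id"]

    @property
    def tau(self) -> np.ndarray:
        return self.table["tau_hat"].to_numpy(dtype=float)

    @property
    def has_arm_predictions(self) -> bool:
        return {"mu0_hat", "mu1_hat"}.issubset(self.table.columns)

    def aligned_to(self, subject_id) -> "CateEstimate":
        """Reorder rows to match the given subject_id sequence."""
        ids = pd.Index(np.asarray(subject_id).astype(str))
        indexed = self.table.set_index(self.table["subject_id"].astype(str))
        missing = ids.difference(indexed.index)
        if len(missing):
            raise UnsupportedInputError(
                f"estimate lacks {len(missing)} subjects, e.g. {list(missing[:3])}"
            )
        return CateEstimate(
            table=indexed.loc[ids].reset_index(drop=True),
            provenance=self.provenance,
            metadata=dict(self.metadata),
        )


def write_estimate(estimate: CateEstimate, path: str | Path) -> Path:
    path = Path(path)
    estimate.table.to_csv(path, index=False)
    return path


def read_estimate(path: str | Path, provenance: str = "imported") -> CateEstimate:
    table = pd.read_csv(path, dtype={"subject_id": str})
    return CateEstimate(table=table, provenance=provenance)


# ---------------------------------------------------------------------------
# Censoring weights
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CensoringWeights:
    """IPCW weights for retained subjects.

    ``probability`` holds the modeled retention probability for every
    subject; ``weights`` holds 1/probability, truncated, for retained
    subjects only (indexed by subject_id).
    """

    probability: pd.Series
    weights: pd.Series
    truncation_quantile: float
    metadata: dict = dataclasses.field(default_factory=dict)

    def for_subjects(self, subject_id) -> np.ndarray:
        ids = np.asarray(subject_id).astype(str)
        return self.weights.reindex(ids).to_numpy(dtype=float)


def unit_weights(dataset: TrialDataset) -> CensoringWeights:
    """All-ones weights (no censoring adjustment)."""
    ids = dataset.subject_id.astype(str)
    prob = pd.Series(1.0, index=ids.to_numpy())
    retained_ids = ids[dataset.retained == 1].to_numpy()
    return CensoringWeights(
        probability=prob,
        weights=pd.Series(1.0, index=retained_ids),
        truncation_quantile=1.0,
        metadata={"method": "unit"},
    )


def fit_censoring_weights(
    dataset: TrialDataset,
    truncation_quantile: float = 0.99,
    covariate_names: list[str] | None = None,
) -> CensoringWeights:
    """Fit retention ~ treatment + covariates and invert into IPCW weights.

    Falls back to an intercept-only fit (weights equal to 1 over the retained
    proportion) when the logistic fit cannot be computed, and records the
    route taken in ``metadata``.
    """
    if not 0 < truncation_quantile <= 1:
        raise ConfigurationError("truncation_quantile must lie in (0, 1]")
    retained = dataset.retained.to_numpy()
    names = dataset.covariate_names if covariate_names is None else covariate_names
    ids = dataset.subject_id.astype(str).to_numpy()

    method = "logistic"
    probs: np.ndarray
    if retained.min() == retained.max():
        probs = np.full(dataset.n, float(retained.mean()) if dataset.n else 1.0)
        method = "constant"
    elif not names:
        probs = np.full(dataset.n, float(retained.mean()))
        method = "intercept-only"
    else:
        design = dataset.frame[names].copy()
        design.insert(0, "treatment", dataset.treatment.to_numpy(dtype=float))
        kinds = {"treatment": "binary", **{c: dataset.covariate_kinds[c] for c in names}}
        X = ColumnEncoder().fit_transform(design, kinds)
        # standardize for lbfgs stability; invariant for the fitted probabilities
        sd = X.std(axis=0)
        sd[sd == 0] = 1.0
        X = (X - X.mean(axis=0)) / sd
        import warnings

        try:
            with warnings.catch_warnings():
                warnings.simplefilter("error", ConvergenceWarning)
                model = LogisticRegression(
                    C=1e8, solver="lbfgs", max_iter=5000
                ).fit(X, retained)
            probs = model.predict_proba(X)[:, 1]
        except Exception:
            probs = np.full(dataset.n, float(retained.mean()))
            method = "intercept-only-fallback"
    probs = np.clip(probs, 1e-12, 1.0)
    weights = 1.0 / probs[retained == 1]
    if len(weights):
        cap = np.quantile(weights, truncation_quantile)
        weights = np.minimum(weights, cap)
    return CensoringWeights(
        probability=pd.Series(probs, index=ids),
        weights=pd.Series(weights, index=ids[retained == 1]),
        truncation_quantile=truncation_quantile,
        metadata={"method": method},
    )


# ---------------------------------------------------------------------------
# Honest T-learner
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class EstimatorSettings:
    n_trees: int = 200
    min_leaf: int = 20
    honest: bool = True
    max_depth: int | None = None


@dataclasses.dataclass
class _HonestTree:
    tree: DecisionTreeRegressor
    leaf_values: dict[int, float]
    fallback: float

    def predict(self, X: np.ndarray) -> np.ndarray:
        leaves = self.tree.apply(X)
        return np.array([self.leaf_values.get(l, self.fallback) for l in leaves])


@dataclasses.dataclass
class CateModel:
    """Fitted arm-specific outcome predictors with estimator metadata."""

    encoder: ColumnEncoder
    arm_models: dict[int, list[_HonestTree]]
    settings: EstimatorSettings
    seed: int
    metadata: dict = dataclasses.field(default_factory=dict)
    training_subject_id: np.ndarray | None = None

    def predict_mu(self, covariates: pd.DataFrame, arm: int) -> np.ndarray:
        X = self.encoder.transform(covariates)
        preds = np.zeros(len(covariates))
        for t in self.arm_models[arm]:
            preds += t.predict(X)
        return preds / len(self.arm_models[arm])


def _fit_honest_ensemble(
    X: np.ndarray,
    y: np.ndarray,
    w: np.ndarray,
    settings: EstimatorSettings,
    rng: np.random.Generator,
) -> list[_HonestTree]:
    n = len(y)
    trees: list[_HonestTree] = []
    for _ in range(settings.n_trees):
        idx = rng.choice(n, size=n, replace=True)
        half = n // 2
        split_idx, est_idx = idx[:half], idx[half:]
        if not settings.honest:
            split_idx = est_idx = idx
        tree = DecisionTreeRegressor(
            min_samples_leaf=settings.min_leaf,
            max_depth=settings.max_depth,
            random_state=int(rng.integers(0, 2**31 - 1)),
        )
        tree.fit(X[split_idx], y[split_idx], sample_weight=w[split_idx])
        leaves = tree.apply(X[est_idx])
        w_est, y_est = w[est_idx], y[est_idx]
        fallback = float(np.average(y_est, weights=w_est))
        leaf_values: dict[int, float] = {}
        for leaf in np.unique(leaves):
            mask = leaves == leaf
            leaf_values[int(leaf)] = float(np.average(y_est[mask], weights=w_est[mask]))
        trees.append(_HonestTree(tree=tree, leaf_values=leaf_values, fallback=fallback))
    return trees


def fit_cate_model(
    dataset: TrialDataset,
    weights: CensoringWeights | None = None,
    settings: EstimatorSettings | None = None,
    seed: int = 0,
) -> CateModel:
    """Fit the honest T-learner on the retained subjects.

    Each arm needs at least ``settings.min_leaf`` retained subjects. All
    randomness (bootstrap draws, tree tie-breaking) flows from ``seed``.
    """
    settings = settings or EstimatorSettings()
    analytic = dataset.retained_subset()
    if analytic.n == 0:
        raise InsufficientDataError("no retained subjects")
    w = (
        weights.for_subjects(analytic.subject_id)
        if weights is not None
        else np.ones(analytic.n)
    )
    if np.isnan(w).any():
        raise ConfigurationError("weights missing for some retained subjects")
    encoder = ColumnEncoder()
    X = encoder.fit_transform(analytic.covariates, analytic.covariate_kinds)
    y = analytic.outcome.to_numpy(dtype=float)
    a = analytic.treatment.to_numpy()
    rng = np.random.default_rng(seed)
    arm_models: dict[int, list[_HonestTree]] = {}
    for arm in (0, 1):
        mask = a == arm
        if mask.sum() < settings.min_leaf:
            raise InsufficientDataError(
                f"arm {arm} has {int(mask.sum())} retained subjects "
                f"(< min_leaf={settings.min_leaf})"
            )
        arm_models[arm] = _fit_honest_ensemble(
            X[mask], y[mask], w[mask], settings, rng
        )
    return CateModel(
        encoder=encoder,
        arm_models=arm_models,
        settings=settings,
        seed=seed,
        metadata={
            "estimator": "honest-t-learner",
            "n_trees": settings.n_trees,
            "min_leaf": settings.min_leaf,
            "honest": settings.honest,
            "seed": seed,
        },
        training_subject_id=analytic.subject_id.astype(str).to_numpy(),
    )


def predict_effects(model: CateModel, covariates: pd.DataFrame,
                    subject_id=None) -> CateEstimate:
    """Predict tau_hat = mu1_hat - mu0_hat for each row of ``covariates``."""
    mu0 = np.clip(model.predict_mu(covariates, 0), 0.0, 1.0)
    mu1 = np.clip(model.predict_mu(covariates, 1), 0.0, 1.0)
    if subject_id is None:
        subject_id = covariates.index.astype(str).to_numpy()
    return CateEstimate.from_arrays(
        subject_id=subject_id,
        tau=mu1 - mu0,
        mu0=mu0,
        mu1=mu1,
        provenance="model",
        metadata=dict(model.metadata),
    )


def estimate_cate(
    dataset: TrialDataset,
    weights: CensoringWeights | None = None,
    settings: EstimatorSettings | None = None,
    seed: int = 0,
) -> CateEstimate:
    """Fit on the retained subjects and return their in-sample estimates."""
    model = fit_cate_model(dataset, weights=weights, settings=settings, seed=seed)
    analytic = dataset.retained_subset()
    return predict_effects(
        model, analytic.covariates, subject_id=analytic.subject_id.to_numpy()
    )
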