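"""Synthetic two-arm randomized trials with planted effect heterogeneity.

The generator produces a :class:`~pragsub.datasets.TrialDataset` with

* 1:1 (or configurable) randomization independent of covariates,
* a binary reverse-coded outcome drawn directly on the probability scale,
  so planted cell effects are exact risk differences,
* covariate-dependent (MAR) loss to follow-up via a logistic model whose
  intercept is calibrated to hit the requested marginal censoring rate, and
* the planted per-subject effect exposed for oracle checks.

Scenarios
---------
``null``
    No treatment effect anywhere.
``step_subgroups``
    Cells defined by the joint levels of (usually two) binary covariates
    receive distinct constant risk-difference effects.
``continuous_threshold``
    A single continuous covariate splits the population at a threshold into
    a low-effect and a high-effect region.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd
from scipy.optimize import brentq
from scipy.special import expit

from .datasets import TrialDataset
from .exceptions import ConfigurationError, UnsupportedInputError

SCENARIOS = ("null", "step_subgroups", "continuous_threshold")


@dataclasses.dataclass
class CovariateSpec:
    """Marginal distribution of one synthetic covariate."""

    name: str
    kind: str  # continuous | binary | categorical
    mean: float = 0.0
    sd: float = 1.0
    p: float = 0.5  # binary success probability
    levels: tuple[str, ...] = ()
    probs: tuple[float, ...] = ()
    lower: float | None = None  # optional truncation for continuous draws

    def draw(self, n: int, rng: np.random.Generator):
        if self.kind == "continuous":
            x = rng.normal(self.mean, self.sd, size=n)
            if self.lower is not None:
                x = np.maximum(x, self.lower)
            return x
        if self.kind == "binary":
            return rng.binomial(1, self.p, size=n).astype(float)
        if self.kind == "categorical":
            probs = self.probs or tuple(1.0 / len(self.levels) for _ in self.levels)
            draws = rng.choice(len(self.levels), size=n, p=np.asarray(probs) / np.sum(probs))
            return pd.Categorical.from_codes(draws, categories=list(self.levels))
        raise ConfigurationError(f"unknown covariate kind {self.kind!r}")


@dataclasses.dataclass
class SimulationConfig:
    """Parameters of one simulated trial."""

    n_subjects: int
    covariates: list[CovariateSpec]
    treatment_probability: float = 0.5
    scenario: str = "null"
    cell_covariates: tuple[str, ...] = ()
    cell_effects: dict[str, float] = dataclasses.field(default_factory=dict)
    threshold_covariate: str | None = None
    threshold: float = 0.0
    effect_below: float = 0.0
    effect_above: float = 0.0
    baseline_risk: float = 0.13
    censoring_rate: float = 0.0
    censoring_coefficients: dict[str, float] = dataclasses.field(default_factory=dict)
    seed: int = 0

    @property
    def n_covariates(self) -> int:
        return len(self.covariates)

    def validate(self) -> None:
        if self.n_subjects < 0:
            raise ConfigurationError("n_subjects must be non-negative")
        if not 0 < self.treatment_probability < 1:
            raise ConfigurationError("treatment_probability must lie in (0, 1)")
        if not 0 <= self.baseline_risk <= 1:
            raise ConfigurationError("baseline_risk must be a probability")
        if not 0 <= self.censoring_rate <= 0.5:
            raise ConfigurationError("censoring_rate must lie in [0, 0.5]")
        if self.scenario not in SCENARIOS:
            raise ConfigurationError(f"unknown scenario {self.scenario!r}")
        names = [c.name for c in self.covariates]
        if len(set(names)) != len(names):
            raise ConfigurationError("duplicate covariate names")
        p0 = 1.0 - self.baseline_risk
        effects: dict[str, float] = {}
        if self.scenario == "step_subgroups":
            if not self.cell_covariates or not self.cell_effects:
                raise ConfigurationError(
                    "step_subgroups requires cell_covariates and cell_effects"
                )
            effects = dict(self.cell_effects)
        elif self.scenario == "continuous_threshold":
            if self.threshold_covariate is None:
                raise ConfigurationError(
                    "continuous_threshold requires threshold_covariate"
                )
            effects = {"below": self.effect_below, "above": self.effect_above}
        for cell, eff in effects.items():
            if not -1 <= eff <= 1:
                raise ConfigurationError(f"cell {cell!r}: effect outside [-1, 1]")
            if not 0 <= p0 + eff <= 1:
                raise ConfigurationError(
                    f"cell {cell!r}: baseline risk {self.baseline_risk} plus effect "
                    f"{eff} puts the event probability outside [0, 1]"
                )

    @property
    def covariate_kinds(self) -> dict[str, str]:
        return {c.name: c.kind for c in self.covariates}


def _cell_key(values) -> str:
    return ",".join(str(int(v)) for v in values)


def planted_effects(config: SimulationConfig, covariates: pd.DataFrame) -> np.ndarray:
    """Planted per-subject risk difference for the configured scenario."""
    n = len(covariates)
    if config.scenario == "null":
        return np.zeros(n)
    if config.scenario == "step_subgroups":
        tau = np.zeros(n)
        cols = [covariates[c].to_numpy(dtype=float) for c in config.cell_covariates]
        keys = [_cell_key(vals) for vals in zip(*cols)] if n else []
        for i, key in enumerate(keys):
            tau[i] = config.cell_effects.get(key, 0.0)
        return tau
    x = covariates[config.threshold_covariate].to_numpy(dtype=float)
    return np.where(x >= config.threshold, config.effect_above, config.effect_below)


def _calibrated_retention(
    config: SimulationConfig,
    covariates: pd.DataFrame,
    treatment: np.ndarray,
    rng: np.random.Generator,
) -> np.ndarray:
    """Draw retention indicators with the marginal censoring rate calibrated."""
    n = len(treatment)
    if config.censoring_rate <= 0 or n == 0:
        return np.ones(n, dtype=int)
    lp = np.zeros(n)
    for name, coef in config.censoring_coefficients.items():
        if name == "treatment":
            lp += coef * treatment
            continue
        col = covariates[name]
        if isinstance(col.dtype, pd.CategoricalDtype):
            x = col.cat.codes.to_numpy(dtype=float)
        else:
            x = col.to_numpy(dtype=float)
        sd = x.std()
        if sd > 0 and not set(np.unique(x)).issubset({0.0, 1.0}):
            x = (x - x.mean()) / sd
        lp += coef * x

    def gap(intercept: float) -> float:
        return expit(intercept + lp).mean() - config.censoring_rate

    intercept = brentq(gap, -40.0, 40.0)
    p_censor = expit(intercept + lp)
    return (rng.random(n) >= p_censor).astype(int)


def simulate_trial(config: SimulationConfig) -> TrialDataset:
    """Generate a trial dataset with the planted heterogeneity structure."""
    config.validate()
    rng = np.random.default_rng(config.seed)
    n = config.n_subjects
    width = max(len(str(max(n, 1))), 1)
    cov = pd.DataFrame(
        {spec.name: spec.draw(n, rng) for spec in config.covariates},
        index=range(n),
    )
    tau = planted_effects(config, cov)
    p0 = 1.0 - config.baseline_risk
    treatment = rng.binomial(1, config.treatment_probability, size=n)
    p_outcome = np.where(treatment == 1, p0 + tau, p0)
    outcome = (rng.random(n) < p_outcome).astype(float)
    retained = _calibrated_retention(config, cov, treatment, rng)
    outcome = np.where(retained == 1, outcome, np.nan)

    frame = pd.DataFrame(
        {
            "subject_id": [f"S{i:0{width}d}" for i in range(n)],
            "treatment": treatment.astype("int64"),
            "outcome": outcome,
            "retained": retained.astype("int64"),
        }
    )
    frame = pd.concat([frame, cov], axis=1)
    return TrialDataset(
        frame=frame,
        covariate_kinds=config.covariate_kinds,
        oracle_effect=pd.Series(tau, name="oracle_effect"),
        oracle_control_risk=p0,
    )


def oracle_cate(dataset: TrialDataset):
    """Planted per-subject effect as a :class:`~pragsub.estimation.CateEstimate`.

    Exposes the exact risk difference the generator used, together with the
    arm-specific event-free probabilities, so the oracle can stand in for a
    fitted model anywhere downstream.
    """
    from .estimation import CateEstimate  # local import to avoid a cycle

    if dataset.oracle_effect is None:
        raise UnsupportedInputError(
            "dataset carries no oracle annotations (not produced by simulate_trial)"
        )
    tau = dataset.oracle_effect.to_numpy(dtype=float)
    mu0 = None
    mu1 = None
    if dataset.oracle_control_risk is not None:
        mu0 = np.full(dataset.n, float(dataset.oracle_control_risk))
        mu1 = mu0 + tau
    return CateEstimate.from_arrays(
        subject_id=dataset.subject_id.to_numpy(),
        tau=tau,
        mu0=mu0,
        mu1=mu1,
        provenance="oracle",
    )


# ---------------------------------------------------------------------------
# Default "Look AHEAD"-like roster: 47 mixed-type covariates whose names match
# the shipped recoding ruleset, with a planted 4-cell effect structure on two
# binary history covariates.
# ---------------------------------------------------------------------------

DEFAULT_CELL_EFFECTS = {"1,1": -0.10, "1,0": 0.00, "0,1": 0.03, "0,0": 0.08}


def lookahead_like_covariates() -> list[CovariateSpec]:
    """Roster of 30 continuous, 12 binary and 5 categorical covariates."""
    c = CovariateSpec
    continuous = [
        c("age", "continuous", mean=59.0, sd=6.8),
        c("bmi", "continuous", mean=36.0, sd=5.9, lower=15.0),
        c("alcohol_oz_week", "continuous", mean=1.0, sd=2.5, lower=0.0),
        c("fasting_glucose", "continuous", mean=153.0, sd=45.0, lower=40.0),
        c("hba1c", "continuous", mean=7.3, sd=1.2, lower=4.0),
        c("hdl_cholesterol", "continuous", mean=43.5, sd=11.9, lower=10.0),
        c("ldl_cholesterol", "continuous", mean=112.0, sd=32.0, lower=20.0),
        c("triglycerides", "continuous", mean=180.0, sd=110.0, lower=30.0),
        c("urine_albumin", "continuous", mean=3.0, sd=8.0, lower=0.0),
        c("urine_creatinine", "continuous", mean=120.0, sd=60.0, lower=5.0),
        c("urine_acr", "continuous", mean=30.0, sd=80.0, lower=0.0),
        c("systolic_bp", "continuous", mean=129.0, sd=17.0, lower=70.0),
        c("sf36_general_health", "continuous", mean=48.0, sd=9.0),
        c("sf36_mental_health", "continuous", mean=53.0, sd=8.5),
        c("sf36_bodily_pain", "continuous", mean=49.0, sd=9.5),
        c("sf36_physical_functioning", "continuous", mean=46.0, sd=9.0),
        c("sf36_role_emotional", "continuous", mean=50.0, sd=9.0),
        c("sf36_role_physical", "continuous", mean=48.0, sd=9.5),
        c("sf36_social_functioning", "continuous", mean=51.0, sd=9.0),
        c("sf36_vitality", "continuous", mean=50.0, sd=9.5),
        c("sf36_transition", "continuous", mean=3.0, sd=1.0),
        c("sf36_mcs", "continuous", mean=54.0, sd=8.0),
        c("sf36_pcs", "continuous", mean=45.0, sd=8.5),
        c("beck_score", "continuous", mean=8.0, sd=7.0, lower=0.0),
        c("diastolic_bp", "continuous", mean=70.0, sd=9.5, lower=40.0),
        c("weight_kg", "continuous", mean=101.0, sd=19.0, lower=45.0),
        c("waist_cm", "continuous", mean=114.0, sd=14.0, lower=60.0),
        c("resting_heart_rate", "continuous", mean=72.0, sd=10.0, lower=40.0),
        c("diabetes_duration_years", "continuous", mean=6.8, sd=6.5, lower=0.0),
        c("serum_creatinine", "continuous", mean=0.9, sd=0.25, lower=0.3),
    ]
    binary = [
        c("female", "binary", p=0.58),
        c("history_cvd", "binary", p=0.14),
        c("history_mi", "binary", p=0.35),
        c("current_smoker", "binary", p=0.04),
        c("insulin_use", "binary", p=0.16),
        c("statin_use", "binary", p=0.45),
        c("metformin_use", "binary", p=0.62),
        c("antihypertensive_use", "binary", p=0.72),
        c("history_stroke", "binary", p=0.03),
        c("history_angina", "binary", p=0.05),
        c("family_history_cvd", "binary", p=0.40),
        c("retinopathy", "binary", p=0.08),
    ]
    categorical = [
        c("race_ethnicity", "categorical",
          levels=("white", "black", "hispanic", "other"),
          probs=(0.63, 0.16, 0.13, 0.08)),
        c("education", "categorical",
          levels=("high_school_or_less", "some_college", "college", "postgraduate"),
          probs=(0.2, 0.3, 0.3, 0.2)),
        c("income", "categorical",
          levels=("low", "middle", "high", "not_reported"),
          probs=(0.25, 0.4, 0.25, 0.1)),
        c("marital_status", "categorical",
          levels=("married", "single", "widowed_divorced"),
          probs=(0.65, 0.12, 0.23)),
        c("clinic_region", "categorical",
          levels=("northeast", "south", "midwest", "west"),
          probs=(0.25, 0.3, 0.2, 0.25)),
    ]
    return continuous + binary + categorical


def lookahead_like_config(
    n_subjects: int = 4600,
    scenario: str = "step_subgroups",
    seed: int = 0,
    censoring_rate: float = 0.062,
    cell_effects: dict[str, float] | None = None,
) -> SimulationConfig:
    """Default trial configuration mirroring the target study's shape.

    ~4,600 subjects, 47 mixed-type covariates, 1:1 randomization, 13% 7-year
    event rate and ~6% covariate-dependent loss to follow-up; the planted
    heterogeneity lives on the (history_cvd, history_mi) cells.
    """
    return SimulationConfig(
        n_subjects=n_subjects,
        covariates=lookahead_like_covariates(),
        treatment_probability=0.5,
        scenario=scenario,
        cell_covariates=("history_cvd", "history_mi"),
        cell_effects=dict(DEFAULT_CELL_EFFECTS if cell_effects is None else cell_effects),
        threshold_covariate="hba1c",
        threshold=7.0,
        effect_below=0.06,
        effect_above=-0.02,
        baseline_risk=0.13,
        censoring_rate=censoring_rate,
        censoring_coefficients={
            "treatment": -0.3,
            "age": 0.4,
            "history_cvd": 0.8,
            "beck_score": 0.3,
        },
        seed=seed,
    )
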