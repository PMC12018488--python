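import numpy as np
import pandas as pd
import pytest

from pragsub.datasets import TrialDataset
from pragsub.synthesis import CovariateSpec, SimulationConfig

CELL_EFFECTS = {"1,1": -0.10, "1,0": 0.00, "0,1": 0.03, "0,0": 0.08}
WIDE_CELL_EFFECTS = {"1,1": -0.20, "1,0": -0.05, "0,1": 0.05, "0,0": 0.13}


def two_binary_roster(extra: bool = True) -> list[CovariateSpec]:
    """Two balanced binary cell covariates plus a few distractors."""
    roster = [
        CovariateSpec("c1", "binary", p=0.5),
        CovariateSpec("c2", "binary", p=0.5),
    ]
    if extra:
        roster += [
            CovariateSpec("x_cont", "continuous", mean=0.0, sd=1.0),
            CovariateSpec("x_bin", "binary", p=0.3),
            CovariateSpec(
                "x_cat", "categorical", levels=("a", "b", "c"), probs=(0.5, 0.3, 0.2)
            ),
        ]
    return roster


def cell_config(
    n: int,
    seed: int,
    cell_effects: dict | None = None,
    censoring_rate: float = 0.0,
    censoring_coefficients: dict | None = None,
    extra: bool = True,
) -> SimulationConfig:
    """Small planted 4-cell scenario used throughout the tests."""
    return SimulationConfig(
        n_subjects=n,
        covariates=two_binary_roster(extra=extra),
        scenario="step_subgroups",
        cell_covariates=("c1", "c2"),
        cell_effects=dict(CELL_EFFECTS if cell_effects is None else cell_effects),
        baseline_risk=0.13,
        censoring_rate=censoring_rate,
        censoring_coefficients=censoring_coefficients or {},
        seed=seed,
    )


def null_config(n: int, seed: int, **kwargs) -> SimulationConfig:
    return SimulationConfig(
        n_subjects=n,
        covariates=two_binary_roster(),
        scenario="null",
        baseline_risk=0.13,
        seed=seed,
        **kwargs,
    )


def tiny_dataset(a, y, tau=None, retained=None, **covs) -> TrialDataset:
    """Hand-built dataset for worked examples."""
    n = len(a)
    frame = pd.DataFrame(
        {
            "subject_id": [f"s{i}" for i in range(n)],
            "treatment": np.asarray(a, dtype="int64"),
            "outcome": np.asarray(y, dtype=float),
            "retained": np.ones(n, dtype="int64") if retained is None
            else np.asarray(retained, dtype="int64"),
        }
    )
    kinds = {}
    for name, values in covs.items():
        frame[name] = values
        kinds[name] = "binary" if set(np.unique(values)) <= {0, 1} else "continuous"
    oracle = None if tau is None else pd.Series(np.asarray(tau, dtype=float))
    if retained is not None:
        frame.loc[frame["retained"] == 0, "outcome"] = np.nan
    return TrialDataset(frame=frame, covariate_kinds=kinds, oracle_effect=oracle)


@pytest.fixture(scope="session")
def small_trial():
    from pragsub.synthesis import simulate_trial

    return simulate_trial(cell_config(800, seed=11))


@pytest.fixture(scope="session")
def lookahead_trial():
    from pragsub.synthesis import lookahead_like_config, simulate_trial

    return simulate_trial(lookahead_like_config(n_subjects=1200, seed=7))
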