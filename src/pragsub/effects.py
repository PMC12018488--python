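"""Subgroup-specific treatment effects via augmented inverse probability weighting.

Each retained subject gets an AIPW influence value built from the
arm-specific outcome predictions and the (known or supplied) treatment
propensity; group effects are censoring-weighted means of those values with
normal-approximation confidence intervals, reported in percentage points.
Positive values mean benefit because the outcome is reverse-coded
(1 = event-free).
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import TrialDataset
from .estimation import CateEstimate, CensoringWeights
from .exceptions import ConfigurationError, UnsupportedInputError

Z_95 = 1.959963984540054


@dataclasses.dataclass
class GroupEffect:
    group: object
    n: int
    rd_pp: float
    se_pp: float
    ci_lower: float
    ci_upper: float
    flagged: bool = False


def aipw_scores(
    dataset: TrialDataset,
    estimate: CateEstimate,
    propensity: float = 0.5,
    weights: CensoringWeights | None = None,
) -> pd.DataFrame:
    """Per-subject AIPW influence values on the retained subjects.

    psi_i = mu1 - mu0 + A (Y - mu1) / e - (1 - A)(Y - mu0) / (1 - e),
    carrying each subject's IPCW weight for downstream aggregation.
    """
    if not 0 < propensity < 1:
        raise ConfigurationError("propensity must lie strictly in (0, 1)")
    analytic = dataset.retained_subset()
    est = estimate.aligned_to(analytic.subject_id.to_numpy())
    if not est.has_arm_predictions:
        raise UnsupportedInputError(
            "estimate lacks arm predictions (mu0_hat/mu1_hat) required for AIPW"
        )
    mu0 = est.table["mu0_hat"].to_numpy(dtype=float)
    mu1 = est.table["mu1_hat"].to_numpy(dtype=float)
    y = analytic.outcome.to_numpy(dtype=float)
    a = analytic.treatment.to_numpy(dtype=float)
    psi = (
        mu1 - mu0
        + a * (y - mu1) / propensity
        - (1.0 - a) * (y - mu0) / (1.0 - propensity)
    )
    w = (
        weights.for_subjects(analytic.subject_id)
        if weights is not None
        else np.ones(analytic.n)
    )
    return pd.DataFrame(
        {
            "subject_id": analytic.subject_id.astype(str).to_numpy(),
            "psi": psi,
            "weight": w,
        }
    )


def _one_row(group, psi: np.ndarray, w: np.ndarray) -> GroupEffect:
    n = len(psi)
    wsum = w.sum()
    point = float(np.average(psi, weights=w))
    if n < 2:
        return GroupEffect(group, n, point * 100, float("nan"),
                           float("nan"), float("nan"), flagged=True)
    var = float(np.average((psi - point) ** 2, weights=w))
    n_eff = wsum**2 / np.sum(w**2)
    se = np.sqrt(var / n_eff)
    return GroupEffect(
        group=group,
        n=n,
        rd_pp=point * 100,
        se_pp=se * 100,
        ci_lower=(point - Z_95 * se) * 100,
        ci_upper=(point + Z_95 * se) * 100,
    )


def group_ate_table(
    scores: pd.DataFrame,
    groups: pd.Series | np.ndarray,
) -> pd.DataFrame:
    """Risk-difference table (percentage points) per group plus an overall row.

    ``groups`` must align with the rows of ``scores`` (same order or shared
    subject_id index) and partition them.
    """
    psi = scores["psi"].to_numpy(dtype=float)
    w = scores["weight"].to_numpy(dtype=float)
    g = np.asarray(groups)
    if len(g) != len(psi):
        raise UnsupportedInputError("group labels do not align with scores")
    rows = [
        _one_row(label, psi[g == label], w[g == label])
        for label in sorted(pd.unique(g), key=str)
    ]
    rows.append(_one_row("all", psi, w))
    table = pd.DataFrame([dataclasses.asdict(r) for r in rows])
    return table


def format_effects(table: pd.DataFrame) -> pd.DataFrame:
    """Rounded presentation copy (2 decimals, percentage points)."""
    out = table.copy()
    for col in ("rd_pp", "se_pp", "ci_lower", "ci_upper"):
        out[col] = out[col].round(2)
    return out
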