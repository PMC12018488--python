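"""Calibration diagnostics for estimated treatment effects.

Two diagnostics are provided, both computed on retained subjects and
optionally weighted by IPCW weights:

* the Qini curve and coefficient — cumulative weighted uplift in the
  reverse-coded outcome along the descending predicted-effect ranking,
  compared against the straight line a random ordering would trace; and
* C-for-benefit — the concordance probability between predicted and
  observed benefit over rank-matched treated/control pairs, with a
  percentile-bootstrap confidence interval.

A positive Qini coefficient and a C-for-benefit above 0.5 indicate
calibration better than chance.
"""

from __future__ import annotations

import dataclasses

import numpy as np
import pandas as pd

from .datasets import TrialDataset
from .estimation import CateEstimate, CensoringWeights
from .exceptions import DegenerateInputError, UnsupportedInputError


@dataclasses.dataclass
class QiniResult:
    curve: pd.DataFrame  # columns: fraction, uplift (includes the (0, 0) start)
    total_uplift: float  # baseline is the line (0,0) -> (1, total_uplift)
    scale: str = "counts"

    @property
    def baseline(self) -> pd.DataFrame:
        return pd.DataFrame(
            {
                "fraction": self.curve["fraction"],
                "uplift": self.curve["fraction"] * self.total_uplift,
            }
        )


def _ranked_arrays(estimate: CateEstimate, dataset: TrialDataset,
                   weights: CensoringWeights | None):
    analytic = dataset.retained_subset()
    est = estimate.aligned_to(analytic.subject_id.to_numpy())
    tau = est.tau
    y = analytic.outcome.to_numpy(dtype=float)
    a = analytic.treatment.to_numpy()
    w = (
        weights.for_subjects(analytic.subject_id)
        if weights is not None
        else np.ones(analytic.n)
    )
    ids = analytic.subject_id.astype(str).to_numpy()
    return tau, y, a, w, ids


def qini_curve(
    estimate: CateEstimate,
    dataset: TrialDataset,
    weights: CensoringWeights | None = None,
    grid: int | np.ndarray = 100,
    scale: str = "counts",
) -> QiniResult:
    """Cumulative uplift along the descending predicted-effect ranking.

    At a prefix of size k, uplift(k) = sum of weighted treated outcomes minus
    the weighted control outcomes rescaled to the treated weight mass within
    the prefix; prefixes with no control subjects are omitted.
    """
    if scale not in ("counts", "per-subject"):
        raise UnsupportedInputError(f"unknown qini scale {scale!r}")
    tau, y, a, w, ids = _ranked_arrays(estimate, dataset, weights)
    if len(np.unique(a)) < 2:
        raise UnsupportedInputError("qini curve needs subjects in both arms")
    n = len(tau)
    order = np.lexsort((ids, -tau))  # tau descending, ties by subject_id
    y, a, w = y[order], a[order], w[order]

    wy1 = np.cumsum(w * y * (a == 1))
    wy0 = np.cumsum(w * y * (a == 0))
    w1 = np.cumsum(w * (a == 1))
    w0 = np.cumsum(w * (a == 0))

    fractions = (
        np.linspace(1.0 / grid, 1.0, grid) if np.isscalar(grid) else np.asarray(grid)
    )
    ks = np.unique(np.clip(np.floor(fractions * n + 1e-9).astype(int), 0, n))
    ks = ks[ks > 0]
    if ks.size == 0 or ks[-1] != n:
        ks = np.append(ks, n)
    points = [(0.0, 0.0)]
    for k in ks:
        if w0[k - 1] <= 0:
            continue  # no control mass in the prefix; point undefined
        uplift = wy1[k - 1] - wy0[k - 1] * (w1[k - 1] / w0[k - 1])
        points.append((k / n, float(uplift)))
    curve = pd.DataFrame(points, columns=["fraction", "uplift"])
    denom = w.sum() if scale == "per-subject" else 1.0
    curve["uplift"] /= denom
    total = float(curve["uplift"].iloc[-1]) if len(curve) > 1 else 0.0
    return QiniResult(curve=curve, total_uplift=total, scale=scale)


def qini_coefficient(result: QiniResult) -> float:
    """Trapezoidal area between the Qini curve and its random-ordering baseline."""
    if len(result.curve) < 2:
        raise DegenerateInputError("qini curve has fewer than 2 points")
    x = result.curve["fraction"].to_numpy()
    y = result.curve["uplift"].to_numpy()
    area = float(np.trapezoid(y, x))
    baseline_area = result.total_uplift * (x[-1] ** 2) / 2.0
    return area - baseline_area


# ---------------------------------------------------------------------------
# C-for-benefit
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class CforBenefitResult:
    statistic: float
    ci: tuple[float, float] | None
    level: float
    n_boot: int
    seed: int
    pairs: pd.DataFrame  # treated_id, control_id, observed, predicted
    degenerate: bool = False


def _pair(tau_t, y_t, tau_c, y_c):
    """Rank-match treated to controls by predicted effect (descending)."""
    ot = np.argsort(-tau_t, kind="stable")
    oc = np.argsort(-tau_c, kind="stable")
    m = min(len(ot), len(oc))
    ot, oc = ot[:m], oc[:m]
    observed = y_t[ot] - y_c[oc]
    predicted = (tau_t[ot] + tau_c[oc]) / 2.0
    return ot, oc, observed, predicted


def concordance_for_benefit(observed: np.ndarray, predicted: np.ndarray) -> float:
    """Pair-of-pairs concordance with ties in predictions counted 1/2.

    Only pairs with unequal observed benefit are informative; returns NaN if
    there are none.
    """
    levels = np.unique(observed)
    total = 0.0
    concordant = 0.0
    sorted_preds = {lv: np.sort(predicted[observed == lv]) for lv in levels}
    for i, hi in enumerate(levels):
        for lo in levels[:i]:
            p_hi = predicted[observed == hi]
            s_lo = sorted_preds[lo]
            total += len(p_hi) * len(s_lo)
            less = np.searchsorted(s_lo, p_hi, side="left").sum()
            ties = (np.searchsorted(s_lo, p_hi, side="right")
                    - np.searchsorted(s_lo, p_hi, side="left")).sum()
            concordant += less + 0.5 * ties
    if total == 0:
        return float("nan")
    return concordant / total


def c_for_benefit(
    estimate: CateEstimate,
    dataset: TrialDataset,
    n_boot: int = 200,
    level: float = 0.95,
    seed: int = 0,
) -> CforBenefitResult:
    """Concordance between predicted and observed benefit over matched pairs."""
    tau, y, a, _, ids = _ranked_arrays(estimate, dataset, None)
    treated, control = a == 1, a == 0
    if treated.sum() == 0 or control.sum() == 0:
        raise UnsupportedInputError("c-for-benefit needs subjects in both arms")
    tau_t, y_t, id_t = tau[treated], y[treated], ids[treated]
    tau_c, y_c, id_c = tau[control], y[control], ids[control]

    ot, oc, observed, predicted = _pair(tau_t, y_t, tau_c, y_c)
    stat = concordance_for_benefit(observed, predicted)
    degenerate = not np.isfinite(stat)
    pairs = pd.DataFrame(
        {
            "treated_id": id_t[ot],
            "control_id": id_c[oc],
            "observed": observed.astype(int),
            "predicted": predicted,
        }
    )

    ci = None
    if not degenerate and n_boot > 0:
        rng = np.random.default_rng(seed)
        reps = []
        for _ in range(n_boot):
            bt = rng.integers(0, len(tau_t), len(tau_t))
            bc = rng.integers(0, len(tau_c), len(tau_c))
            _, _, obs_b, pred_b = _pair(tau_t[bt], y_t[bt], tau_c[bc], y_c[bc])
            s = concordance_for_benefit(obs_b, pred_b)
            if np.isfinite(s):
                reps.append(s)
        if reps:
            alpha = (1.0 - level) / 2.0
            ci = (
                float(np.quantile(reps, alpha)),
                float(np.quantile(reps, 1.0 - alpha)),
            )
    return CforBenefitResult(
        statistic=float(stat),
        ci=ci,
        level=level,
        n_boot=n_boot,
        seed=seed,
        pairs=pairs,
        degenerate=degenerate,
    )
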