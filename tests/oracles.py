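"""Independent brute-force oracles used to cross-check package computations.

These deliberately re-derive quantities from first principles (enumeration,
direct prefix sums, O(n^2) loops) and must stay independent of the package
implementations they check.
"""

from __future__ import annotations

import itertools

import numpy as np
import pandas as pd


# -- Qini ------------------------------------------------------------------


def brute_qini_points(tau, a, y, w, ids, fractions):
    """Prefix uplifts by direct summation, tau descending with id tie-break."""
    order = sorted(range(len(tau)), key=lambda i: (-tau[i], ids[i]))
    n = len(tau)
    points = [(0.0, 0.0)]
    ks = sorted({min(n, int(np.floor(f * n + 1e-9))) for f in fractions} | {n})
    for k in ks:
        if k == 0:
            continue
        prefix = order[:k]
        w1 = sum(w[i] for i in prefix if a[i] == 1)
        w0 = sum(w[i] for i in prefix if a[i] == 0)
        if w0 <= 0:
            continue
        s1 = sum(w[i] * y[i] for i in prefix if a[i] == 1)
        s0 = sum(w[i] * y[i] for i in prefix if a[i] == 0)
        points.append((k / n, s1 - s0 * (w1 / w0)))
    return points


def brute_qini_coefficient(points):
    xs = [p[0] for p in points]
    ys = [p[1] for p in points]
    area = sum(
        (xs[i + 1] - xs[i]) * (ys[i + 1] + ys[i]) / 2 for i in range(len(xs) - 1)
    )
    total = ys[-1]
    return area - total * xs[-1] ** 2 / 2


# -- C-for-benefit ---------------------------------------------------------


def brute_concordance(observed, predicted):
    """O(P^2) pair-of-pairs concordance, ties counted one half."""
    total = 0.0
    conc = 0.0
    for i in range(len(observed)):
        for j in range(len(observed)):
            if observed[i] <= observed[j]:
                continue
            total += 1
            if predicted[i] > predicted[j]:
                conc += 1
            elif predicted[i] == predicted[j]:
                conc += 0.5
    return conc / total if total else float("nan")


# -- CART split ------------------------------------------------------------


def _sse(values, weights):
    if weights.sum() <= 0:
        return 0.0
    m = np.average(values, weights=weights)
    return float(np.sum(weights * (values - m) ** 2))


def brute_best_split(tau, covariates: pd.DataFrame, weights, min_leaf):
    """Exhaustive scan over all admissible single splits of every covariate.

    Tie-breaking mirrors the documented convention: largest reduction, then
    lexicographically smallest variable, then lowest threshold / smallest
    left level-set. Returns (variable, left_mask, reduction) or None.
    """
    tau = np.asarray(tau, dtype=float)
    weights = np.asarray(weights, dtype=float)
    total = _sse(tau, weights)
    best = None  # (reduction, variable, key, mask)
    for name in sorted(covariates.columns):
        col = covariates[name]
        candidates = []
        if isinstance(col.dtype, pd.CategoricalDtype) and not col.cat.ordered:
            levels = list(col.cat.categories)
            as_str = col.astype(str).to_numpy()
            for r in range(1, len(levels)):
                for subset in itertools.combinations(levels, r):
                    mask = np.isin(as_str, [str(s) for s in subset])
                    candidates.append((tuple(sorted(map(str, subset))), mask))
        else:
            if isinstance(col.dtype, pd.CategoricalDtype):
                vals = col.cat.codes.to_numpy(dtype=float)
            else:
                vals = col.to_numpy(dtype=float)
            for cut in np.unique(vals)[:-1]:
                candidates.append((float(cut), vals <= cut))
        for key, mask in candidates:
            nl, nr = int(mask.sum()), int((~mask).sum())
            if nl < min_leaf or nr < min_leaf:
                continue
            red = total - _sse(tau[mask], weights[mask]) - _sse(tau[~mask], weights[~mask])
            if red <= 1e-12:
                continue
            entry = (red, name, key, mask)
            if best is None or red > best[0] + 1e-12:
                best = entry
            elif abs(red - best[0]) <= 1e-12 and name == best[1] and key < best[2]:
                best = entry
    return best


# -- AIPW ------------------------------------------------------------------


def brute_aipw(y, a, mu0, mu1, e):
    out = []
    for i in range(len(y)):
        psi = mu1[i] - mu0[i]
        if a[i] == 1:
            psi += (y[i] - mu1[i]) / e
        else:
            psi -= (y[i] - mu0[i]) / (1 - e)
        out.append(psi)
    return np.asarray(out)
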