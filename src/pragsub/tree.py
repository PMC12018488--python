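"""Depth-limited CART over interpretable covariates for subgroup discovery.

The tree regresses per-subject estimated treatment effects on the recoded
interpretable covariates with squared-error impurity, greedy recursive
binary splitting, and fully deterministic tie-breaking (largest weighted SSE
reduction, then lexicographically smallest variable name, then lowest
threshold). Leaves are the discovered subgroups, labeled 1..G in ascending
mean estimated effect so group 1 is the lowest-benefit subgroup.

Ordinal columns (numeric, binary, and the ordered categoricals produced by
recoding) split only at between-level thresholds so rules read as natural
inequalities; unordered categoricals split on level subsets found by the
exact mean-ordering scan.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .estimation import CateEstimate
from .exceptions import ConfigurationError, SchemaMismatchError, UnsupportedInputError


# ---------------------------------------------------------------------------
# Column views: map a mixed-type column to split-ready numeric values
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class _ColumnView:
    name: str
    kind: str  # "ordinal" | "nominal"
    values: np.ndarray  # float codes used for splitting
    levels: list | None = None  # category labels (ordinal-categorical / nominal)
    ordered_categorical: bool = False


def _column_view(name: str, col: pd.Series) -> _ColumnView:
    if isinstance(col.dtype, pd.CategoricalDtype):
        codes = col.cat.codes.to_numpy(dtype=float)
        if (codes < 0).any():
            raise UnsupportedInputError(
                f"column {name!r} has missing values; impute before tree fitting"
            )
        levels = list(col.cat.categories)
        if col.cat.ordered:
            return _ColumnView(name, "ordinal", codes, levels, ordered_categorical=True)
        return _ColumnView(name, "nominal", codes, levels)
    if col.dtype == object:
        cat = pd.Categorical(col.astype(str))
        return _ColumnView(
            name, "nominal", cat.codes.astype(float), list(cat.categories)
        )
    vals = col.to_numpy(dtype=float)
    if np.isnan(vals).any():
        raise UnsupportedInputError(
            f"column {name!r} has missing values; impute before tree fitting"
        )
    return _ColumnView(name, "ordinal", vals)


# ---------------------------------------------------------------------------
# Split search
# ---------------------------------------------------------------------------


@dataclasses.dataclass(frozen=True)
class SplitRule:
    """One if-then split; the left child is where the condition holds."""

    variable: str
    kind: str  # "ordinal-threshold" | "level-subset"
    threshold: float | None = None
    left_levels: tuple | None = None
    levels: tuple | None = None  # full level order (categorical variables)
    ordered_categorical: bool = False

    def goes_left(self, col: pd.Series) -> tuple[np.ndarray, np.ndarray]:
        """Boolean routing mask plus a mask of unseen-level rows (sent right)."""
        if self.kind == "ordinal-threshold":
            if isinstance(col.dtype, pd.CategoricalDtype):
                codes = pd.Categorical(
                    col.astype(str), categories=[str(l) for l in self.levels]
                ).codes.astype(float)
                unseen = codes < 0
                return (codes <= self.threshold) & ~unseen, unseen
            vals = col.to_numpy(dtype=float)
            return vals <= self.threshold, np.zeros(len(col), dtype=bool)
        left_set = {str(l) for l in self.left_levels}
        known = {str(l) for l in self.levels}
        as_str = col.astype(str).to_numpy()
        unseen = ~np.isin(as_str, list(known))
        return np.isin(as_str, list(left_set)) & ~unseen, unseen

    def describe(self, left: bool) -> str:
        if self.kind == "level-subset":
            levels = self.left_levels if left else tuple(
                l for l in self.levels if l not in self.left_levels
            )
            inner = ", ".join(str(l) for l in levels)
            return f"{self.variable} in {{{inner}}}"
        if self.levels is not None:  # ordered categorical: name the boundary level
            k = int(np.floor(self.threshold))
            if left:
                return f"{self.variable} ≤ '{self.levels[k]}'"
            return f"{self.variable} ≥ '{self.levels[k + 1]}'"
        op = "≤" if left else ">"
        return f"{self.variable} {op} {self.threshold:g}"


_NO_SPLIT = (None, 0.0)


def _sse(wy: float, wyy: float, w: float) -> float:
    return wyy - wy * wy / w if w > 0 else 0.0


def _best_ordinal_threshold(values, tau, weights, min_leaf):
    """Scan all between-level thresholds; returns (threshold, reduction)."""
    order = np.argsort(values, kind="stable")
    v, y, w = values[order], tau[order], weights[order]
    n = len(v)
    cw = np.cumsum(w)
    cwy = np.cumsum(w * y)
    cwyy = np.cumsum(w * y * y)
    total_sse = _sse(cwy[-1], cwyy[-1], cw[-1])
    # candidate cut positions: last index of each distinct value except the max
    change = np.nonzero(np.diff(v) > 0)[0]
    best = _NO_SPLIT
    for pos in change:
        n_left = pos + 1
        if n_left < min_leaf or n - n_left < min_leaf:
            continue
        left = _sse(cwy[pos], cwyy[pos], cw[pos])
        right = _sse(cwy[-1] - cwy[pos], cwyy[-1] - cwyy[pos], cw[-1] - cw[pos])
        reduction = total_sse - left - right
        threshold = (v[pos] + v[pos + 1]) / 2.0
        if reduction > best[1] + 1e-12 or (
            best[0] is not None
            and abs(reduction - best[1]) <= 1e-12
            and threshold < best[0]
        ):
            best = (threshold, reduction)
    return best


def best_split(
    tau: np.ndarray,
    column: pd.Series,
    weights: np.ndarray | None = None,
    min_leaf: int = 1,
) -> tuple[SplitRule | None, float]:
    """Best binary split of one covariate by weighted SSE reduction.

    Returns ``(None, 0.0)`` when no admissible split improves the fit.
    """
    tau = np.asarray(tau, dtype=float)
    weights = np.ones(len(tau)) if weights is None else np.asarray(weights, float)
    view = _column_view(column.name or "x", column)
    if view.kind == "ordinal":
        threshold, reduction = _best_ordinal_threshold(
            view.values, tau, weights, min_leaf
        )
        if threshold is None:
            return None, 0.0
        rule = SplitRule(
            variable=view.name,
            kind="ordinal-threshold",
            threshold=float(threshold),
            levels=tuple(view.levels) if view.levels is not None else None,
            ordered_categorical=view.ordered_categorical,
        )
        return rule, float(reduction)

    left_levels, reduction = _best_level_subset(view, tau, weights, min_leaf)
    if left_levels is None:
        return None, 0.0
    rule = SplitRule(
        variable=view.name,
        kind="level-subset",
        left_levels=left_levels,
        levels=tuple(view.levels),
    )
    return rule, float(reduction)


_MAX_EXACT_LEVELS = 15


def _best_level_subset(view: _ColumnView, tau, weights, min_leaf):
    """Best level subset of an unordered categorical.

    Exact subset enumeration for up to ``_MAX_EXACT_LEVELS`` levels (the
    mean-ordering shortcut is exact only without the min-leaf constraint);
    beyond that, falls back to scanning thresholds on the mean ordering.
    """
    codes = view.values.astype(int)
    n_levels = len(view.levels)
    sums = np.bincount(codes, weights=weights * tau, minlength=n_levels)
    sq = np.bincount(codes, weights=weights * tau * tau, minlength=n_levels)
    wsum = np.bincount(codes, weights=weights, minlength=n_levels)
    counts = np.bincount(codes, minlength=n_levels)
    total_sse = _sse(sums.sum(), sq.sum(), wsum.sum())
    n = len(codes)

    def evaluate(mask: np.ndarray):
        n_left = counts[mask].sum()
        if n_left < min_leaf or n - n_left < min_leaf:
            return None
        left = _sse(sums[mask].sum(), sq[mask].sum(), wsum[mask].sum())
        right = _sse(sums[~mask].sum(), sq[~mask].sum(), wsum[~mask].sum())
        return total_sse - left - right

    best_levels, best_red = None, 0.0
    if n_levels <= _MAX_EXACT_LEVELS:
        # enumerate subsets excluding the last level (complement symmetry),
        # in lexicographic bitmask order for deterministic tie-breaking
        for bits in range(1, 2 ** (n_levels - 1)):
            mask = np.array(
                [(bits >> j) & 1 == 1 for j in range(n_levels)], dtype=bool
            )
            red = evaluate(mask)
            if red is not None and red > best_red + 1e-12:
                best_red = red
                best_levels = tuple(
                    view.levels[j] for j in range(n_levels) if mask[j]
                )
    else:
        means = np.where(wsum > 0, sums / np.maximum(wsum, 1e-300), np.inf)
        order = np.lexsort((np.array(view.levels, dtype=object), means))
        for k in range(1, n_levels):
            mask = np.zeros(n_levels, dtype=bool)
            mask[order[:k]] = True
            red = evaluate(mask)
            if red is not None and red > best_red + 1e-12:
                best_red = red
                best_levels = tuple(
                    view.levels[j] for j in range(n_levels) if mask[j]
                )
    return best_levels, best_red


# ---------------------------------------------------------------------------
# Tree
# ---------------------------------------------------------------------------


@dataclasses.dataclass
class TreeNode:
    depth: int
    n: int
    mean: float
    sse: float
    rule: SplitRule | None = None
    left: "TreeNode | None" = None
    right: "TreeNode | None" = None
    group: int | None = None  # leaf only, 1..G ascending mean tau
    member_ids: np.ndarray | None = None

    @property
    def is_leaf(self) -> bool:
        return self.rule is None


@dataclasses.dataclass
class SubgroupTree:
    root: TreeNode
    max_depth: int
    min_leaf: int
    columns: list[str]

    def leaves(self) -> list[TreeNode]:
        out: list[TreeNode] = []

        def walk(node: TreeNode) -> None:
            if node.is_leaf:
                out.append(node)
            else:
                walk(node.left)
                walk(node.right)

        walk(self.root)
        return sorted(out, key=lambda l: l.group)

    def leaf_conditions(self) -> dict[int, list[tuple[SplitRule, bool]]]:
        """Per group: the (rule, went_left) path from root to leaf."""
        out: dict[int, list[tuple[SplitRule, bool]]] = {}

        def walk(node: TreeNode, path) -> None:
            if node.is_leaf:
                out[node.group] = list(path)
                return
            walk(node.left, path + [(node.rule, True)])
            walk(node.right, path + [(node.rule, False)])

        walk(self.root, [])
        return out


def _weighted_stats(tau, weights):
    w = weights.sum()
    mean = float(np.average(tau, weights=weights)) if w > 0 else 0.0
    sse = float(np.sum(weights * (tau - mean) ** 2))
    return mean, sse


def fit_tree(
    estimate: CateEstimate | np.ndarray,
    covariates: pd.DataFrame,
    max_depth: int = 2,
    min_leaf: int = 50,
    weights: np.ndarray | None = None,
) -> SubgroupTree:
    """Greedy depth-limited CART of estimated effects on interpretable covariates.

    ``covariates`` must be indexed by subject id (or share row order with the
    estimate). Leaves are numbered 1..G by ascending mean estimated effect.
    """
    if covariates.shape[1] == 0:
        raise ConfigurationError("no interpretable covariates supplied")
    if isinstance(estimate, CateEstimate):
        est = estimate.aligned_to(covariates.index.astype(str).to_numpy())
        tau = est.tau
    else:
        tau = np.asarray(estimate, dtype=float)
        if len(tau) != len(covariates):
            raise UnsupportedInputError("effects and covariates differ in length")
    weights = np.ones(len(tau)) if weights is None else np.asarray(weights, float)
    ids = covariates.index.astype(str).to_numpy()
    columns = sorted(covariates.columns)

    def build(idx: np.ndarray, depth: int) -> TreeNode:
        t, w = tau[idx], weights[idx]
        mean, sse = _weighted_stats(t, w)
        node = TreeNode(depth=depth, n=len(idx), mean=mean, sse=sse,
                        member_ids=ids[idx])
        if depth >= max_depth or len(idx) < 2 * min_leaf:
            return node
        best_rule, best_reduction, best_var = None, 0.0, None
        for name in columns:  # lexicographic variable order breaks ties
            rule, reduction = best_split(
                t, covariates[name].iloc[idx], weights=w, min_leaf=min_leaf
            )
            if rule is not None and reduction > best_reduction + 1e-12:
                best_rule, best_reduction, best_var = rule, reduction, name
        if best_rule is None:
            return node
        go_left, _ = best_rule.goes_left(covariates[best_var].iloc[idx])
        node.rule = best_rule
        node.left = build(idx[go_left], depth + 1)
        node.right = build(idx[~go_left], depth + 1)
        node.member_ids = None
        return node

    root = build(np.arange(len(tau)), 0)

    leaves: list[TreeNode] = []

    def collect(node: TreeNode) -> None:
        if node.is_leaf:
            leaves.append(node)
        else:
            collect(node.left)
            collect(node.right)

    collect(root)
    order = sorted(
        range(len(leaves)),
        key=lambda i: (leaves[i].mean, str(leaves[i].member_ids[0])
                       if len(leaves[i].member_ids) else ""),
    )
    for g, i in enumerate(order, start=1):
        leaves[i].group = g
    return SubgroupTree(root=root, max_depth=max_depth, min_leaf=min_leaf,
                        columns=list(covariates.columns))


@dataclasses.dataclass
class RoutingReport:
    unseen: list[tuple[str, str]]  # (variable, unseen level), routed right


def assign_groups(
    tree: SubgroupTree, covariates: pd.DataFrame
) -> tuple[pd.Series, RoutingReport]:
    """Route every row to its leaf; returns group labels plus a routing report."""
    missing = [c for c in tree.columns if c not in covariates.columns]
    extra = [c for c in covariates.columns if c not in tree.columns]
    if missing or extra:
        raise SchemaMismatchError(missing=missing, extra=extra)
    labels = np.zeros(len(covariates), dtype=int)
    report = RoutingReport(unseen=[])

    def route(node: TreeNode, idx: np.ndarray) -> None:
        if len(idx) == 0:
            return
        if node.is_leaf:
            labels[idx] = node.group
            return
        col = covariates[node.rule.variable].iloc[idx]
        go_left, unseen = node.rule.goes_left(col)
        if unseen.any():
            for lvl in sorted(set(col.astype(str).to_numpy()[unseen])):
                report.unseen.append((node.rule.variable, lvl))
        route(node.left, idx[go_left])
        route(node.right, idx[~go_left])

    route(tree.root, np.arange(len(covariates)))
    return pd.Series(labels, index=covariates.index, name="group"), report


def rules_text(tree: SubgroupTree) -> pd.DataFrame:
    """One row per subgroup: id, rule conjunction, size, mean effect."""
    rows = []
    for leaf in tree.leaves():
        conditions = tree.leaf_conditions()[leaf.group]
        if conditions:
            rule = " AND ".join(r.describe(left) for r, left in conditions)
        else:
            rule = "all subjects"
        rows.append(
            {"group": leaf.group, "rule": rule, "n": leaf.n,
             "mean_tau": leaf.mean}
        )
    return pd.DataFrame(rows)


def format_rules(tree: SubgroupTree) -> str:
    table = rules_text(tree)
    lines = ["Discovered subgroups (ascending benefit):"]
    for _, row in table.iterrows():
        lines.append(
            f"  group {row['group']}: {row['rule']}  "
            f"(n={row['n']}, mean CATE={row['mean_tau']:+.4f})"
        )
    return "\n".join(lines) + "\n"


# ---------------------------------------------------------------------------
# JSON round-trip
# ---------------------------------------------------------------------------


def _rule_to_dict(rule: SplitRule | None):
    if rule is None:
        return None
    return {
        "variable": rule.variable,
        "kind": rule.kind,
        "threshold": rule.threshold,
        "left_levels": list(rule.left_levels) if rule.left_levels else None,
        "levels": [str(l) for l in rule.levels] if rule.levels else None,
        "ordered_categorical": rule.ordered_categorical,
    }


def _rule_from_dict(d):
    if d is None:
        return None
    return SplitRule(
        variable=d["variable"],
        kind=d["kind"],
        threshold=d["threshold"],
        left_levels=tuple(d["left_levels"]) if d["left_levels"] else None,
        levels=tuple(d["levels"]) if d["levels"] else None,
        ordered_categorical=d.get("ordered_categorical", False),
    )


def _node_to_dict(node: TreeNode):
    return {
        "depth": node.depth,
        "n": node.n,
        "mean": node.mean,
        "sse": node.sse,
        "group": node.group,
        "rule": _rule_to_dict(node.rule),
        "left": _node_to_dict(node.left) if node.left else None,
        "right": _node_to_dict(node.right) if node.right else None,
    }


def _node_from_dict(d):
    return TreeNode(
        depth=d["depth"],
        n=d["n"],
        mean=d["mean"],
        sse=d["sse"],
        group=d["group"],
        rule=_rule_from_dict(d["rule"]),
        left=_node_from_dict(d["left"]) if d["left"] else None,
        right=_node_from_dict(d["right"]) if d["right"] else None,
    )


def write_tree(tree: SubgroupTree, path: str | Path) -> Path:
    path = Path(path)
    payload = {
        "max_depth": tree.max_depth,
        "min_leaf": tree.min_leaf,
        "columns": tree.columns,
        "root": _node_to_dict(tree.root),
        "rules": rules_text(tree).to_dict(orient="records"),
    }
    path.write_text(json.dumps(payload, indent=2, ensure_ascii=False))
    return path


def read_tree(path: str | Path) -> SubgroupTree:
    payload = json.loads(Path(path).read_text())
    return SubgroupTree(
        root=_node_from_dict(payload["root"]),
        max_depth=payload["max_depth"],
        min_leaf=payload["min_leaf"],
        columns=payload["columns"],
    )
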