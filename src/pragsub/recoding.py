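"""Declarative recoding of raw covariates into interpretable covariates.

Subgroup rules are only actionable when they are phrased on categories an
audience already uses (guideline cutpoints, yes/no history flags), so this
module converts each raw covariate according to a small declarative rule:
``keep`` it as-is, ``categorize`` it at fixed cutpoints into an ordered
categorical, or ``remove`` it from the interpretable set entirely.

Categorization uses left-closed / right-open intervals on the stated
cutpoints: ``(-inf, c1), [c1, c2), ..., [ck, inf)``, which makes the
categories an exact partition of the reals.
"""

from __future__ import annotations

import dataclasses
import importlib.resources
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .datasets import TrialDataset
from .exceptions import ValidationError

ACTIONS = ("keep", "categorize", "remove")
DEFAULT_RULESET_RESOURCE = "table2_lookahead.yaml"


@dataclasses.dataclass(frozen=True)
class RecodingRule:
    variable: str
    action: str
    cutpoints: tuple[float, ...] = ()
    labels: tuple[str, ...] = ()

    def validate(self) -> None:
        if self.action not in ACTIONS:
            raise ValidationError(
                f"rule for {self.variable!r}: unknown action {self.action!r}"
            )
        if self.action == "categorize":
            if not self.cutpoints:
                raise ValidationError(
                    f"rule for {self.variable!r}: categorize requires cutpoints"
                )
            cuts = np.asarray(self.cutpoints, dtype=float)
            if not np.all(np.diff(cuts) > 0):
                raise ValidationError(
                    f"rule for {self.variable!r}: cutpoints must be strictly increasing"
                )
            if len(self.labels) != len(self.cutpoints) + 1:
                raise ValidationError(
                    f"rule for {self.variable!r}: need {len(self.cutpoints) + 1} "
                    f"labels, got {len(self.labels)}"
                )
            if len(set(self.labels)) != len(self.labels):
                raise ValidationError(
                    f"rule for {self.variable!r}: labels must be unique"
                )
        elif self.cutpoints or self.labels:
            raise ValidationError(
                f"rule for {self.variable!r}: action {self.action!r} takes no "
                "cutpoints or labels"
            )


@dataclasses.dataclass(frozen=True)
class RecodingRuleSet:
    rules: tuple[RecodingRule, ...]
    unlisted_policy: str = "keep"

    def validate(self) -> None:
        if self.unlisted_policy not in ("keep", "error"):
            raise ValidationError(
                f"unknown unlisted_policy {self.unlisted_policy!r}"
            )
        seen: set[str] = set()
        for rule in self.rules:
            rule.validate()
            if rule.variable in seen:
                raise ValidationError(f"variable {rule.variable!r} appears in two rules")
            seen.add(rule.variable)

    def rule_for(self, variable: str) -> RecodingRule | None:
        for rule in self.rules:
            if rule.variable == variable:
                return rule
        return None


def _parse_ruleset(payload: dict) -> RecodingRuleSet:
    rules = []
    for variable, spec in (payload.get("rules") or {}).items():
        spec = spec or {}
        rules.append(
            RecodingRule(
                variable=str(variable),
                action=spec.get("action", "keep"),
                cutpoints=tuple(float(c) for c in spec.get("cutpoints") or ()),
                labels=tuple(str(x) for x in spec.get("labels") or ()),
            )
        )
    ruleset = RecodingRuleSet(
        rules=tuple(rules),
        unlisted_policy=payload.get("unlisted_policy", "keep"),
    )
    ruleset.validate()
    return ruleset


def load_rules(path: str | Path) -> RecodingRuleSet:
    """Load and validate a YAML ruleset file."""
    with open(path) as fh:
        payload = yaml.safe_load(fh) or {}
    return _parse_ruleset(payload)


def default_ruleset() -> RecodingRuleSet:
    """The shipped guideline-cutpoint ruleset for the default covariate roster."""
    resource = importlib.resources.files("pragsub.data") / DEFAULT_RULESET_RESOURCE
    return _parse_ruleset(yaml.safe_load(resource.read_text(encoding="utf-8")))


def default_ruleset_path() -> Path:
    return Path(str(importlib.resources.files("pragsub.data") / DEFAULT_RULESET_RESOURCE))


def _categorize(values: pd.Series, rule: RecodingRule) -> pd.Series:
    cuts = np.asarray(rule.cutpoints, dtype=float)
    x = values.to_numpy(dtype=float)
    codes = np.searchsorted(cuts, x, side="right")  # [c_k, c_{k+1}) -> k
    codes = np.where(np.isnan(x), -1, codes).astype(int)
    return pd.Series(
        pd.Categorical.from_codes(codes, categories=list(rule.labels), ordered=True),
        index=values.index,
        name=values.name,
    )


def apply_recoding(
    data: TrialDataset | pd.DataFrame,
    rules: RecodingRuleSet,
    kinds: dict[str, str] | None = None,
) -> pd.DataFrame:
    """Map a raw covariate table to the interpretable covariate table.

    Accepts either a :class:`TrialDataset` (covariate kinds taken from its
    schema) or a bare DataFrame plus a ``kinds`` mapping.
    """
    rules.validate()
    if isinstance(data, TrialDataset):
        covariates = data.covariates
        kinds = data.covariate_kinds
    else:
        covariates = data
        kinds = kinds or {}
    out: dict[str, pd.Series] = {}
    for col in covariates.columns:
        rule = rules.rule_for(col)
        if rule is None:
            if rules.unlisted_policy == "error":
                raise ValidationError(f"no rule for variable {col!r}")
            out[col] = covariates[col]
            continue
        if rule.action == "remove":
            continue
        if rule.action == "keep":
            out[col] = covariates[col]
            continue
        if kinds.get(col, "continuous") != "continuous":
            raise ValidationError(
                f"categorize rule targets non-continuous covariate {col!r}"
            )
        out[col] = _categorize(covariates[col], rule)
    return pd.DataFrame(out, index=covariates.index)


@dataclasses.dataclass
class RuleValidationReport:
    missing_variables: list[str]
    empty_categories: list[tuple[str, str]]
    removed_variables: list[str]

    @property
    def is_clean(self) -> bool:
        return not self.missing_variables and not self.empty_categories


def validate_rules(rules: RecodingRuleSet, dataset: TrialDataset) -> RuleValidationReport:
    """Report rules that reference absent variables or produce empty categories."""
    rules.validate()
    missing: list[str] = []
    empty: list[tuple[str, str]] = []
    removed: list[str] = []
    for rule in rules.rules:
        if rule.variable not in dataset.frame.columns:
            missing.append(rule.variable)
            continue
        if rule.action == "remove":
            removed.append(rule.variable)
        elif rule.action == "categorize":
            recoded = _categorize(dataset.frame[rule.variable], rule)
            counts = recoded.value_counts()
            for label in rule.labels:
                if counts.get(label, 0) == 0:
                    empty.append((rule.variable, label))
    return RuleValidationReport(missing, empty, removed)
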