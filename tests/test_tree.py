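import numpy as np
import pandas as pd
import pytest

from pragsub.estimation import CateEstimate
from pragsub.exceptions import ConfigurationError, SchemaMismatchError
from pragsub.recoding import apply_recoding, default_ruleset
from pragsub.synthesis import lookahead_like_config, oracle_cate, simulate_trial
from pragsub.tree import (
    assign_groups,
    best_split,
    fit_tree,
    format_rules,
    read_tree,
    rules_text,
    write_tree,
)

from conftest import CELL_EFFECTS, cell_config
from oracles import brute_best_split


def _random_instance(rng, n_covariates):
    n = int(rng.integers(8, 51))
    cols = {}
    for j in range(n_covariates):
        kind = rng.integers(0, 3)
        if kind == 0:
            cols[f"v{j}"] = rng.normal(size=n).round(1)
        elif kind == 1:
            cols[f"v{j}"] = rng.integers(0, 2, n).astype(float)
        else:
            levels = ["a", "b", "c", "d"][: int(rng.integers(2, 5))]
            cols[f"v{j}"] = pd.Categorical(rng.choice(levels, n), categories=levels)
    tau = rng.normal(size=n)
    return tau, pd.DataFrame(cols)


class TestBestSplit:
    def test_six_value_worked_example(self):
        tau = np.array([1.0, 1.0, 2.0, 5.0, 5.0, 6.0])
        x = pd.Series([0, 0, 0, 1, 1, 1], name="x", dtype=float)
        rule, reduction = best_split(tau, x, min_leaf=1)
        assert reduction == pytest.approx(24.0)
        assert rule.variable == "x"
        assert rule.threshold == pytest.approx(0.5)

    def test_constant_tau_no_split(self):
        tau = np.full(20, 0.3)
        x = pd.Series(np.arange(20.0), name="x")
        rule, reduction = best_split(tau, x, min_leaf=1)
        assert rule is None and reduction == 0.0

    def test_min_leaf_blocks_split(self):
        tau = np.array([0.0, 0.0, 5.0])
        x = pd.Series([0.0, 0.0, 1.0], name="x")
        rule, _ = best_split(tau, x, min_leaf=2)
        assert rule is None

    def test_matches_brute_force_single_covariate(self):
        rng = np.random.default_rng(10)
        for _ in range(100):
            tau, cov = _random_instance(rng, 1)
            min_leaf = int(rng.integers(1, 5))
            rule, reduction = best_split(
                tau, cov.iloc[:, 0], min_leaf=min_leaf
            )
            expected = brute_best_split(tau, cov, np.ones(len(tau)), min_leaf)
            if expected is None:
                assert rule is None
                continue
            assert rule is not None
            assert reduction == pytest.approx(expected[0], abs=1e-8)
            left, _ = rule.goes_left(cov.iloc[:, 0])
            # same partition; left/right orientation is immaterial
            assert (left == expected[3]).all() or (left == ~expected[3]).all()

    def test_weighted_split(self):
        # weights can move the optimum; check against brute force
        rng = np.random.default_rng(11)
        for _ in range(30):
            tau, cov = _random_instance(rng, 1)
            w = rng.uniform(0.2, 3.0, len(tau))
            rule, reduction = best_split(tau, cov.iloc[:, 0], weights=w, min_leaf=2)
            expected = brute_best_split(tau, cov, w, 2)
            if expected is None:
                assert rule is None
            else:
                assert reduction == pytest.approx(expected[0], abs=1e-8)


class TestFitTree:
    def test_recovers_planted_cells(self):
        ds = simulate_trial(cell_config(4000, seed=70))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates[["c1", "c2"]].copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=2, min_leaf=50)
        groups, _ = assign_groups(tree, cov)
        planted = (
            cov["c1"].astype(int).astype(str) + "," + cov["c2"].astype(int).astype(str)
        )
        # leaves == planted cells (as partitions)
        table = pd.crosstab(groups, planted)
        assert (table.gt(0).sum(axis=1) == 1).all()
        assert len(tree.leaves()) == 4
        # group order matches planted effect order (ascending benefit)
        order = [
            planted[groups == g].iloc[0] for g in sorted(groups.unique())
        ]
        effects = [CELL_EFFECTS[key] for key in order]
        assert effects == sorted(effects)

    def test_max_depth_zero_single_leaf(self):
        ds = simulate_trial(cell_config(500, seed=71))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates.copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=0, min_leaf=10)
        leaves = tree.leaves()
        assert len(leaves) == 1
        assert leaves[0].n == analytic.n
        assert leaves[0].mean == pytest.approx(est.aligned_to(cov.index).tau.mean())
        assert rules_text(tree)["rule"].iloc[0] == "all subjects"

    def test_depth_limit_on_rule_length(self):
        ds = simulate_trial(lookahead_like_config(n_subjects=1500, seed=72))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = apply_recoding(analytic, default_ruleset())
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=2, min_leaf=50)
        for rule in rules_text(tree)["rule"]:
            assert rule == "all subjects" or len(rule.split(" AND ")) <= 2

    def test_empty_covariates_rejected(self):
        est = CateEstimate.from_arrays(subject_id=["a", "b"], tau=[0.1, 0.2])
        with pytest.raises(ConfigurationError):
            fit_tree(est, pd.DataFrame(index=["a", "b"]))

    def test_greedy_depth1_equals_brute_force(self):
        rng = np.random.default_rng(12)
        for _ in range(100):
            n_cov = int(rng.integers(1, 5))
            tau, cov = _random_instance(rng, n_cov)
            cov.index = [f"s{i}" for i in range(len(tau))]
            min_leaf = int(rng.integers(1, 4))
            tree = fit_tree(tau, cov, max_depth=1, min_leaf=min_leaf)
            expected = brute_best_split(tau, cov, np.ones(len(tau)), min_leaf)
            if expected is None:
                assert len(tree.leaves()) == 1
                continue
            groups, _ = assign_groups(tree, cov)
            left_ids = set(np.asarray(cov.index)[expected[3]])
            leaf_memberships = {
                frozenset(leaf.member_ids) for leaf in tree.leaves()
            }
            assert frozenset(left_ids) in leaf_memberships

    def test_stable_under_row_permutation(self):
        ds = simulate_trial(cell_config(1000, seed=73))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates.copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree1 = fit_tree(est, cov, max_depth=2, min_leaf=30)
        rng = np.random.default_rng(0)
        perm = rng.permutation(len(cov))
        tree2 = fit_tree(est, cov.iloc[perm], max_depth=2, min_leaf=30)
        t1 = rules_text(tree1)
        t2 = rules_text(tree2)
        pd.testing.assert_frame_equal(t1, t2)
        g1, _ = assign_groups(tree1, cov)
        g2, _ = assign_groups(tree2, cov)
        assert (g1 == g2).all()

    def test_unit_weights_match_unweighted(self):
        ds = simulate_trial(cell_config(800, seed=74))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates.copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        t1 = fit_tree(est, cov, max_depth=2, min_leaf=30)
        t2 = fit_tree(est, cov, max_depth=2, min_leaf=30,
                      weights=np.ones(analytic.n))
        pd.testing.assert_frame_equal(rules_text(t1), rules_text(t2))


class TestAssignGroups:
    def _fitted(self, seed=75, n=800):
        ds = simulate_trial(cell_config(n, seed=seed))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates.copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=2, min_leaf=30)
        return tree, cov

    def test_replay_matches_fit_membership(self):
        tree, cov = self._fitted()
        groups, report = assign_groups(tree, cov)
        assert not report.unseen
        for leaf in tree.leaves():
            assert set(groups.index[groups == leaf.group]) == set(leaf.member_ids)

    def test_partition_sizes_sum_to_n(self):
        tree, cov = self._fitted(seed=76)
        groups, _ = assign_groups(tree, cov)
        assert groups.value_counts().sum() == len(cov)
        assert sum(l.n for l in tree.leaves()) == len(cov)

    def test_schema_mismatch_rejected(self):
        tree, cov = self._fitted(seed=77)
        with pytest.raises(SchemaMismatchError):
            assign_groups(tree, cov.drop(columns=[cov.columns[0]]))

    def test_unseen_level_routed_and_flagged(self):
        rng = np.random.default_rng(13)
        n = 200
        cov = pd.DataFrame(
            {"cat": pd.Categorical(rng.choice(["a", "b"], n), categories=["a", "b"])},
            index=[f"s{i}" for i in range(n)],
        )
        tau = np.where(cov["cat"] == "a", 1.0, -1.0) + rng.normal(0, 0.01, n)
        tree = fit_tree(tau, cov, max_depth=1, min_leaf=10)
        new = cov.copy()
        new["cat"] = pd.Categorical(
            ["z"] * 3 + list(cov["cat"][3:].astype(str)), categories=["a", "b", "z"]
        )
        groups, report = assign_groups(tree, new)
        assert ("cat", "z") in report.unseen
        assert set(groups.unique()) <= {1, 2}


class TestRulesText:
    def test_rules_reproduce_routing(self):
        ds = simulate_trial(cell_config(1200, seed=78))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates.copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=2, min_leaf=30)
        groups, _ = assign_groups(tree, cov)
        # evaluate each leaf's path conditions directly against the data
        for group, conditions in tree.leaf_conditions().items():
            mask = np.ones(len(cov), dtype=bool)
            for rule, went_left in conditions:
                left, _ = rule.goes_left(cov[rule.variable])
                mask &= left if went_left else ~left
            np.testing.assert_array_equal(mask, (groups == group).to_numpy())

    def test_four_leaf_table_shape(self):
        ds = simulate_trial(cell_config(4000, seed=79))
        analytic = ds.retained_subset()
        est = oracle_cate(ds)
        cov = analytic.covariates[["c1", "c2"]].copy()
        cov.index = analytic.subject_id.astype(str).to_numpy()
        tree = fit_tree(est, cov, max_depth=2, min_leaf=50)
        table = rules_text(tree)
        assert len(table) == 4
        assert (table["group"] == [1, 2, 3, 4]).all()
        assert table["mean_tau"].is_monotonic_increasing
        for rule in table["rule"]:
            assert len(rule.split(" AND ")) == 2
        assert "group 1" in format_rules(tree)

    def test_json_round_trip(self, tmp_path):
        tree, cov = TestAssignGroups()._fitted(seed=80)
        path = write_tree(tree, tmp_path / "tree.json")
        back = read_tree(path)
        g1, _ = assign_groups(tree, cov)
        g2, _ = assign_groups(back, cov)
        assert (g1 == g2).all()
        pd.testing.assert_frame_equal(rules_text(tree), rules_text(back))
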