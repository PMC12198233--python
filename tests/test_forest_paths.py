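"""Forest extraction, depth tables, path enumeration/merging, case convention."""

import numpy as np
import pandas as pd
import pytest

from cpforest.benchmark import make_forest
from cpforest.cohort import default_cohort_spec, generate_cohort
from cpforest.forest import (
    CanonicalPath,
    ForestStructure,
    HighLeafRule,
    PathStep,
    RawPath,
    attach_precisions,
    depth_frequency,
    enumerate_high_paths,
    extract_forest,
    merge_paths,
    parse_rendered,
    path_precision,
    path_table,
    render_signature,
    signature_of,
)
from cpforest.preprocess import GroupLabeling, assign_outcome_groups

from conftest import leaf, random_extracted_forest, split


# --- independent brute-force oracle over sklearn tree arrays ---------------


def brute_force_high_paths(sk_forest, feature_names, high_cut):
    """Enumerate high-leaf paths straight from sklearn's node arrays,
    independently of the package's ExtractedTree walk."""
    paths = []
    for t_idx, est in enumerate(sk_forest.estimators_):
        t = est.tree_
        stack = [(0, [])]
        while stack:
            nid, steps = stack.pop()
            if t.children_left[nid] == -1:
                value = float(t.value[nid].ravel()[0])
                if value >= high_cut:
                    samples = int(round(t.weighted_n_node_samples[nid]))
                    paths.append((tuple(steps), value, samples, t_idx))
                continue
            var = feature_names[int(t.feature[nid])]
            thr = float(t.threshold[nid])
            stack.append((int(t.children_right[nid]), steps + [(var, "gt", thr)]))
            stack.append((int(t.children_left[nid]), steps + [(var, "le", thr)]))
    return paths


def brute_force_merge(paths):
    """Signature -> (count, per-step threshold means), via plain dicts."""
    groups = {}
    for steps, _value, _samples, _t in paths:
        sig = tuple((v, d) for v, d, _ in steps)
        groups.setdefault(sig, []).append([thr for _, _, thr in steps])
    return {
        sig: (len(members), np.mean(members, axis=0))
        for sig, members in groups.items()
    }


def _fit_small_forest(seed, n_trees=8, depth=3, n=150, n_features=6):
    rng = np.random.default_rng(seed)
    X = pd.DataFrame(
        rng.uniform(1, 5, size=(n, n_features)),
        columns=[f"V{i}.1" for i in range(n_features)],
    )
    y = X.iloc[:, 0] * 0.4 + rng.normal(0, 0.5, n) + 1
    model = make_forest(
        {"n_estimators": n_trees, "max_depth": depth, "criterion": "squared_error"},
        "A",
        seed=seed,
    )
    model.fit(X, y)
    return model, X, y


class TestExtraction:
    def test_smallest_case_one_stump(self):
        rng = np.random.default_rng(0)
        X = pd.DataFrame({"X": rng.uniform(1, 5, 50), "Y": rng.uniform(1, 5, 50)})
        y = (X["X"] > 3).astype(float) + 1
        model = make_forest(
            {"n_estimators": 1, "max_depth": 1, "criterion": "squared_error",
             "bootstrap": False},
            "A", seed=0,
        )
        model.fit(X, y)
        fs = extract_forest(model, X.columns)
        assert len(fs.trees) == 1
        nodes = fs.trees[0].nodes
        assert sum(not n.is_leaf for n in nodes) == 1
        assert sum(n.is_leaf for n in nodes) == 2

    def test_round_trip_predictions_per_tree(self):
        model, X, _ = _fit_small_forest(seed=5)
        fs = extract_forest(model, X.columns)
        probe = pd.DataFrame(
            np.random.default_rng(1).uniform(1, 5, size=(100, X.shape[1])),
            columns=X.columns,
        )
        for est, tree in zip(model.estimators_, fs.trees):
            np.testing.assert_allclose(
                tree.predict(probe), est.predict(probe.to_numpy()), rtol=0, atol=1e-12
            )

    def test_tree_count_matches_configuration(self):
        model, X, _ = _fit_small_forest(seed=2, n_trees=25)
        fs = extract_forest(model, X.columns)
        assert len(fs.trees) == 25

    def test_leaf_sample_conservation(self):
        """Per tree, leaf sample counts sum to the bootstrap draw size."""
        model, X, _ = _fit_small_forest(seed=9)
        fs = extract_forest(model, X.columns)
        for tree in fs.trees:
            assert tree.leaf_sample_total() == len(X)

    def test_unsupported_model_rejected(self):
        from sklearn.linear_model import LinearRegression

        with pytest.raises(Exception, match="unsupported"):
            extract_forest(LinearRegression(), ["a"])

    def test_json_round_trip(self, tmp_path):
        model, X, _ = _fit_small_forest(seed=3)
        fs = extract_forest(model, X.columns)
        path = tmp_path / "forest.json"
        fs.to_json(path)
        back = ForestStructure.from_json(path)
        assert back == fs

    def test_dot_export_mentions_splits(self, depth1_forest):
        dot = depth1_forest.trees[0].to_dot()
        assert dot.startswith("digraph") and "X <= 3.000" in dot


class TestDepthFrequency:
    def test_hand_built_tree_counts(self, make_tree):
        tree = make_tree(
            [
                split(0, "X", 3.0, 1, 2),
                split(1, "Y", 2.0, 3, 4),
                split(2, "Y", 4.0, 5, 6),
                leaf(3, 1.0), leaf(4, 2.0), leaf(5, 1.5), leaf(6, 2.5),
            ]
        )
        fs = ForestStructure(trees=(tree,), feature_names=("X", "Y"))
        table, deeper = depth_frequency(fs)
        assert table.loc["X", 0] == 1
        assert table.loc["Y", 1] == 2
        assert deeper == 0

    def test_root_column_sums_to_tree_count(self):
        fs = random_extracted_forest(np.random.default_rng(4), n_trees=12, depth=4)
        table, _ = depth_frequency(fs)
        assert table[0].sum() == 12

    def test_every_internal_node_counted_once(self):
        fs = random_extracted_forest(np.random.default_rng(8), n_trees=6, depth=4)
        table, deeper = depth_frequency(fs)
        n_internal = sum(
            sum(not n.is_leaf for n in t.nodes) for t in fs.trees
        )
        assert table.to_numpy().sum() + deeper == n_internal

    def test_uniform_roots_dominate_level_zero(self):
        from cpforest.forest import ExtractedTree

        stumps = tuple(
            ExtractedTree(
                nodes=(split(0, "CP.1", 1.5 + 0.01 * i, 1, 2), leaf(1, 1.0), leaf(2, 2.0))
            )
            for i in range(250)
        )
        fs = ForestStructure(trees=stumps, feature_names=("CP.1",))
        table, _ = depth_frequency(fs)
        assert table.loc["CP.1", 0] == 250


class TestHighPathEnumeration:
    def test_no_qualifying_leaf_gives_empty_list(self, depth1_forest):
        assert enumerate_high_paths(depth1_forest, HighLeafRule(9.0)) == []

    def test_single_high_leaf_single_path(self, make_tree):
        tree = make_tree(
            [
                split(0, "X", 3.0, 1, 2),
                split(1, "Y", 2.0, 3, 4),
                leaf(2, 1.0, 4),
                leaf(3, 1.1, 5),
                leaf(4, 2.4, 2),  # the only high leaf
            ]
        )
        fs = ForestStructure(trees=(tree,), feature_names=("X", "Y"))
        paths = enumerate_high_paths(fs, HighLeafRule(2.0))
        assert len(paths) == 1
        (p,) = paths
        assert signature_of(p.steps) == (("X", "le"), ("Y", "gt"))
        assert p.leaf_samples == 2

    def test_matches_brute_force_on_random_forests(self):
        for seed in range(5):
            model, X, _ = _fit_small_forest(seed=seed, n_trees=10, depth=4)
            fs = extract_forest(model, X.columns)
            cut = float(np.quantile(model.predict(X), 0.8))
            mine = enumerate_high_paths(fs, HighLeafRule(cut))
            oracle = brute_force_high_paths(model, list(X.columns), cut)
            assert len(mine) == len(oracle)
            mine_set = {
                (signature_of(p.steps), p.leaf_samples, p.tree_index) for p in mine
            }
            oracle_set = {
                (tuple((v, d) for v, d, _ in s), n, t) for s, _, n, t in oracle
            }
            assert mine_set == oracle_set

    def test_deterministic_enumeration_order(self, make_tree):
        tree = make_tree(
            [
                split(0, "X", 3.0, 1, 2),
                leaf(1, 5.0, 1),
                leaf(2, 5.0, 1),
            ]
        )
        fs = ForestStructure(trees=(tree, tree), feature_names=("X",))
        paths = enumerate_high_paths(fs, HighLeafRule(2.0))
        assert [(p.tree_index, p.steps[0].direction) for p in paths] == [
            (0, "le"), (0, "gt"), (1, "le"), (1, "gt"),
        ]


class TestPathPrecision:
    TABLE = pd.DataFrame(
        {
            "GD.1": [3.0, 3.5, 4.0, 1.0, 1.2, 1.1],
            "CP.2": [2.5, 2.6, 1.0, 1.1, 1.2, 1.3],
        }
    )

    def _labels(self):
        return assign_outcome_groups(self.TABLE["CP.2"].to_numpy())

    def test_manual_row_filtering(self):
        labels = self._labels()
        steps = (PathStep("GD.1", "gt", 2.5),)
        # rows 0,1,2 selected; labels: rows 0,1 high, row 2 low -> 2/3
        assert path_precision(steps, self.TABLE, labels) == pytest.approx(2 / 3)

    def test_empty_condition_gives_base_rate(self):
        labels = self._labels()
        base = path_precision((), self.TABLE, labels)
        assert base == pytest.approx(
            (np.asarray(labels.labels) == "high").mean()
        )

    def test_no_satisfying_rows_flagged_none(self):
        labels = self._labels()
        assert path_precision((PathStep("GD.1", "gt", 99.0),), self.TABLE, labels) is None

    def test_pure_high_selection_is_one(self):
        labels = self._labels()
        steps = (PathStep("GD.1", "gt", 2.5), PathStep("GD.1", "le", 3.6))
        assert path_precision(steps, self.TABLE, labels) == pytest.approx(1.0)


class TestMergePaths:
    def _raw(self, sig_thresholds, leaf_samples=1, precision=None, tree=0):
        steps = tuple(
            PathStep(v, d, thr) for (v, d), thr in sig_thresholds
        )
        return RawPath(
            steps=steps, leaf_value=3.0, leaf_samples=leaf_samples,
            tree_index=tree, precision=precision,
        )

    def test_same_signature_thresholds_averaged(self):
        a = self._raw([(("GD.1", "gt"), 3.0)], leaf_samples=4, precision=0.5)
        b = self._raw([(("GD.1", "gt"), 3.2)], leaf_samples=8, precision=0.7)
        (merged,) = merge_paths([a, b])
        assert merged.occurrence_count == 2
        assert merged.steps[0].threshold == pytest.approx(3.1)
        assert merged.avg_leaf_samples == pytest.approx(6.0)
        assert merged.precision_high == pytest.approx(0.6)

    def test_distinct_signatures_pass_through(self):
        a = self._raw([(("GD.1", "gt"), 3.0)])
        b = self._raw([(("GD.1", "le"), 3.0)])
        merged = merge_paths([a, b])
        assert [m.occurrence_count for m in merged] == [1, 1]
        assert {m.steps[0].threshold for m in merged} == {3.0}

    def test_sorted_by_count_then_signature(self):
        a = self._raw([(("B.1", "le"), 2.0)])
        b = self._raw([(("A.1", "le"), 2.0)])
        c1 = self._raw([(("C.1", "gt"), 2.0)])
        c2 = self._raw([(("C.1", "gt"), 2.4)])
        merged = merge_paths([a, b, c1, c2])
        assert [m.signature[0][0] for m in merged] == ["C.1", "A.1", "B.1"]

    def test_merge_agrees_with_brute_force(self):
        model, X, _ = _fit_small_forest(seed=21, n_trees=12, depth=4)
        fs = extract_forest(model, X.columns)
        cut = float(np.quantile(model.predict(X), 0.7))
        merged = merge_paths(enumerate_high_paths(fs, HighLeafRule(cut)))
        oracle = brute_force_merge(
            brute_force_high_paths(model, list(X.columns), cut)
        )
        assert {m.signature for m in merged} == set(oracle)
        for m in merged:
            count, thr = oracle[m.signature]
            assert m.occurrence_count == count
            np.testing.assert_allclose(
                [s.threshold for s in m.steps], thr, atol=1e-9
            )


class TestCaseConvention:
    def test_worked_rendering_example(self):
        steps = (
            PathStep("TEMP_INHIB.1", "le", 3.34),
            PathStep("GD.1", "gt", 2.07),
            PathStep("LAB_NEG.1", "gt", 2.17),
            PathStep("CONFLICT.1", "gt", 3.57),
            PathStep("TEMP_INHIB.1", "le", 3.07),
            PathStep("EMP_AF.1", "gt", 1.67),
        )
        assert render_signature(steps) == (
            "temp_inhib.1 GD.1 LAB_NEG.1 CONFLICT.1 temp_inhib.1 EMP_AF.1"
        )

    def test_round_trip_recovers_signature(self):
        steps = (
            PathStep("GD.1", "gt", 2.1),
            PathStep("REG.1", "le", 3.7),
            PathStep("GD.1", "le", 3.0),  # repeated variable kept positionally
        )
        assert parse_rendered(render_signature(steps)) == signature_of(steps)

    def test_path_table_layout(self):
        cp = CanonicalPath(
            steps=(PathStep("GD.1", "gt", 2.066), PathStep("CU.1", "le", 1.5)),
            occurrence_count=3,
            avg_leaf_samples=13.0,
            precision_high=1.0,
            avg_leaf_value=2.2,
        )
        tbl = path_table([cp])
        assert tbl.loc[0, "Node 0"] == "GD.1"
        assert tbl.loc[0, "Node 1"] == "cu.1"
        assert tbl.loc[0, "Thr 0"] == pytest.approx(2.07)
        assert tbl.loc[0, "Precision"] == "100.00%"
        assert tbl.loc[0, "Leaf samples"] == pytest.approx(13.0)


class TestPlantedStructureRecovery:
    def test_case_b_forest_recovers_planted_interaction(self, cohort_2000):
        """On the synthetic cohort with the planted GD.1 x CONFLICT.1
        interaction, at least one of the 10 most frequent high-path
        signatures in the Case B forest contains both GD.1(gt) and
        CONFLICT.1(gt)."""
        from cpforest.benchmark import CaseConfig
        from cpforest.preprocess import balance_training_set

        labeling = assign_outcome_groups(cohort_2000["CP.2"].to_numpy())
        case = CaseConfig.case_b(cohort_2000.columns)
        balanced = balance_training_set(cohort_2000, labeling.labels, seed=3)
        model = make_forest(
            {"n_estimators": 60, "max_depth": 6, "min_samples_leaf": 0.001,
             "min_samples_split": 0.001, "criterion": "squared_error"},
            "B", seed=0,
        )
        model.fit(balanced[list(case.predictor_set)], balanced["CP.2"])
        fs = extract_forest(model, case.predictor_set)
        merged = merge_paths(enumerate_high_paths(fs, HighLeafRule(labeling.high_cut)))
        top = merged[:10]
        assert any(
            ("GD.1", "gt") in m.signature and ("CONFLICT.1", "gt") in m.signature
            for m in top
        )
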