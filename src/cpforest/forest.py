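"""Forest structure extraction and decision-path mining.

A fitted random-forest regressor is first copied into a language-neutral
:class:`ForestStructure` (split variable, threshold, children, leaf value,
leaf sample count per node), decoupling the explainability analysis from the
fitting library.  On that structure the module computes the explainability
primitives:

* depth-frequency tables — how often each predictor is the splitting
  variable at each tree level (0 = root);
* enumeration of all root-to-leaf paths whose leaf regresses to a *high*
  outcome (leaf value at or above the frozen high-group cut);
* canonicalization — paths with the same ordered (variable, direction)
  signature are merged, thresholds averaged over occurrences;
* the case-rendering convention: a step whose samples exceed the threshold
  prints the variable in UPPERCASE, a step at/below in lowercase.

Split semantics follow the binary-tree convention: left child receives
samples with value <= threshold, right child those above it.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd

from .preprocess import GroupLabeling

__all__ = [
    "TreeNode",
    "ExtractedTree",
    "ForestStructure",
    "PathStep",
    "RawPath",
    "CanonicalPath",
    "HighLeafRule",
    "ForestExtractionError",
    "extract_forest",
    "depth_frequency",
    "enumerate_high_paths",
    "path_precision",
    "attach_precisions",
    "merge_paths",
    "signature_of",
    "render_signature",
    "parse_rendered",
    "path_table",
]


class ForestExtractionError(ValueError):
    pass


@dataclass(frozen=True)
class TreeNode:
    """One node of an extracted tree; internal nodes split, leaves predict."""

    node_id: int
    split_variable: str | None
    threshold: float | None
    left: int | None
    right: int | None
    leaf_value: float | None
    leaf_samples: int | None

    @property
    def is_leaf(self) -> bool:
        return self.split_variable is None


@dataclass(frozen=True)
class ExtractedTree:
    nodes: tuple[TreeNode, ...]
    root: int = 0

    def predict_row(self, row: dict[str, float]) -> float:
        node = self.nodes[self.root]
        while not node.is_leaf:
            node = self.nodes[node.left if row[node.split_variable] <= node.threshold else node.right]
        return node.leaf_value

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        records = frame.to_dict("records")
        return np.array([self.predict_row(r) for r in records], dtype=float)

    def leaf_sample_total(self) -> int:
        return sum(n.leaf_samples for n in self.nodes if n.is_leaf)

    def to_dot(self, name: str = "tree") -> str:
        """GraphViz DOT rendering of the tree."""
        lines = [f"digraph {name} {{", "  node [shape=box];"]
        for n in self.nodes:
            if n.is_leaf:
                lines.append(
                    f'  n{n.node_id} [label="value={n.leaf_value:.3f}\\n'
                    f'samples={n.leaf_samples}"];'
                )
            else:
                lines.append(
                    f'  n{n.node_id} [label="{n.split_variable} <= {n.threshold:.3f}"];'
                )
                lines.append(f'  n{n.node_id} -> n{n.left} [label="yes"];')
                lines.append(f'  n{n.node_id} -> n{n.right} [label="no"];')
        lines.append("}")
        return "\n".join(lines)


@dataclass(frozen=True)
class ForestStructure:
    trees: tuple[ExtractedTree, ...]
    feature_names: tuple[str, ...]

    def predict(self, frame: pd.DataFrame) -> np.ndarray:
        return np.mean([t.predict(frame) for t in self.trees], axis=0)

    def to_json(self, path=None) -> str:
        payload = {
            "feature_names": list(self.feature_names),
            "trees": [
                [
                    {
                        "id": n.node_id,
                        "var": n.split_variable,
                        "thr": n.threshold,
                        "left": n.left,
                        "right": n.right,
                        "value": n.leaf_value,
                        "samples": n.leaf_samples,
                    }
                    for n in t.nodes
                ]
                for t in self.trees
            ],
        }
        text = json.dumps(payload, indent=1, sort_keys=True)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text)
        return text

    @classmethod
    def from_json(cls, source) -> "ForestStructure":
        if hasattr(source, "read"):
            payload = json.load(source)
        else:
            text = str(source)
            if text.lstrip().startswith("{"):
                payload = json.loads(text)
            else:
                with open(text) as fh:
                    payload = json.load(fh)
        trees = tuple(
            ExtractedTree(
                nodes=tuple(
                    TreeNode(
                        node_id=n["id"],
                        split_variable=n["var"],
                        threshold=n["thr"],
                        left=n["left"],
                        right=n["right"],
                        leaf_value=n["value"],
                        leaf_samples=n["samples"],
                    )
                    for n in tree
                )
            )
            for tree in payload["trees"]
        )
        return cls(trees=trees, feature_names=tuple(payload["feature_names"]))


def extract_forest(fitted_model, feature_names) -> ForestStructure:
    """Lossless structural copy of a fitted scikit-learn tree ensemble.

    Re-evaluating inputs through the returned structure reproduces each
    estimator's predictions exactly (same splits, same leaf values).
    """
    if not hasattr(fitted_model, "estimators_"):
        raise ForestExtractionError(
            f"unsupported model type {type(fitted_model).__name__}: no estimators_"
        )
    feature_names = tuple(feature_names)
    trees = []
    for est in fitted_model.estimators_:
        t = est.tree_
        nodes = []
        for i in range(t.node_count):
            if t.children_left[i] == -1:  # leaf
                nodes.append(
                    TreeNode(
                        node_id=i,
                        split_variable=None,
                        threshold=None,
                        left=None,
                        right=None,
                        # weighted count: with bootstrapping this is the
                        # draw multiplicity, so leaves sum to the draw size
                        leaf_value=float(t.value[i].ravel()[0]),
                        leaf_samples=int(round(t.weighted_n_node_samples[i])),
                    )
                )
            else:
                nodes.append(
                    TreeNode(
                        node_id=i,
                        split_variable=feature_names[int(t.feature[i])],
                        threshold=float(t.threshold[i]),
                        left=int(t.children_left[i]),
                        right=int(t.children_right[i]),
                        leaf_value=None,
                        leaf_samples=None,
                    )
                )
        trees.append(ExtractedTree(nodes=tuple(nodes)))
    return ForestStructure(trees=tuple(trees), feature_names=feature_names)


# ---------------------------------------------------------------------------
# depth-frequency tables


def depth_frequency(
    forest: ForestStructure, max_level: int = 6
) -> tuple[pd.DataFrame, int]:
    """Count splitting variables per tree level over the whole forest.

    Returns (table, n_deeper): the table has one row per variable and one
    column per level 0..max_level-1, sorted by earliest level then count
    descending; internal nodes deeper than the reported range are counted in
    ``n_deeper`` (leaves are never counted).  The level-0 column sums to the
    number of trees.
    """
    if not forest.trees:
        raise ForestExtractionError("empty forest")
    counts: dict[str, np.ndarray] = {}
    n_deeper = 0
    for tree in forest.trees:
        stack = [(tree.root, 0)]
        while stack:
            nid, depth = stack.pop()
            node = tree.nodes[nid]
            if node.is_leaf:
                continue
            if depth < max_level:
                arr = counts.setdefault(node.split_variable, np.zeros(max_level, int))
                arr[depth] += 1
            else:
                n_deeper += 1
            stack.append((node.right, depth + 1))
            stack.append((node.left, depth + 1))
    table = pd.DataFrame(counts).T
    table.columns = list(range(max_level))
    # report order: variables that surface earliest (and most often) first
    order = sorted(
        table.index,
        key=lambda v: tuple(
            (-table.loc[v, d]) for d in range(max_level)
        ),
    )
    return table.loc[order], n_deeper


# ---------------------------------------------------------------------------
# paths


@dataclass(frozen=True)
class PathStep:
    """One decision along a path: variable, branch direction, threshold."""

    variable: str
    direction: str  # 'le' (at/below threshold) or 'gt' (above)
    threshold: float

    def __post_init__(self):
        if self.direction not in ("le", "gt"):
            raise ForestExtractionError(f"bad direction {self.direction!r}")

    def render(self) -> str:
        return self.variable.upper() if self.direction == "gt" else self.variable.lower()

    def satisfied(self, values: np.ndarray) -> np.ndarray:
        return values <= self.threshold if self.direction == "le" else values > self.threshold


@dataclass(frozen=True)
class RawPath:
    """A single root-to-leaf path of one tree ending in a high leaf."""

    steps: tuple[PathStep, ...]
    leaf_value: float
    leaf_samples: int
    tree_index: int
    precision: float | None = None


@dataclass(frozen=True)
class CanonicalPath:
    """Merged paths sharing one ordered (variable, direction) signature."""

    steps: tuple[PathStep, ...]  # thresholds averaged over occurrences
    occurrence_count: int
    avg_leaf_samples: float
    precision_high: float | None
    avg_leaf_value: float

    @property
    def signature(self) -> tuple[tuple[str, str], ...]:
        return signature_of(self.steps)

    @property
    def length(self) -> int:
        return len(self.steps)


@dataclass(frozen=True)
class HighLeafRule:
    """A leaf is 'high' iff its regressed value reaches the frozen high cut."""

    high_cut: float

    def is_high(self, leaf_value: float) -> bool:
        return leaf_value >= self.high_cut


def signature_of(steps) -> tuple[tuple[str, str], ...]:
    return tuple((s.variable, s.direction) for s in steps)


def render_signature(steps) -> str:
    """Tabular case convention: UPPERCASE above threshold, lowercase at/below."""
    return " ".join(s.render() for s in steps)


def parse_rendered(text: str) -> tuple[tuple[str, str], ...]:
    """Invert the case convention back into a (variable, direction) signature.

    Variable identity is case-insensitive; canonical names are uppercase as
    in the cohort header.
    """
    sig = []
    for token in text.split():
        direction = "gt" if token == token.upper() else "le"
        sig.append((token.upper(), direction))
    return tuple(sig)


def enumerate_high_paths(forest: ForestStructure, rule: HighLeafRule) -> list[RawPath]:
    """Depth-first enumeration of every path ending in a high leaf.

    Order is deterministic: tree index, then left-before-right within a tree.
    """
    out: list[RawPath] = []
    for t_idx, tree in enumerate(forest.trees):

        def walk(nid: int, steps: tuple[PathStep, ...]) -> None:
            node = tree.nodes[nid]
            if node.is_leaf:
                if rule.is_high(node.leaf_value):
                    out.append(
                        RawPath(
                            steps=steps,
                            leaf_value=node.leaf_value,
                            leaf_samples=node.leaf_samples,
                            tree_index=t_idx,
                        )
                    )
                return
            walk(nid=node.left, steps=steps + (PathStep(node.split_variable, "le", node.threshold),))
            walk(nid=node.right, steps=steps + (PathStep(node.split_variable, "gt", node.threshold),))

        walk(tree.root, ())
    return out


def path_precision(
    steps, table: pd.DataFrame, labels: GroupLabeling
) -> float | None:
    """Among cohort rows satisfying every step, the fraction truly high.

    Evaluated on the full (unbalanced) analysis sample so that precisions
    are comparable across trees; returns None when no row satisfies the
    path (flagged rather than zeroed).
    """
    mask = np.ones(len(table), dtype=bool)
    for s in steps:
        if s.variable not in table.columns:
            raise ForestExtractionError(f"path references unknown column {s.variable!r}")
        mask &= s.satisfied(table[s.variable].to_numpy(dtype=float))
    if not mask.any():
        return None
    true_labels = np.asarray(labels.labels, dtype=str)
    return float((true_labels[mask] == "high").mean())


def attach_precisions(
    paths: list[RawPath], table: pd.DataFrame, labels: GroupLabeling
) -> list[RawPath]:
    return [
        replace(p, precision=path_precision(p.steps, table, labels)) for p in paths
    ]


def merge_paths(raw_paths: list[RawPath]) -> list[CanonicalPath]:
    """Merge raw paths by signature, averaging thresholds over occurrences.

    Output is sorted by occurrence count descending, ties broken by
    signature lexicographic order.  Member precisions (if attached) are
    averaged, skipping undefined ones.
    """
    groups: dict[tuple, list[RawPath]] = {}
    for p in raw_paths:
        groups.setdefault(signature_of(p.steps), []).append(p)
    merged = []
    for sig, members in groups.items():
        thr = np.mean([[s.threshold for s in m.steps] for m in members], axis=0)
        steps = tuple(
            PathStep(variable=v, direction=d, threshold=float(t))
            for (v, d), t in zip(sig, thr)
        )
        precs = [m.precision for m in members if m.precision is not None]
        merged.append(
            CanonicalPath(
                steps=steps,
                occurrence_count=len(members),
                avg_leaf_samples=float(np.mean([m.leaf_samples for m in members])),
                precision_high=float(np.mean(precs)) if precs else None,
                avg_leaf_value=float(np.mean([m.leaf_value for m in members])),
            )
        )
    merged.sort(key=lambda c: (-c.occurrence_count, c.signature))
    return merged


def path_table(paths: list[CanonicalPath], max_nodes: int = 6) -> pd.DataFrame:
    """Tabular report of canonical paths: one row per path, node columns
    holding the case-rendered variable, threshold columns its averaged cut."""
    rows = []
    for i, p in enumerate(paths):
        row: dict[str, object] = {"Path": i}
        for j in range(max_nodes):
            if j < len(p.steps):
                row[f"Node {j}"] = p.steps[j].render()
                row[f"Thr {j}"] = round(p.steps[j].threshold, 2)
            else:
                row[f"Node {j}"] = ""
                row[f"Thr {j}"] = ""
        row["Count"] = p.occurrence_count
        row["Leaf samples"] = round(p.avg_leaf_samples, 2)
        row["Precision"] = (
            f"{100 * p.precision_high:.2f}%" if p.precision_high is not None else "n/a"
        )
        rows.append(row)
    return pd.DataFrame(rows)
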