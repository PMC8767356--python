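"""Recursive decision-tree induction with the (optionally cost-weighted)
gain-ratio criterion, plus prediction and JSON (de)serialization.

Continuous attributes are split at boundary-point midpoints (midpoints
between consecutive distinct values whose records differ in class);
categorical attributes branch on every observed value. Records equal to a
continuous threshold route to the ``<=`` branch.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import pandas as pd

from .criterion import (
    SPLIT_INFO_GUARD,
    TIE_TOLERANCE,
    ClassDistribution,
    CostMatrix,
    SplitEvaluation,
    WeightVector,
    class_weights,
)
from .data import CATEGORICAL, CONTINUOUS, LabeledDataset
from .exceptions import ConfigError, DomainError, InputError, TreeFormatError

TREE_FORMAT = "fittree.tree"
TREE_VERSION = 1


@dataclass(frozen=True)
class InductionConfig:
    min_samples_to_split: int = 2
    max_depth: Optional[int] = None
    cost_sensitive: bool = False
    tie_tolerance: float = TIE_TOLERANCE

    def __post_init__(self) -> None:
        if self.min_samples_to_split < 2:
            raise ConfigError("min_samples_to_split must be >= 2")
        if self.max_depth is not None and self.max_depth < 1:
            raise ConfigError("max_depth must be >= 1 (or None for unlimited)")


@dataclass(frozen=True)
class SplitTest:
    attribute: str
    kind: str  # "continuous" or "categorical"
    threshold: Optional[float] = None

    def route(self, value) -> str:
        if self.kind == CONTINUOUS:
            return "le" if float(value) <= self.threshold else "gt"
        return str(value)


@dataclass
class LeafNode:
    label: object
    counts: dict  # class label -> raw count at this leaf

    is_leaf = True


@dataclass
class InternalNode:
    test: SplitTest
    children: dict  # branch key -> node
    majority_key: str  # fallback branch for unseen categorical values

    is_leaf = False


def candidate_thresholds(values: Sequence[float], labels: Sequence) -> list[float]:
    """Boundary-point thresholds for one continuous attribute.

    Midpoints between consecutive distinct values are kept only when the two
    value-groups are not both pure with the same class.
    """
    values = np.asarray(values, dtype=float)
    labels = np.asarray(labels, dtype=object)
    if values.shape != labels.shape:
        raise InputError("values and labels must have equal length")
    order = np.argsort(values, kind="mergesort")
    values, labels = values[order], labels[order]
    out: list[float] = []
    # group records by distinct value, tracking a single class or None if mixed
    distinct: list[float] = []
    group_class: list = []
    for v, lab in zip(values, labels):
        if distinct and v == distinct[-1]:
            if group_class[-1] is not _MIXED and group_class[-1] != lab:
                group_class[-1] = _MIXED
        else:
            distinct.append(v)
            group_class.append(lab)
    for k in range(len(distinct) - 1):
        a, b = group_class[k], group_class[k + 1]
        if a is _MIXED or b is _MIXED or a != b:
            out.append((distinct[k] + distinct[k + 1]) / 2.0)
    return out


class _Mixed:
    __slots__ = ()


_MIXED = _Mixed()


def _entropy_rows(rows: np.ndarray) -> np.ndarray:
    """Row-wise entropy in bits of a (k, m) matrix of non-negative masses."""
    totals = rows.sum(axis=1, keepdims=True)
    with np.errstate(divide="ignore", invalid="ignore"):
        p = np.where(totals > 0, rows / totals, 0.0)
        logs = np.where(p > 0, np.log2(np.where(p > 0, p, 1.0)), 0.0)
    return -(p * logs).sum(axis=1)


class _Inducer:
    """Array-backed recursive tree builder over one dataset."""

    def __init__(self, dataset: LabeledDataset, config: InductionConfig, costs: Optional[CostMatrix]):
        if len(dataset) == 0:
            raise DomainError("cannot induce a tree from an empty dataset")
        self.config = config
        self.classes = dataset.classes
        self.m = len(self.classes)
        class_index = {lab: i for i, lab in enumerate(self.classes)}
        self.y = dataset.labels.map(class_index).to_numpy(dtype=np.int64)
        self.attr_order = list(dataset.attributes)
        self.kinds = dict(dataset.attributes)
        self.cont: dict[str, np.ndarray] = {}
        self.cat_codes: dict[str, np.ndarray] = {}
        self.cat_values: dict[str, list] = {}
        for name, kind in dataset.attributes.items():
            col = dataset.frame[name]
            if kind == CONTINUOUS:
                self.cont[name] = col.to_numpy(dtype=float)
            else:
                cats = sorted(map(str, col.unique()))
                code = {v: k for k, v in enumerate(cats)}
                self.cat_codes[name] = col.astype(str).map(code).to_numpy(dtype=np.int64)
                self.cat_values[name] = cats

        base_counts = np.bincount(self.y, minlength=self.m).astype(float)
        dist = ClassDistribution(self.classes, base_counts)
        if config.cost_sensitive:
            if costs is None:
                raise ConfigError("cost_sensitive induction requires a cost matrix")
            # class weights are fixed from the full training distribution
            self.weights = class_weights(costs, dist)
        else:
            self.weights = WeightVector.ones(self.classes)
        self.record_weight = self.weights.values[self.y]

    # -- node-level statistics -------------------------------------------------

    def _node_counts(self, idx: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        raw = np.bincount(self.y[idx], minlength=self.m).astype(float)
        wtd = np.bincount(self.y[idx], weights=self.record_weight[idx], minlength=self.m)
        return raw, wtd

    def _leaf(self, idx: np.ndarray) -> LeafNode:
        raw, wtd = self._node_counts(idx)
        best = int(np.argmax(wtd))  # ties -> first class in sorted order
        counts = {lab: int(raw[i]) for i, lab in enumerate(self.classes) if raw[i] > 0}
        return LeafNode(label=self.classes[best], counts=counts)

    # -- split search ----------------------------------------------------------

    def best_split(self, idx: np.ndarray) -> Optional[SplitEvaluation]:
        raw, wtd = self._node_counts(idx)
        if np.count_nonzero(raw) <= 1:
            return None
        node_entropy = _entropy_rows(wtd[np.newaxis, :])[0]
        tol = self.config.tie_tolerance
        best: Optional[SplitEvaluation] = None
        for name in self.attr_order:
            if self.kinds[name] == CONTINUOUS:
                cand = self._scan_continuous(name, idx, node_entropy)
            else:
                cand = self._scan_categorical(name, idx, node_entropy)
            if cand is None:
                continue
            if best is None or cand.gain_ratio > best.gain_ratio + tol:
                best = cand
        return best

    def _scan_continuous(self, name: str, idx: np.ndarray, node_entropy: float) -> Optional[SplitEvaluation]:
        v = self.cont[name][idx]
        order = np.argsort(v, kind="mergesort")
        vs = v[order]
        ys = self.y[idx][order]
        ws = self.record_weight[idx][order]
        n = len(vs)
        if n < 2 or vs[0] == vs[-1]:
            return None

        # candidate boundary positions: last index of each value-run, kept
        # only when the two flanking runs are not both pure in the same class
        change = np.flatnonzero(vs[1:] > vs[:-1])  # run ends at these indices
        if change.size == 0:
            return None
        run_starts = np.concatenate(([0], change + 1))
        run_ends = np.concatenate((change, [n - 1]))
        run_class = np.full(len(run_starts), -1, dtype=np.int64)  # -1 == mixed
        for r, (a, b) in enumerate(zip(run_starts, run_ends)):
            block = ys[a : b + 1]
            if block.min() == block.max():
                run_class[r] = block[0]
        keep = []
        for r in range(len(run_starts) - 1):
            a, b = run_class[r], run_class[r + 1]
            if a < 0 or b < 0 or a != b:
                keep.append(run_ends[r])
        if not keep:
            return None
        positions = np.asarray(keep, dtype=np.int64)

        onehot_w = np.zeros((n, self.m))
        onehot_w[np.arange(n), ys] = ws
        cum_w = np.cumsum(onehot_w, axis=0)
        total_w = cum_w[-1]

        left_w = cum_w[positions]
        right_w = total_w[np.newaxis, :] - left_w
        left_n = (positions + 1).astype(float)
        right_n = n - left_n

        h_left = _entropy_rows(left_w)
        h_right = _entropy_rows(right_w)
        cond = (left_n / n) * h_left + (right_n / n) * h_right
        gain = node_entropy - cond
        pl = left_n / n
        split_info = -(pl * np.log2(pl) + (1 - pl) * np.log2(1 - pl))

        # zero-gain candidates stay valid (they still shrink every subset, so
        # recursion terminates and XOR-style interactions remain learnable);
        # negative gain can only arise under cost weighting and is rejected
        valid = (gain > -self.config.tie_tolerance) & (split_info > SPLIT_INFO_GUARD)
        if not valid.any():
            return None
        ratio = np.where(valid, gain / np.where(split_info > 0, split_info, 1.0), -np.inf)
        # ties within tolerance resolve to the smallest threshold
        best_ratio = ratio.max()
        k = int(np.flatnonzero(ratio >= best_ratio - self.config.tie_tolerance)[0])
        p = positions[k]
        threshold = float((vs[p] + vs[p + 1]) / 2.0)
        return SplitEvaluation(
            attribute=name,
            threshold=threshold,
            gain=float(gain[k]),
            split_info=float(split_info[k]),
            gain_ratio=float(ratio[k]),
            weighted=self.config.cost_sensitive,
        )

    def _scan_categorical(self, name: str, idx: np.ndarray, node_entropy: float) -> Optional[SplitEvaluation]:
        codes = self.cat_codes[name][idx]
        k = len(self.cat_values[name])
        raw = np.zeros((k, self.m))
        wtd = np.zeros((k, self.m))
        np.add.at(raw, (codes, self.y[idx]), 1.0)
        np.add.at(wtd, (codes, self.y[idx]), self.record_weight[idx])
        sizes = raw.sum(axis=1)
        present = sizes > 0
        if present.sum() < 2:
            return None
        sizes = sizes[present]
        n = sizes.sum()
        weights = sizes / n
        cond = float((weights * _entropy_rows(wtd[present])).sum())
        gain = node_entropy - cond
        split_info = float(-(weights * np.log2(weights)).sum())
        if gain < -self.config.tie_tolerance or split_info <= SPLIT_INFO_GUARD:
            return None
        return SplitEvaluation(
            attribute=name,
            threshold=None,
            gain=gain,
            split_info=split_info,
            gain_ratio=gain / split_info,
            weighted=self.config.cost_sensitive,
        )

    # -- recursion -------------------------------------------------------------

    def build(self) -> "DecisionTree":
        idx = np.arange(len(self.y))
        root = self._grow(idx, depth=0)
        return DecisionTree(
            root=root,
            classes=self.classes,
            attributes=dict(self.kinds),
            cost_sensitive=self.config.cost_sensitive,
            class_weights={lab: float(w) for lab, w in zip(self.classes, self.weights.values)},
            config={
                "min_samples_to_split": self.config.min_samples_to_split,
                "max_depth": self.config.max_depth,
            },
        )

    def _grow(self, idx: np.ndarray, depth: int):
        raw, _ = self._node_counts(idx)
        if (
            np.count_nonzero(raw) <= 1
            or len(idx) < self.config.min_samples_to_split
            or (self.config.max_depth is not None and depth >= self.config.max_depth)
        ):
            return self._leaf(idx)
        split = self.best_split(idx)
        if split is None:
            return self._leaf(idx)
        name = split.attribute
        if self.kinds[name] == CONTINUOUS:
            test = SplitTest(name, CONTINUOUS, split.threshold)
            mask = self.cont[name][idx] <= split.threshold
            groups = {"le": idx[mask], "gt": idx[~mask]}
        else:
            test = SplitTest(name, CATEGORICAL)
            codes = self.cat_codes[name][idx]
            groups = {}
            for code, value in enumerate(self.cat_values[name]):
                sub = idx[codes == code]
                if len(sub):
                    groups[value] = sub
        majority_key = max(groups, key=lambda key: (len(groups[key]), key))
        children = {key: self._grow(sub, depth + 1) for key, sub in groups.items()}
        return InternalNode(test=test, children=children, majority_key=majority_key)


@dataclass
class DecisionTree:
    """A fitted tree: internal nodes carry split tests, leaves carry labels
    and the raw training class counts that reached them."""

    root: object
    classes: tuple
    attributes: dict
    cost_sensitive: bool = False
    class_weights: dict = field(default_factory=dict)
    config: dict = field(default_factory=dict)

    # -- prediction ------------------------------------------------------------

    def predict_record(self, record: Mapping) -> tuple:
        """Route one record to a leaf; returns (label, leaf class counts)."""
        node = self.root
        while not node.is_leaf:
            test = node.test
            if test.attribute not in record:
                raise InputError(f"record lacks tested attribute {test.attribute!r}")
            value = record[test.attribute]
            if value is None or (isinstance(value, float) and math.isnan(value)):
                raise InputError(f"record has missing value for {test.attribute!r}")
            key = test.route(value)
            if key not in node.children:
                # unseen categorical value: fall through to the majority child
                warnings.warn(
                    f"unseen value {value!r} for {test.attribute!r}; routing to majority branch",
                    stacklevel=2,
                )
                key = node.majority_key
            node = node.children[key]
        return node.label, dict(node.counts)

    def predict(self, records: Union[Mapping, pd.DataFrame]):
        """Predict one record (mapping) or every row of a frame (returns Series)."""
        if isinstance(records, pd.DataFrame):
            labels = [self.predict_record(row) [0] for row in records.to_dict("records")]
            return pd.Series(labels, index=records.index, name="prediction")
        return self.predict_record(records)[0]

    def depth(self) -> int:
        def walk(node):
            if node.is_leaf:
                return 0
            return 1 + max(walk(child) for child in node.children.values())

        return walk(self.root)

    def n_leaves(self) -> int:
        def walk(node):
            if node.is_leaf:
                return 1
            return sum(walk(child) for child in node.children.values())

        return walk(self.root)

    def thresholds(self) -> list[tuple[str, float]]:
        """All (attribute, threshold) pairs of continuous tests, in tree order."""
        out: list[tuple[str, float]] = []

        def walk(node):
            if node.is_leaf:
                return
            if node.test.kind == CONTINUOUS:
                out.append((node.test.attribute, node.test.threshold))
            for key in sorted(node.children):
                walk(node.children[key])

        walk(self.root)
        return out

    # -- serialization ---------------------------------------------------------

    def to_dict(self) -> dict:
        def encode(node):
            if node.is_leaf:
                return {
                    "type": "leaf",
                    "label": node.label,
                    "counts": {str(k): v for k, v in sorted(node.counts.items(), key=lambda kv: str(kv[0]))},
                }
            return {
                "type": "split",
                "attribute": node.test.attribute,
                "kind": node.test.kind,
                "threshold": node.test.threshold,
                "majority": node.majority_key,
                "children": {key: encode(child) for key, child in sorted(node.children.items())},
            }

        return {
            "format": TREE_FORMAT,
            "version": TREE_VERSION,
            "classes": list(self.classes),
            "attributes": dict(self.attributes),
            "cost_sensitive": self.cost_sensitive,
            "class_weights": {str(k): v for k, v in sorted(self.class_weights.items(), key=lambda kv: str(kv[0]))},
            "config": self.config,
            "root": encode(self.root),
        }

    def to_json(self) -> str:
        return json.dumps(self.to_dict(), indent=2, sort_keys=True)

    def save(self, path: Union[str, Path]) -> None:
        Path(path).write_text(self.to_json() + "\n")

    @classmethod
    def from_dict(cls, document: Mapping) -> "DecisionTree":
        def fail(path: str, message: str):
            raise TreeFormatError(f"tree document invalid at {path}: {message}")

        if not isinstance(document, Mapping):
            raise TreeFormatError("tree document invalid at $: not a mapping")
        if document.get("format") != TREE_FORMAT:
            fail("$.format", f"expected {TREE_FORMAT!r}")
        if document.get("version") != TREE_VERSION:
            fail("$.version", f"unsupported version {document.get('version')!r}")
        classes = document.get("classes")
        if not isinstance(classes, list) or not classes:
            fail("$.classes", "must be a non-empty list")
        attributes = document.get("attributes")
        if not isinstance(attributes, Mapping):
            fail("$.attributes", "must be a mapping of attribute -> kind")

        def decode(node, path):
            if not isinstance(node, Mapping):
                fail(path, "not a mapping")
            kind = node.get("type")
            if kind == "leaf":
                if "label" not in node:
                    fail(path + ".label", "missing")
                counts = node.get("counts", {})
                if not isinstance(counts, Mapping):
                    fail(path + ".counts", "must be a mapping")
                return LeafNode(label=node["label"], counts=dict(counts))
            if kind == "split":
                attribute = node.get("attribute")
                if attribute not in attributes:
                    fail(path + ".attribute", f"undeclared attribute {attribute!r}")
                test_kind = node.get("kind")
                if test_kind not in (CONTINUOUS, CATEGORICAL):
                    fail(path + ".kind", f"unknown kind {test_kind!r}")
                threshold = node.get("threshold")
                if test_kind == CONTINUOUS and not isinstance(threshold, (int, float)):
                    fail(path + ".threshold", "continuous test requires a numeric threshold")
                children = node.get("children")
                if not isinstance(children, Mapping) or not children:
                    fail(path + ".children", "must be a non-empty mapping")
                if test_kind == CONTINUOUS and set(children) != {"le", "gt"}:
                    fail(path + ".children", "continuous test requires exactly 'le' and 'gt' branches")
                majority = node.get("majority")
                if majority not in children:
                    fail(path + ".majority", "must name one of the children")
                decoded = {
                    key: decode(child, f"{path}.children[{key!r}]") for key, child in children.items()
                }
                return InternalNode(
                    test=SplitTest(attribute, test_kind, threshold if test_kind == CONTINUOUS else None),
                    children=decoded,
                    majority_key=majority,
                )
            fail(path + ".type", f"unknown node type {kind!r}")

        return cls(
            root=decode(document.get("root"), "$.root"),
            classes=tuple(classes),
            attributes=dict(attributes),
            cost_sensitive=bool(document.get("cost_sensitive", False)),
            class_weights=dict(document.get("class_weights", {})),
            config=dict(document.get("config", {})),
        )

    @classmethod
    def from_json(cls, text: str) -> "DecisionTree":
        try:
            document = json.loads(text)
        except json.JSONDecodeError as exc:
            raise TreeFormatError(f"tree document is not valid JSON: {exc}") from None
        return cls.from_dict(document)

    @classmethod
    def load(cls, path: Union[str, Path]) -> "DecisionTree":
        return cls.from_json(Path(path).read_text())


def best_split(
    dataset: LabeledDataset,
    config: InductionConfig = InductionConfig(),
    costs: Optional[CostMatrix] = None,
) -> Optional[SplitEvaluation]:
    """Best (attribute, threshold) by gain ratio at the root; None if no valid candidate."""
    inducer = _Inducer(dataset, config, costs)
    return inducer.best_split(np.arange(len(dataset)))


def build_tree(
    dataset: LabeledDataset,
    config: InductionConfig = InductionConfig(),
    costs: Optional[CostMatrix] = None,
) -> DecisionTree:
    """Grow a tree by recursive partitioning until purity, min_samples,
    max_depth, or criterion exhaustion."""
    return _Inducer(dataset, config, costs).build()
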