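"""Split-criterion mathematics.

Entropy, conditional entropy, information gain, split information and gain
ratio, together with the misclassification-cost machinery that turns the
standard criterion into a cost-sensitive one: per-class row-sum costs
``C(i)``, normalized class weights ``w(i)`` and weight-adjusted class
probabilities.

All entropies are in bits (base-2 logarithms) with the usual convention
``0 * log2(0) = 0``.
"""

from __future__ import annotations

import json
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Optional, Sequence, Union

import numpy as np
import yaml

from .exceptions import (
    ConfigError,
    DegenerateSplitError,
    DomainError,
    PartitionConsistencyError,
)

#: Candidates whose split information falls below this are rejected outright.
SPLIT_INFO_GUARD = 1e-12

#: Two criterion values closer than this are considered tied.
TIE_TOLERANCE = 1e-9


def _entropy(probabilities: np.ndarray) -> float:
    p = probabilities[probabilities > 0]
    if p.size == 0:
        return 0.0
    return float(-(p * np.log2(p)).sum())


@dataclass(frozen=True)
class ClassDistribution:
    """Per-class counts (or weighted masses) over an ordered set of labels."""

    labels: tuple
    counts: np.ndarray

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)
        if len(self.labels) < 1:
            raise DomainError("a class distribution needs at least one class")
        if counts.shape != (len(self.labels),):
            raise DomainError("counts must align one-to-one with labels")
        if np.any(counts < 0):
            raise DomainError("class counts must be non-negative")

    @classmethod
    def from_observations(cls, observed: Sequence, labels: Optional[Sequence] = None) -> "ClassDistribution":
        """Tally observed class labels; class order defaults to sorted unique labels."""
        observed = list(observed)
        if labels is None:
            labels = sorted(set(observed), key=str)
        counts = np.array([sum(1 for o in observed if o == lab) for lab in labels], dtype=float)
        return cls(tuple(labels), counts)

    @property
    def total(self) -> float:
        return float(self.counts.sum())

    @property
    def probabilities(self) -> np.ndarray:
        total = self.total
        if total <= 0:
            raise DomainError("probabilities undefined for an empty distribution")
        return self.counts / total

    @property
    def n_classes(self) -> int:
        return len(self.labels)


@dataclass(frozen=True)
class AttributePartition:
    """A split of a sample set by one attribute into ``v`` subsets.

    ``cell_counts[j, i]`` is the number of records of class ``labels[i]``
    that fall into branch ``j``.
    """

    attribute: str
    labels: tuple
    branches: tuple
    cell_counts: np.ndarray

    def __post_init__(self) -> None:
        cells = np.asarray(self.cell_counts, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "branches", tuple(self.branches))
        object.__setattr__(self, "cell_counts", cells)
        if len(self.branches) < 1:
            raise DomainError("a partition needs at least one branch")
        if cells.shape != (len(self.branches), len(self.labels)):
            raise DomainError("cell_counts must be shaped (branches, classes)")
        if np.any(cells < 0):
            raise DomainError("cell counts must be non-negative")

    @property
    def subset_sizes(self) -> np.ndarray:
        return self.cell_counts.sum(axis=1)

    @property
    def total(self) -> float:
        return float(self.cell_counts.sum())

    @property
    def subset_weights(self) -> np.ndarray:
        """W_j = |S_j| / |S|."""
        total = self.total
        if total <= 0:
            raise DomainError("subset weights undefined for an empty partition")
        return self.subset_sizes / total

    @property
    def class_totals(self) -> np.ndarray:
        return self.cell_counts.sum(axis=0)


@dataclass(frozen=True)
class CostMatrix:
    """Pairwise misclassification costs; ``costs[i, j]`` penalizes predicting
    class ``j`` when the truth is class ``i``. The diagonal is fixed at 0."""

    labels: tuple
    costs: np.ndarray

    def __post_init__(self) -> None:
        costs = np.asarray(self.costs, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "costs", costs)
        m = len(self.labels)
        if costs.shape != (m, m):
            raise ConfigError("cost matrix must be square and aligned with labels")
        if np.any(np.diagonal(costs) != 0):
            raise ConfigError("cost matrix diagonal must be exactly 0")
        if np.any(costs < 0):
            raise ConfigError("misclassification costs must be non-negative")

    @classmethod
    def uniform(cls, labels: Sequence, off_diagonal: float = 1.0) -> "CostMatrix":
        labels = tuple(labels)
        m = len(labels)
        costs = np.full((m, m), float(off_diagonal))
        np.fill_diagonal(costs, 0.0)
        return cls(labels, costs)

    @classmethod
    def from_mapping(
        cls,
        mapping: Mapping,
        labels: Optional[Sequence] = None,
        default_off_diagonal: float = 1.0,
    ) -> "CostMatrix":
        """Build from ``{true_class: {predicted_class: cost}}``.

        Omitted cells default to ``default_off_diagonal`` off the diagonal
        and to 0 on it.
        """
        if labels is None:
            seen: list = []
            for true_lab, row in mapping.items():
                if true_lab not in seen:
                    seen.append(true_lab)
                if not isinstance(row, Mapping):
                    raise ConfigError(f"cost row for {true_lab!r} must be a mapping")
                for pred_lab in row:
                    if pred_lab not in seen:
                        seen.append(pred_lab)
            labels = seen
        labels = tuple(labels)
        index = {lab: k for k, lab in enumerate(labels)}
        m = len(labels)
        costs = np.full((m, m), float(default_off_diagonal))
        np.fill_diagonal(costs, 0.0)
        for true_lab, row in mapping.items():
            if true_lab not in index:
                raise ConfigError(f"unknown class in cost config: {true_lab!r}")
            for pred_lab, cost in row.items():
                if pred_lab not in index:
                    raise ConfigError(f"unknown class in cost config: {pred_lab!r}")
                costs[index[true_lab], index[pred_lab]] = float(cost)
        return cls(labels, costs)

    @classmethod
    def from_file(cls, path: Union[str, Path], labels: Optional[Sequence] = None) -> "CostMatrix":
        path = Path(path)
        text = path.read_text()
        document = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
        if not isinstance(document, Mapping):
            raise ConfigError(f"{path}: cost config must be a mapping of class -> {{class: cost}}")
        return cls.from_mapping(document, labels=labels)

    @property
    def row_costs(self) -> np.ndarray:
        """C(i) = sum_j cost(i, j)."""
        return self.costs.sum(axis=1)

    def row_cost(self, label) -> float:
        try:
            i = self.labels.index(label)
        except ValueError:
            raise ConfigError(f"label {label!r} not covered by the cost matrix") from None
        return float(self.row_costs[i])

    def is_uniform(self, tol: float = 0.0) -> bool:
        off = self.costs[~np.eye(len(self.labels), dtype=bool)]
        if off.size == 0:
            return True
        return bool(np.all(np.abs(off - off[0]) <= tol))

    def aligned_to(self, labels: Sequence) -> "CostMatrix":
        """Reindex rows/columns to a new label order (all must be covered)."""
        try:
            order = [self.labels.index(lab) for lab in labels]
        except ValueError as exc:
            raise ConfigError(f"cost matrix does not cover all classes: {exc}") from None
        return CostMatrix(tuple(labels), self.costs[np.ix_(order, order)])


@dataclass(frozen=True)
class WeightVector:
    """Per-class weights w(i) aligned with an ordered label set."""

    labels: tuple
    values: np.ndarray

    def __post_init__(self) -> None:
        values = np.asarray(self.values, dtype=float)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "values", values)
        if values.shape != (len(self.labels),):
            raise DomainError("weights must align one-to-one with labels")
        if np.any(values < 0):
            raise DomainError("class weights must be non-negative")

    @classmethod
    def ones(cls, labels: Sequence) -> "WeightVector":
        return cls(tuple(labels), np.ones(len(tuple(labels))))


@dataclass(frozen=True)
class SplitEvaluation:
    """Outcome of scoring one candidate split."""

    attribute: str
    gain: float
    split_info: float
    gain_ratio: float
    threshold: Optional[float] = None
    weighted: bool = False


def expected_information(dist: ClassDistribution) -> float:
    """Entropy of the class distribution, in bits; in [0, log2 m]."""
    return _entropy(dist.probabilities)


def conditional_entropy(
    partition: AttributePartition,
    class_weights: Optional[WeightVector] = None,
) -> float:
    """Size-weighted mean entropy of the partition's subsets.

    With ``class_weights``, each subset's class probabilities become
    ``w_i n_ij / sum_k w_k n_kj`` while the subset weights ``W_j`` stay
    size-based.
    """
    sizes = partition.subset_sizes
    if np.any(sizes <= 0):
        raise DomainError(f"partition on {partition.attribute!r} has an empty subset")
    cells = partition.cell_counts
    if class_weights is not None:
        if tuple(class_weights.labels) != partition.labels:
            raise DomainError("weight vector labels do not match partition labels")
        cells = cells * class_weights.values[np.newaxis, :]
        if np.any(cells.sum(axis=1) <= 0):
            raise DomainError("a subset has zero total weighted mass")
    weights = partition.subset_weights
    total = 0.0
    for j in range(len(partition.branches)):
        row = cells[j]
        total += float(weights[j]) * _entropy(row / row.sum())
    return total


def information_gain(
    dist: ClassDistribution,
    partition: AttributePartition,
    class_weights: Optional[WeightVector] = None,
) -> float:
    """Entropy reduction achieved by the partition (weighted variant optional)."""
    if tuple(dist.labels) != partition.labels:
        raise PartitionConsistencyError("distribution and partition use different class labels")
    if not np.allclose(partition.class_totals, dist.counts, atol=1e-9):
        raise PartitionConsistencyError(
            f"class totals of partition on {partition.attribute!r} do not match the parent distribution"
        )
    if class_weights is not None:
        parent = weighted_class_distribution(dist, class_weights)
    else:
        parent = dist
    return expected_information(parent) - conditional_entropy(partition, class_weights)


def split_information(partition: AttributePartition) -> float:
    """Entropy of the subset-size distribution; 0 iff all mass sits in one subset."""
    return _entropy(partition.subset_weights)


def gain_ratio(gain: float, split_info: float) -> float:
    """gain / split_info; degenerate splits raise instead of returning inf."""
    if split_info < 0:
        raise DomainError("split information cannot be negative")
    if split_info < SPLIT_INFO_GUARD:
        raise DegenerateSplitError("split information is zero; candidate rejected")
    return gain / split_info


def class_weights(costs: CostMatrix, dist: ClassDistribution) -> WeightVector:
    """w(i) = C(i) n / sum_k C(k) n_k, so that sum_i w(i) n_i = n."""
    aligned = costs.aligned_to(dist.labels)
    row = aligned.row_costs
    n = dist.total
    denominator = float((row * dist.counts).sum())
    if denominator <= 0:
        raise ConfigError(
            "cost-derived weights undefined: every class has zero cost or zero count"
        )
    return WeightVector(dist.labels, row * n / denominator)


def weighted_class_distribution(
    dist: ClassDistribution,
    weights: WeightVector,
    subset_counts: Optional[np.ndarray] = None,
) -> ClassDistribution:
    """Rescale class counts by w(i); probabilities become w_i n_i / sum w_k n_k.

    Pass ``subset_counts`` (n_ij for one subset) to get the within-subset
    weighted distribution instead.
    """
    if tuple(weights.labels) != tuple(dist.labels):
        raise DomainError("weight vector labels do not match distribution labels")
    counts = np.asarray(subset_counts, dtype=float) if subset_counts is not None else dist.counts
    if counts.shape != (len(dist.labels),):
        raise DomainError("subset counts must align with class labels")
    mass = counts * weights.values
    if mass.sum() <= 0:
        raise DomainError("zero total weighted mass")
    return ClassDistribution(dist.labels, mass)
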