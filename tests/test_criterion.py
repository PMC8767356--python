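"""Unit and property tests for the split-criterion mathematics."""

import itertools
import math

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fittree import (
    AttributePartition,
    ClassDistribution,
    CostMatrix,
    WeightVector,
    class_weights,
    conditional_entropy,
    expected_information,
    gain_ratio,
    information_gain,
    split_information,
    weighted_class_distribution,
)
from fittree.exceptions import (
    ConfigError,
    DegenerateSplitError,
    DomainError,
    PartitionConsistencyError,
)

# ---------------------------------------------------------------------------
# independent brute-force oracle, written directly from the formulas


def oracle_entropy(counts):
    total = sum(counts)
    return -sum((c / total) * math.log2(c / total) for c in counts if c > 0)


def oracle_conditional(cells):
    total = sum(sum(row) for row in cells)
    return sum((sum(row) / total) * oracle_entropy(row) for row in cells)


def oracle_split_info(cells):
    sizes = [sum(row) for row in cells]
    return oracle_entropy(sizes)


def compositions(total, parts):
    """All ways to write `total` as an ordered sum of `parts` non-negatives."""
    if parts == 1:
        yield (total,)
        return
    for first in range(total + 1):
        for rest in compositions(total - first, parts - 1):
            yield (first, *rest)


def binary_partitions(counts):
    """All splits of per-class counts into two non-empty subsets."""
    ranges = [range(c + 1) for c in counts]
    for left in itertools.product(*ranges):
        right = tuple(c - l for c, l in zip(counts, left))
        if sum(left) and sum(right):
            yield [list(left), list(right)]


def labels_for(m):
    return tuple(f"c{i}" for i in range(m))


# ---------------------------------------------------------------------------
# worked examples (values frozen from the oracle above)


class TestExpectedInformation:
    def test_pure_class_is_zero(self):
        assert expected_information(ClassDistribution(("a", "b"), [10, 0])) == 0.0

    def test_symmetric_two_class_is_one_bit(self):
        assert expected_information(ClassDistribution(("a", "b"), [5, 5])) == pytest.approx(1.0)

    def test_nine_five(self):
        dist = ClassDistribution(("a", "b"), [9, 5])
        assert expected_information(dist) == pytest.approx(0.9402859587, abs=1e-9)

    def test_empty_distribution_rejected(self):
        with pytest.raises(DomainError):
            expected_information(ClassDistribution(("a",), [0]))

    def test_negative_counts_rejected(self):
        with pytest.raises(DomainError):
            ClassDistribution(("a", "b"), [3, -1])


class TestConditionalEntropy:
    def test_pure_subsets_zero(self):
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[4, 0], [0, 6]])
        assert conditional_entropy(part) == 0.0

    def test_single_subset_equals_parent_entropy(self):
        part = AttributePartition("x", ("a", "b"), ("only",), [[9, 5]])
        assert conditional_entropy(part) == pytest.approx(
            expected_information(ClassDistribution(("a", "b"), [9, 5]))
        )

    def test_three_one_six_four(self):
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[3, 1], [6, 4]])
        assert conditional_entropy(part) == pytest.approx(0.9253298887, abs=1e-9)

    def test_empty_subset_rejected(self):
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[0, 0], [9, 5]])
        with pytest.raises(DomainError):
            conditional_entropy(part)


class TestInformationGain:
    def test_pure_partition_gain_equals_parent_entropy(self):
        dist = ClassDistribution(("a", "b"), [4, 6])
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[4, 0], [0, 6]])
        assert information_gain(dist, part) == pytest.approx(expected_information(dist))

    def test_proportional_partition_gains_nothing(self):
        dist = ClassDistribution(("a", "b"), [6, 3])
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[4, 2], [2, 1]])
        assert information_gain(dist, part) == pytest.approx(0.0, abs=1e-12)

    def test_nine_five_example(self):
        dist = ClassDistribution(("a", "b"), [9, 5])
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[3, 1], [6, 4]])
        assert information_gain(dist, part) == pytest.approx(0.0149560699, abs=1e-9)

    def test_mismatched_totals_rejected(self):
        dist = ClassDistribution(("a", "b"), [9, 9])
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[3, 1], [6, 4]])
        with pytest.raises(PartitionConsistencyError):
            information_gain(dist, part)


class TestSplitInformation:
    def test_single_subset_zero(self):
        part = AttributePartition("x", ("a",), ("only",), [[7]])
        assert split_information(part) == 0.0

    def test_two_equal_subsets_one_bit(self):
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[3, 2], [1, 4]])
        assert split_information(part) == pytest.approx(1.0)

    def test_four_ten(self):
        part = AttributePartition("x", ("a", "b"), ("l", "r"), [[3, 1], [6, 4]])
        assert split_information(part) == pytest.approx(0.8631205686, abs=1e-9)


class TestGainRatio:
    def test_derived_quotient(self):
        assert gain_ratio(0.0149560699, 0.8631205686) == pytest.approx(0.0173284, abs=1e-6)

    def test_zero_gain(self):
        assert gain_ratio(0.0, 0.9) == 0.0

    def test_degenerate_split_rejected(self):
        with pytest.raises(DegenerateSplitError):
            gain_ratio(0.5, 0.0)


class TestClassWeights:
    def test_uniform_costs_give_unit_weights(self):
        costs = CostMatrix.uniform(("a", "b", "c"), off_diagonal=3.0)
        dist = ClassDistribution(("a", "b", "c"), [7, 2, 1])
        w = class_weights(costs, dist)
        assert np.allclose(w.values, 1.0, atol=1e-12)

    def test_imbalanced_two_class_example(self):
        costs = CostMatrix(("a", "b"), [[0, 1], [9, 0]])
        dist = ClassDistribution(("a", "b"), [90, 10])
        w = class_weights(costs, dist)
        assert w.values == pytest.approx([0.5555555556, 5.0], abs=1e-9)

    def test_single_class(self):
        costs = CostMatrix(("a", "b"), [[0, 2], [2, 0]])
        dist = ClassDistribution(("a", "b"), [30, 0])
        assert class_weights(costs, dist).values[0] == pytest.approx(1.0)

    def test_normalization_sums_to_n(self, rng):
        for _ in range(20):
            m = int(rng.integers(2, 5))
            labels = labels_for(m)
            counts = rng.integers(1, 30, m)
            costs = np.round(rng.uniform(0.5, 9.0, (m, m)), 3)
            np.fill_diagonal(costs, 0.0)
            w = class_weights(CostMatrix(labels, costs), ClassDistribution(labels, counts))
            assert (w.values * counts).sum() == pytest.approx(counts.sum(), rel=1e-12)

    def test_all_zero_denominator_rejected(self):
        costs = CostMatrix(("a", "b"), [[0, 0], [0, 0]])
        with pytest.raises(ConfigError):
            class_weights(costs, ClassDistribution(("a", "b"), [5, 5]))


class TestWeightedDistribution:
    def test_unit_weights_reduce(self):
        dist = ClassDistribution(("a", "b"), [9, 5])
        w = WeightVector(("a", "b"), [1.0, 1.0])
        assert weighted_class_distribution(dist, w).probabilities == pytest.approx(
            dist.probabilities
        )

    def test_cost_balanced_probabilities(self):
        dist = ClassDistribution(("a", "b"), [90, 10])
        w = WeightVector(("a", "b"), [0.5555555556, 5.0])
        wd = weighted_class_distribution(dist, w)
        assert wd.probabilities == pytest.approx([0.5, 0.5], abs=1e-9)
        assert expected_information(wd) == pytest.approx(1.0, abs=1e-9)

    def test_zero_mass_rejected(self):
        dist = ClassDistribution(("a", "b"), [9, 5])
        with pytest.raises(DomainError):
            weighted_class_distribution(dist, WeightVector(("a", "b"), [0.0, 0.0]))


# ---------------------------------------------------------------------------
# exhaustive oracle equivalence and invariants


def test_entropy_oracle_exhaustive():
    checked = 0
    for m in (1, 2, 3):
        labels = labels_for(m)
        for total in range(1, 13):
            for counts in compositions(total, m):
                dist = ClassDistribution(labels, counts)
                assert expected_information(dist) == pytest.approx(
                    oracle_entropy(counts), abs=1e-9
                )
                assert -1e-12 <= expected_information(dist) <= math.log2(m) + 1e-12
                checked += 1
    assert checked == 556  # every composition with m <= 3, total <= 12


def test_gain_and_ratio_oracle_exhaustive_small():
    checked = 0
    for m in (2, 3):
        labels = labels_for(m)
        for total in range(2, 8):
            for counts in compositions(total, m):
                dist = ClassDistribution(labels, counts)
                for cells in binary_partitions(counts):
                    part = AttributePartition("x", labels, ("l", "r"), cells)
                    gain = information_gain(dist, part)
                    si = split_information(part)
                    assert gain == pytest.approx(
                        oracle_entropy(counts) - oracle_conditional(cells), abs=1e-9
                    )
                    assert si == pytest.approx(oracle_split_info(cells), abs=1e-9)
                    assert gain >= -1e-9  # concavity of entropy
                    if si > 1e-12:
                        assert gain_ratio(gain, si) == pytest.approx(
                            (oracle_entropy(counts) - oracle_conditional(cells))
                            / oracle_split_info(cells),
                            abs=1e-9,
                        )
                    checked += 1
    assert checked > 1500


def test_refinement_never_increases_conditional_entropy(rng):
    labels = labels_for(3)
    for _ in range(100):
        cells = rng.integers(0, 6, (2, 3))
        if cells.sum(axis=1).min() == 0:
            continue
        coarse = AttributePartition("x", labels, ("l", "r"), cells)
        # refine the larger branch into two non-empty halves when possible
        j = int(np.argmax(cells.sum(axis=1)))
        split = np.array([rng.integers(0, c + 1) for c in cells[j]])
        rest = cells[j] - split
        if split.sum() == 0 or rest.sum() == 0:
            continue
        refined_cells = [cells[1 - j], split, rest]
        refined = AttributePartition("x", labels, ("o", "p", "q"), refined_cells)
        assert conditional_entropy(refined) <= conditional_entropy(coarse) + 1e-9


@settings(max_examples=200, deadline=None)
@given(
    counts=st.lists(st.integers(min_value=0, max_value=25), min_size=2, max_size=4).filter(
        lambda c: sum(c) > 0 and any(c)
    ),
    off_diagonal=st.floats(min_value=0.1, max_value=50.0, allow_nan=False),
)
def test_uniform_cost_reduction_property(counts, off_diagonal):
    """Uniform off-diagonal costs collapse every weighted quantity to the
    unweighted one (to 1e-12)."""
    labels = labels_for(len(counts))
    dist = ClassDistribution(labels, counts)
    costs = CostMatrix.uniform(labels, off_diagonal=off_diagonal)
    w = class_weights(costs, dist)
    assert np.allclose(w.values, 1.0, atol=1e-12)
    wd = weighted_class_distribution(dist, w)
    assert expected_information(wd) == pytest.approx(expected_information(dist), abs=1e-12)
    # any two-way partition of the counts behaves identically weighted/unweighted
    left = [c // 2 for c in counts]
    right = [c - l for c, l in zip(counts, left)]
    if sum(left) and sum(right):
        part = AttributePartition("x", labels, ("l", "r"), [left, right])
        assert conditional_entropy(part, w) == pytest.approx(
            conditional_entropy(part), abs=1e-12
        )
        assert information_gain(dist, part, w) == pytest.approx(
            information_gain(dist, part), abs=1e-12
        )


def test_cost_matrix_validation():
    with pytest.raises(ConfigError):
        CostMatrix(("a", "b"), [[1, 1], [1, 0]])  # nonzero diagonal
    with pytest.raises(ConfigError):
        CostMatrix(("a", "b"), [[0, -1], [1, 0]])  # negative cost
    with pytest.raises(ConfigError):
        CostMatrix.from_mapping({"a": {"zzz": 2}}, labels=("a", "b"))


def test_cost_matrix_from_mapping_defaults():
    cm = CostMatrix.from_mapping({"a": {"b": 7}}, labels=("a", "b", "c"))
    assert cm.costs[0, 1] == 7
    assert cm.costs[0, 2] == 1  # omitted cells default to 1 off-diagonal
    assert np.all(np.diagonal(cm.costs) == 0)
    assert cm.row_cost("a") == 8
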