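"""Confusion-matrix evaluation with cost-stratified error rates.

Records are stratified by their TRUE class's row-sum misclassification cost
C(i): classes ranked by C(i) fall into high / general / low cost strata
(explicit mapping overridable). Each stratum rate is the misclassification
percentage among records whose true class belongs to the stratum; the
"error value" of a comparison is (new model - adjusted model) per rate, in
percentage points, sign preserved.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Mapping, Optional, Sequence

import numpy as np
import pandas as pd

from .criterion import CostMatrix
from .data import LabeledDataset
from .exceptions import ConfigError, InputError
from .induction import DecisionTree, InductionConfig, build_tree

STRATA = ("high", "general", "low")
RATE_NAMES = ("total", "high", "general", "low")


@dataclass(frozen=True)
class ConfusionMatrix:
    labels: tuple
    counts: np.ndarray  # rows = true class, columns = predicted

    def __post_init__(self) -> None:
        counts = np.asarray(self.counts, dtype=np.int64)
        object.__setattr__(self, "labels", tuple(self.labels))
        object.__setattr__(self, "counts", counts)
        m = len(self.labels)
        if counts.shape != (m, m):
            raise InputError("confusion matrix must be square and aligned with labels")
        if np.any(counts < 0):
            raise InputError("confusion counts must be non-negative")

    @classmethod
    def from_predictions(
        cls, truth: Sequence, predictions: Sequence, labels: Optional[Sequence] = None
    ) -> "ConfusionMatrix":
        truth = list(truth)
        predictions = list(predictions)
        if len(truth) != len(predictions) or len(truth) == 0:
            raise InputError("truth and predictions must have equal, non-zero length")
        if labels is None:
            labels = sorted(set(truth) | set(predictions), key=str)
        labels = tuple(labels)
        index = {lab: k for k, lab in enumerate(labels)}
        counts = np.zeros((len(labels), len(labels)), dtype=np.int64)
        for t, p in zip(truth, predictions):
            if t not in index or p not in index:
                raise InputError(f"label {t if t not in index else p!r} not in declared labels")
            counts[index[t], index[p]] += 1
        return cls(labels, counts)

    @property
    def total(self) -> int:
        return int(self.counts.sum())

    @property
    def misclassified(self) -> int:
        return int(self.counts.sum() - np.trace(self.counts))

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.counts, index=list(self.labels), columns=list(self.labels))


def confusion_matrix(truth: Sequence, predictions: Sequence, labels: Optional[Sequence] = None) -> ConfusionMatrix:
    return ConfusionMatrix.from_predictions(truth, predictions, labels)


def cost_strata(costs: CostMatrix, labels: Optional[Sequence] = None) -> dict:
    """Default class -> stratum map: rank classes by C(i) descending, split
    the ranking into high / general / low thirds (ties keep label order)."""
    labels = tuple(labels) if labels is not None else costs.labels
    aligned = costs.aligned_to(labels)
    row = aligned.row_costs
    m = len(labels)
    order = sorted(range(m), key=lambda i: (-row[i], i))
    mapping = {}
    for rank, i in enumerate(order):
        mapping[labels[i]] = STRATA[(3 * rank) // m]
    return mapping


@dataclass(frozen=True)
class ErrorReport:
    """Total and per-cost-stratum error rates, in percent."""

    role: str  # "modeling" or "test"
    rates: Mapping[str, float]  # keys: total/high/general/low, values in [0, 100]
    stratum_records: Mapping[str, int] = field(default_factory=dict)
    stratum_errors: Mapping[str, int] = field(default_factory=dict)
    empty_strata: tuple = ()

    def __post_init__(self) -> None:
        object.__setattr__(self, "rates", dict(self.rates))
        object.__setattr__(self, "stratum_records", dict(self.stratum_records))
        object.__setattr__(self, "stratum_errors", dict(self.stratum_errors))
        for name in RATE_NAMES:
            if name not in self.rates:
                raise InputError(f"error report lacks rate {name!r}")
            if not 0 <= self.rates[name] <= 100:
                raise InputError(f"rate {name!r} outside [0, 100]")

    def rate(self, name: str) -> float:
        return self.rates[name]

    def rounded(self, ndigits: int = 2) -> dict:
        return {name: round(self.rates[name], ndigits) for name in RATE_NAMES}


@dataclass(frozen=True)
class ErrorDelta:
    """Per-rate difference (new model - adjusted model), percentage points."""

    role: str
    deltas: Mapping[str, float]

    def __post_init__(self) -> None:
        object.__setattr__(self, "deltas", dict(self.deltas))

    def delta(self, name: str) -> float:
        return self.deltas[name]

    def rounded(self, ndigits: int = 2) -> dict:
        return {name: round(self.deltas[name], ndigits) for name in RATE_NAMES}


def stratified_error_rates(
    cm: ConfusionMatrix,
    costs: CostMatrix,
    role: str = "test",
    strata: Optional[Mapping] = None,
) -> ErrorReport:
    """Total plus high/general/low-cost error rates from a confusion matrix."""
    if strata is None:
        strata = cost_strata(costs, cm.labels)
    for lab in cm.labels:
        if lab not in strata:
            raise ConfigError(f"class {lab!r} missing from the stratum mapping")
        if strata[lab] not in STRATA:
            raise ConfigError(f"class {lab!r} mapped to unknown stratum {strata[lab]!r}")
    row_totals = cm.counts.sum(axis=1)
    row_errors = row_totals - np.diagonal(cm.counts)
    rates = {"total": 100.0 * cm.misclassified / cm.total}
    records: dict[str, int] = {s: 0 for s in STRATA}
    errors: dict[str, int] = {s: 0 for s in STRATA}
    for i, lab in enumerate(cm.labels):
        records[strata[lab]] += int(row_totals[i])
        errors[strata[lab]] += int(row_errors[i])
    empty = tuple(s for s in STRATA if records[s] == 0)
    for s in STRATA:
        rates[s] = 100.0 * errors[s] / records[s] if records[s] else 0.0
    return ErrorReport(
        role=role,
        rates=rates,
        stratum_records=records,
        stratum_errors=errors,
        empty_strata=empty,
    )


def error_value(new: ErrorReport, adjusted: ErrorReport) -> ErrorDelta:
    """new - adjusted for every rate; sign preserved (negative = adjusted worse)."""
    if new.role != adjusted.role:
        raise InputError(f"role mismatch: {new.role!r} vs {adjusted.role!r}")
    return ErrorDelta(
        role=new.role,
        deltas={name: new.rates[name] - adjusted.rates[name] for name in RATE_NAMES},
    )


def stratified_split(
    labels: Sequence, test_fraction: float, seed: int
) -> tuple[np.ndarray, np.ndarray]:
    """Seeded per-class random split; returns (modeling_idx, test_idx)."""
    if not 0 < test_fraction < 1:
        raise InputError("test fraction must be in (0, 1)")
    labels = np.asarray(labels, dtype=object)
    rng = np.random.default_rng(seed)
    test_parts = []
    for lab in sorted(set(labels.tolist()), key=str):
        members = np.flatnonzero(labels == lab)
        members = members[rng.permutation(len(members))]
        n_test = int(round(test_fraction * len(members)))
        test_parts.append(members[:n_test])
    test_idx = np.sort(np.concatenate(test_parts)) if test_parts else np.array([], dtype=int)
    mask = np.zeros(len(labels), dtype=bool)
    mask[test_idx] = True
    model_idx = np.flatnonzero(~mask)
    if len(model_idx) == 0 or len(test_idx) == 0:
        raise InputError("degenerate split: a role received no records")
    return model_idx, test_idx


@dataclass(frozen=True)
class ModelComparison:
    """Paired reports (standard vs cost-sensitive arm) plus per-role deltas."""

    reports: Mapping[str, Mapping[str, ErrorReport]]  # role -> {"new","adjusted"}
    deltas: Mapping[str, ErrorDelta]  # role -> delta
    trees: Mapping[str, DecisionTree] = field(default_factory=dict)

    def to_frame(self) -> pd.DataFrame:
        rows = []
        for role in ("modeling", "test"):
            new = self.reports[role]["new"]
            adj = self.reports[role]["adjusted"]
            delta = self.deltas[role]
            for name in RATE_NAMES:
                rows.append(
                    {
                        "analysis_index": f"{role} data",
                        "comparison_model": f"{name} cost error rate (%)" if name != "total" else "total error rate (%)",
                        "newly_built_model": round(new.rates[name], 2),
                        "adjusted_model": round(adj.rates[name], 2),
                        "error_value": round(delta.deltas[name], 2),
                    }
                )
        return pd.DataFrame(rows)

    def to_text(self) -> str:
        frame = self.to_frame()
        return frame.to_string(index=False)


def compare_models(
    dataset: LabeledDataset,
    costs: CostMatrix,
    config: Optional[InductionConfig] = None,
    test_fraction: float = 0.3,
    seed: int = 0,
    strata: Optional[Mapping] = None,
) -> ModelComparison:
    """Train a standard-criterion and a cost-weighted tree on a seeded
    stratified split and report the four-rate x two-role table with deltas."""
    base = config or InductionConfig()
    model_idx, test_idx = stratified_split(dataset.labels.to_numpy(), test_fraction, seed)
    frames = {
        "modeling": dataset.frame.iloc[model_idx].reset_index(drop=True),
        "test": dataset.frame.iloc[test_idx].reset_index(drop=True),
    }
    train = LabeledDataset(frames["modeling"], dataset.attributes, dataset.label)

    standard_cfg = InductionConfig(
        min_samples_to_split=base.min_samples_to_split,
        max_depth=base.max_depth,
        cost_sensitive=False,
        tie_tolerance=base.tie_tolerance,
    )
    weighted_cfg = InductionConfig(
        min_samples_to_split=base.min_samples_to_split,
        max_depth=base.max_depth,
        cost_sensitive=True,
        tie_tolerance=base.tie_tolerance,
    )
    trees = {
        "new": build_tree(train, standard_cfg, costs),
        "adjusted": build_tree(train, weighted_cfg, costs),
    }

    class_labels = train.classes
    reports: dict[str, dict[str, ErrorReport]] = {}
    deltas: dict[str, ErrorDelta] = {}
    for role, frame in frames.items():
        truth = frame[dataset.label].tolist()
        role_reports = {}
        for arm, tree in trees.items():
            predictions = tree.predict(frame).tolist()
            cm = ConfusionMatrix.from_predictions(truth, predictions, labels=class_labels)
            role_reports[arm] = stratified_error_rates(cm, costs, role=role, strata=strata)
        reports[role] = role_reports
        deltas[role] = error_value(role_reports["new"], role_reports["adjusted"])
    return ModelComparison(reports=reports, deltas=deltas, trees=trees)
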