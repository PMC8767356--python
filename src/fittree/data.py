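"""Labeled tabular datasets with declared attribute kinds."""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Union

import pandas as pd
import yaml

from .exceptions import InputError

CONTINUOUS = "continuous"
CATEGORICAL = "categorical"
_KINDS = (CONTINUOUS, CATEGORICAL)


@dataclass
class LabeledDataset:
    """A sample set: a frame of attribute columns plus one class-label column.

    ``attributes`` maps each usable attribute name to its kind
    (``"continuous"`` or ``"categorical"``). Missing values are rejected at
    construction — there are no fractional instances downstream.
    """

    frame: pd.DataFrame
    attributes: Mapping[str, str]
    label: str = "label"

    def __post_init__(self) -> None:
        self.attributes = dict(self.attributes)
        if not self.attributes:
            raise InputError("at least one attribute must be declared")
        for name, kind in self.attributes.items():
            if kind not in _KINDS:
                raise InputError(f"attribute {name!r} has unknown kind {kind!r}")
            if name not in self.frame.columns:
                raise InputError(f"declared attribute {name!r} missing from the table")
        if self.label not in self.frame.columns:
            raise InputError(f"label column {self.label!r} missing from the table")
        used = list(self.attributes) + [self.label]
        if self.frame[used].isna().any().any():
            bad = [c for c in used if self.frame[c].isna().any()]
            raise InputError(f"missing values in columns {bad}; clean the input first")

    def __len__(self) -> int:
        return len(self.frame)

    @property
    def classes(self) -> tuple:
        """Deterministic class order: sorted unique labels."""
        return tuple(sorted(self.frame[self.label].unique(), key=str))

    @property
    def labels(self) -> pd.Series:
        return self.frame[self.label]

    @classmethod
    def from_csv(
        cls,
        csv_path: Union[str, Path],
        attributes: Union[Mapping[str, str], str, Path],
        label: str = "label",
    ) -> "LabeledDataset":
        """Load a CSV; ``attributes`` is a mapping or a YAML/JSON sidecar path
        with keys ``attributes`` (name -> kind) and optional ``label``."""
        frame = pd.read_csv(csv_path)
        if not isinstance(attributes, Mapping):
            path = Path(attributes)
            text = path.read_text()
            doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
            if not isinstance(doc, Mapping) or "attributes" not in doc:
                raise InputError(f"{path}: sidecar must define an 'attributes' mapping")
            label = doc.get("label", label)
            attributes = doc["attributes"]
        return cls(frame=frame, attributes=attributes, label=label)
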