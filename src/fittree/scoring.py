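"""Physical-fitness band scoring.

A :class:`ScoringStandard` maps a measured index (BMI by default) to a band
label and a score, keyed by (grade, gender). Band bounds are expressed at
one-decimal resolution; the measured value is rounded to one decimal (half
away from zero) before lookup, so the bands jointly cover the whole line.

The shipped default transcribes the national BMI standard for the four
strata it defines: freshman/sophomore/junior males and senior females.
Other strata need a user-supplied standard — no undocumented cut-offs are
invented.
"""

from __future__ import annotations

import json
import math
import warnings
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Mapping, Optional, Sequence, Union

import pandas as pd
import yaml

from .exceptions import ConfigError, InputError, MissingStandardError

GRADES = ("freshman", "sophomore", "junior", "senior")
GENDERS = ("male", "female")
BAND_LABELS = ("low weight", "normal", "overweight", "obesity")


def _tenths(value: float) -> int:
    """Round to one decimal, half away from zero, returned in integer tenths."""
    return int(math.floor(abs(value) * 10.0 + 0.5)) * (1 if value >= 0 else -1)


def compute_bmi(weight: float, height: float) -> float:
    """Body mass index: weight (kg) / height (m) squared."""
    if height <= 0:
        raise InputError(f"height must be positive, got {height}")
    if weight <= 0:
        raise InputError(f"weight must be positive, got {weight}")
    return weight / height**2


@dataclass(frozen=True)
class Band:
    """One scoring band: inclusive one-decimal bounds (None = unbounded)."""

    label: str
    score: float
    lo: Optional[float] = None
    hi: Optional[float] = None

    def __post_init__(self) -> None:
        if self.score <= 0:
            raise ConfigError(f"band {self.label!r}: score must be positive")
        if self.lo is not None and self.hi is not None and self.lo > self.hi:
            raise ConfigError(f"band {self.label!r}: lower bound exceeds upper bound")

    @property
    def lo_tenths(self) -> Optional[int]:
        return None if self.lo is None else _tenths(self.lo)

    @property
    def hi_tenths(self) -> Optional[int]:
        return None if self.hi is None else _tenths(self.hi)

    def contains_tenths(self, t: int) -> bool:
        if self.lo_tenths is not None and t < self.lo_tenths:
            return False
        if self.hi_tenths is not None and t > self.hi_tenths:
            return False
        return True


@dataclass(frozen=True)
class ScoringStandard:
    """Ordered bands per (grade, gender) stratum for one index."""

    index: str
    entries: Mapping[tuple, tuple]

    def __post_init__(self) -> None:
        object.__setattr__(self, "entries", dict(self.entries))
        problems: list[str] = []
        for key, bands in self.entries.items():
            grade, gender = key
            if grade not in GRADES:
                problems.append(f"{key}: unknown grade {grade!r}")
            if gender not in GENDERS:
                problems.append(f"{key}: unknown gender {gender!r}")
            if not bands:
                problems.append(f"{key}: no bands")
                continue
            if bands[0].lo is not None:
                problems.append(f"{key}: first band must be open below")
            if bands[-1].hi is not None:
                problems.append(f"{key}: last band must be open above")
            for a, b in zip(bands, bands[1:]):
                if a.hi is None or b.lo is None:
                    problems.append(f"{key}: interior band with open bound")
                    continue
                if b.lo_tenths != a.hi_tenths + 1:
                    problems.append(
                        f"{key}: bands {a.label!r} (..{a.hi}) and {b.label!r} ({b.lo}..) "
                        "overlap or leave a gap at one-decimal resolution"
                    )
        if problems:
            raise ConfigError("invalid scoring standard: " + "; ".join(problems))
        missing = [f"{g}/{s}" for g in GRADES for s in GENDERS if (g, s) not in self.entries]
        if missing:
            warnings.warn(
                f"scoring standard for {self.index!r} lacks strata: {', '.join(missing)}; "
                "lookups for them will fail",
                stacklevel=3,
            )

    @property
    def keys(self) -> tuple:
        return tuple(self.entries)

    def bands_for(self, grade: str, gender: str) -> tuple:
        try:
            return self.entries[(grade, gender)]
        except KeyError:
            raise MissingStandardError(
                f"no {self.index} standard for stratum ({grade}, {gender})"
            ) from None

    def band_labels_for(self, grade: str, gender: str) -> tuple:
        return tuple(b.label for b in self.bands_for(grade, gender))


_DEFAULT_BMI_ROWS = {
    ("freshman", "male"): ((None, 13.4), (13.5, 18.1), (18.2, 20.3), (20.4, None)),
    ("sophomore", "male"): ((None, 13.6), (13.7, 18.4), (18.5, 20.4), (20.5, None)),
    ("junior", "male"): ((None, 17.8), (17.9, 23.9), (24.0, 27.9), (28.0, None)),
    ("senior", "female"): ((None, 17.1), (17.2, 23.9), (24.0, 27.9), (28.0, None)),
}
_DEFAULT_SCORES = (80, 100, 80, 60)


def default_bmi_standard() -> ScoringStandard:
    """The shipped national BMI standard (four strata, four bands each)."""
    entries = {}
    for key, bounds in _DEFAULT_BMI_ROWS.items():
        entries[key] = tuple(
            Band(label=label, score=score, lo=lo, hi=hi)
            for label, score, (lo, hi) in zip(BAND_LABELS, _DEFAULT_SCORES, bounds)
        )
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # the default deliberately omits strata
        return ScoringStandard(index="BMI", entries=entries)


def load_scoring_standard(source: Union[str, Path, Mapping]) -> ScoringStandard:
    """Load a standard from a YAML/JSON document::

        index: BMI
        entries:
          - grade: freshman
            gender: male
            bands:
              - {label: low weight, max: 13.4, score: 80}
              - {label: normal, min: 13.5, max: 18.1, score: 100}
              ...
    """
    if isinstance(source, Mapping):
        doc = source
    else:
        path = Path(source)
        text = path.read_text()
        doc = json.loads(text) if path.suffix == ".json" else yaml.safe_load(text)
    if not isinstance(doc, Mapping) or "entries" not in doc:
        raise ConfigError("standard document must be a mapping with an 'entries' list")
    entries = {}
    for k, entry in enumerate(doc["entries"]):
        if not isinstance(entry, Mapping) or not {"grade", "gender", "bands"} <= set(entry):
            raise ConfigError(f"entries[{k}]: needs grade, gender and bands")
        bands = []
        for j, band in enumerate(entry["bands"]):
            if not isinstance(band, Mapping) or "label" not in band or "score" not in band:
                raise ConfigError(f"entries[{k}].bands[{j}]: needs label and score")
            bands.append(
                Band(
                    label=str(band["label"]),
                    score=float(band["score"]),
                    lo=None if band.get("min") is None else float(band["min"]),
                    hi=None if band.get("max") is None else float(band["max"]),
                )
            )
        key = (str(entry["grade"]), str(entry["gender"]))
        if key in entries:
            raise ConfigError(f"entries[{k}]: duplicate stratum {key}")
        entries[key] = tuple(bands)
    return ScoringStandard(index=str(doc.get("index", "index")), entries=entries)


def score_index(
    value: float,
    grade: str,
    gender: str,
    standard: Optional[ScoringStandard] = None,
) -> tuple[str, float]:
    """Band label and score for one measured value; rounds to one decimal first."""
    if standard is None:
        standard = default_bmi_standard()
    bands = standard.bands_for(grade, gender)
    t = _tenths(value)
    for band in bands:
        if band.contains_tenths(t):
            return band.label, band.score
    raise ConfigError(  # unreachable for validated standards
        f"value {value} falls outside every band of ({grade}, {gender})"
    )


@dataclass(frozen=True)
class StudentRecord:
    """One student: anthropometrics plus cohort stratum."""

    id: str
    grade: str
    gender: str
    height: Optional[float] = None  # m
    weight: Optional[float] = None  # kg
    bmi: Optional[float] = None  # kg/m^2, derived from height/weight if absent
    vital_capacity: Optional[float] = None  # mL
    tested: bool = True

    def problems(self) -> list[str]:
        out = []
        if self.grade not in GRADES:
            out.append(f"unknown grade {self.grade!r}")
        if self.gender not in GENDERS:
            out.append(f"unknown gender {self.gender!r}")
        if self.height is not None and self.height <= 0:
            out.append("non-positive height")
        if self.weight is not None and self.weight <= 0:
            out.append("non-positive weight")
        if self.bmi is None and (self.height is None or self.weight is None):
            out.append("no BMI and no height/weight to derive it")
        return out

    def effective_bmi(self) -> float:
        if self.bmi is not None:
            return self.bmi
        return compute_bmi(self.weight, self.height)


def score_cohort(
    records: Union[pd.DataFrame, Iterable[StudentRecord]],
    standard: Optional[ScoringStandard] = None,
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Score every record; invalid records land in the error table, never dropped.

    Returns ``(scored, errors)``: scored has columns id/index/value/band/score,
    errors has columns id/reason.
    """
    if standard is None:
        standard = default_bmi_standard()
    if isinstance(records, pd.DataFrame):
        records = _records_from_frame(records)
    scored_rows, error_rows = [], []
    for rec in records:
        issues = rec.problems()
        if issues:
            error_rows.append({"id": rec.id, "reason": "; ".join(issues)})
            continue
        try:
            value = rec.effective_bmi()
            band, score = score_index(value, rec.grade, rec.gender, standard)
        except (InputError, MissingStandardError) as exc:
            error_rows.append({"id": rec.id, "reason": str(exc)})
            continue
        scored_rows.append(
            {"id": rec.id, "index": standard.index, "value": value, "band": band, "score": score}
        )
    scored = pd.DataFrame(scored_rows, columns=["id", "index", "value", "band", "score"])
    errors = pd.DataFrame(error_rows, columns=["id", "reason"])
    return scored, errors


def _records_from_frame(frame: pd.DataFrame) -> list[StudentRecord]:
    def get(row, key):
        value = row.get(key)
        if value is None or (isinstance(value, float) and math.isnan(value)):
            return None
        return value

    records = []
    for k, row in enumerate(frame.to_dict("records")):
        records.append(
            StudentRecord(
                id=str(row.get("id", k)),
                grade=str(row.get("grade")),
                gender=str(row.get("gender")),
                height=get(row, "height"),
                weight=get(row, "weight"),
                bmi=get(row, "bmi"),
                vital_capacity=get(row, "vital_capacity"),
                tested=bool(row.get("tested", True)),
            )
        )
    return records
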