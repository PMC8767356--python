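"""Seeded synthetic student-cohort generation.

Emulates a four-grade, two-gender university population with an imbalanced
tested/untested composition and per-stratum BMI drawn from truncated
normals. Class labels are scoring-band labels of the true BMI (optionally
collapsed to pass/fail), flipped to a random other label with a configured
noise rate. Everything is reproducible from the seed: the same config and
seed give a byte-identical CSV.

The default stratum proportions are qualitative mimicry only (tested boys >
tested girls > untested boys > untested girls, uniform over grades); they
are declared synthetic, not measured.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field
from pathlib import Path
from typing import Mapping, Optional, Union

import numpy as np
import pandas as pd
from scipy import stats

from .data import CATEGORICAL, CONTINUOUS, LabeledDataset
from .exceptions import ConfigError
from .scoring import GENDERS, GRADES, ScoringStandard, default_bmi_standard, score_index

COHORT_FORMAT_VERSION = 1

# tested-male > tested-female > untested-male > untested-female
_DEFAULT_GROUP_WEIGHTS = {
    ("male", True): 0.40,
    ("female", True): 0.30,
    ("male", False): 0.18,
    ("female", False): 0.12,
}


def default_proportions() -> dict:
    """Uniform over grades, imbalanced over gender x tested."""
    return {
        (grade, gender, tested): weight / len(GRADES)
        for grade in GRADES
        for (gender, tested), weight in _DEFAULT_GROUP_WEIGHTS.items()
    }


@dataclass(frozen=True)
class BmiModel:
    """Truncated-normal BMI parameters for one stratum."""

    mean: float = 18.0
    sd: float = 3.0
    lo: float = 10.0
    hi: float = 32.0

    def __post_init__(self) -> None:
        if self.sd <= 0 or not self.lo < self.hi:
            raise ConfigError("BMI model needs sd > 0 and lo < hi")


@dataclass(frozen=True)
class CohortConfig:
    n: int = 1000
    seed: int = 0
    proportions: Mapping = field(default_factory=default_proportions)
    bmi: BmiModel = field(default_factory=BmiModel)
    bmi_by_stratum: Mapping = field(default_factory=dict)  # (grade, gender) -> BmiModel
    noise_rate: float = 0.0
    # stratum key used to look up labeling bands; None, None = each record's own
    label_grade: Optional[str] = "freshman"
    label_gender: Optional[str] = "male"
    binary_labels: bool = False  # collapse bands to pass (normal) / fail

    def __post_init__(self) -> None:
        if self.n < 0:
            raise ConfigError("cohort size must be non-negative")
        if not 0 <= self.noise_rate < 1:
            raise ConfigError("noise rate must be in [0, 1)")
        props = dict(self.proportions)
        object.__setattr__(self, "proportions", props)
        object.__setattr__(self, "bmi_by_stratum", dict(self.bmi_by_stratum))
        if any(p < 0 for p in props.values()):
            raise ConfigError("stratum proportions must be non-negative")
        total = sum(props.values())
        if abs(total - 1.0) > 1e-9:
            raise ConfigError(f"stratum proportions must sum to 1, got {total}")
        for grade, gender, _tested in props:
            if grade not in GRADES or gender not in GENDERS:
                raise ConfigError(f"unknown stratum ({grade}, {gender})")

    def strata(self) -> list:
        return sorted(self.proportions, key=lambda k: (GRADES.index(k[0]), GENDERS.index(k[1]), not k[2]))

    def to_jsonable(self) -> dict:
        return {
            "n": self.n,
            "seed": self.seed,
            "proportions": {
                f"{g}/{s}/{'tested' if t else 'untested'}": p
                for (g, s, t), p in sorted(self.proportions.items(), key=str)
            },
            "bmi": vars(self.bmi),
            "bmi_by_stratum": {f"{g}/{s}": vars(m) for (g, s), m in sorted(self.bmi_by_stratum.items())},
            "noise_rate": self.noise_rate,
            "label_grade": self.label_grade,
            "label_gender": self.label_gender,
            "binary_labels": self.binary_labels,
        }


_HEIGHT = {"male": (1.75, 0.06), "female": (1.62, 0.05)}
_VITAL = {"male": (4200.0, 600.0), "female": (3100.0, 500.0)}


def _truncated_normal(rng: np.random.Generator, model: BmiModel, size: int) -> np.ndarray:
    a = (model.lo - model.mean) / model.sd
    b = (model.hi - model.mean) / model.sd
    return stats.truncnorm.rvs(a, b, loc=model.mean, scale=model.sd, size=size, random_state=rng)


def generate_cohort(
    config: CohortConfig,
    standard: Optional[ScoringStandard] = None,
) -> pd.DataFrame:
    """Generate exactly ``config.n`` labeled student records.

    Columns: id, grade, gender, tested, height, weight, bmi, vital_capacity,
    label. Label = scoring band of the true BMI (before any noise flip).
    """
    if standard is None:
        standard = default_bmi_standard()
    rng = np.random.default_rng(config.seed)
    strata = config.strata()
    probs = np.array([config.proportions[s] for s in strata])
    counts = rng.multinomial(config.n, probs)

    pieces = []
    for (grade, gender, tested), count in zip(strata, counts):
        if count == 0:
            continue
        model = config.bmi_by_stratum.get((grade, gender), config.bmi)
        bmi = _truncated_normal(rng, model, count)
        h_mean, h_sd = _HEIGHT[gender]
        height = np.clip(rng.normal(h_mean, h_sd, count), 1.40, 2.10)
        v_mean, v_sd = _VITAL[gender]
        vital = np.clip(rng.normal(v_mean, v_sd, count), 1500.0, None)
        pieces.append(
            pd.DataFrame(
                {
                    "grade": grade,
                    "gender": gender,
                    "tested": tested,
                    "height": np.round(height, 3),
                    "weight": np.round(bmi * height**2, 2),
                    "bmi": np.round(bmi, 4),
                    "vital_capacity": np.round(vital, 0),
                }
            )
        )
    if pieces:
        frame = pd.concat(pieces, ignore_index=True)
    else:
        frame = pd.DataFrame(
            columns=["grade", "gender", "tested", "height", "weight", "bmi", "vital_capacity"]
        )

    # label from the configured band standard, then noise flips
    labels = []
    for row in frame.itertuples(index=False):
        grade = config.label_grade or row.grade
        gender = config.label_gender or row.gender
        band, _score = score_index(row.bmi, grade, gender, standard)
        if config.binary_labels:
            band = "pass" if band == "normal" else "fail"
        labels.append(band)
    frame["label"] = labels

    if len(frame) and config.noise_rate > 0:
        vocabulary = sorted(set(labels))
        flip = rng.random(len(frame)) < config.noise_rate
        if len(vocabulary) > 1:
            for i in np.flatnonzero(flip):
                others = [v for v in vocabulary if v != frame.at[i, "label"]]
                frame.at[i, "label"] = others[rng.integers(len(others))]

    # deterministic shuffle + stable ids
    if len(frame):
        frame = frame.iloc[rng.permutation(len(frame))].reset_index(drop=True)
    frame.insert(0, "id", [f"S{k + 1:06d}" for k in range(len(frame))])
    return frame


def cohort_summary(frame: pd.DataFrame) -> pd.DataFrame:
    """Counts and proportions by grade x gender x tested."""
    if len(frame) == 0:
        return pd.DataFrame(columns=["grade", "gender", "tested", "count", "proportion"])
    grouped = (
        frame.groupby(["grade", "gender", "tested"], observed=True)
        .size()
        .reset_index(name="count")
        .sort_values(["grade", "gender", "tested"], kind="mergesort")
        .reset_index(drop=True)
    )
    grouped["proportion"] = grouped["count"] / grouped["count"].sum()
    return grouped


def as_dataset(
    frame: pd.DataFrame,
    attributes: Optional[Mapping[str, str]] = None,
    label: str = "label",
) -> LabeledDataset:
    """View a cohort frame as a LabeledDataset (default: BMI + grade + gender)."""
    if attributes is None:
        attributes = {"bmi": CONTINUOUS, "grade": CATEGORICAL, "gender": CATEGORICAL}
    return LabeledDataset(frame=frame, attributes=attributes, label=label)


def save_cohort(frame: pd.DataFrame, path: Union[str, Path], config: CohortConfig) -> Path:
    """Write the cohort CSV plus a JSON provenance manifest alongside it."""
    path = Path(path)
    frame.to_csv(path, index=False, float_format="%.4f", lineterminator="\n")
    manifest = {
        "format": "fittree.cohort",
        "version": COHORT_FORMAT_VERSION,
        "n": int(len(frame)),
        "config": config.to_jsonable(),
    }
    manifest_path = path.with_suffix(".manifest.json")
    manifest_path.write_text(json.dumps(manifest, indent=2, sort_keys=True) + "\n")
    return manifest_path
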