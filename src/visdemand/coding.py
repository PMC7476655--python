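"""Scene-coding schema, task vocabulary, and inter-rater agreement.

The shipped schema holds the 14 categorical classifiers used to code each
snapshot; the task vocabulary holds the 48-item visual-functioning
questionnaire inventory plus observed bespoke labels. Agreement between
two coders is raw percent agreement per classifier (no chance
correction); Cohen's kappa is available as an optional extra.
"""

from __future__ import annotations

import datetime as _dt
import re
from dataclasses import dataclass, field
from importlib import resources
from typing import Iterable, Mapping, Sequence

import pandas as pd
import yaml

DIFFICULTY_LEVELS = (
    "very easy",
    "easy",
    "average",
    "difficult",
    "very difficult",
    "unable",
)

TIME_OF_DAY_BINS = ("6-12", "12-18", "18-24", "0-6")


class SchemaValidationError(ValueError):
    """A scene code carries an out-of-vocabulary value."""


class MissingClassifierError(ValueError):
    """A scene code lacks one of the schema's classifiers."""


class PairingError(ValueError):
    """Two coder lists cannot be paired snapshot-by-snapshot."""


@dataclass(frozen=True)
class ClassifierSpec:
    """One categorical classifier: a name and its ordered category set."""

    name: str
    categories: tuple[str, ...]

    def __post_init__(self) -> None:
        if len(self.categories) < 2:
            raise ValueError(f"classifier {self.name!r} needs ≥ 2 categories")
        if len(set(self.categories)) != len(self.categories):
            raise ValueError(f"classifier {self.name!r} has duplicate categories")


@dataclass
class SceneCode:
    """One snapshot's categorical values, keyed by classifier name."""

    snapshot_id: str
    values: dict[str, str] = field(default_factory=dict)


@dataclass
class TaskRecord:
    """One narrated subtask mapped to the task vocabulary."""

    participant_id: str
    snapshot_id: str
    narrative: str
    task_label: str
    is_bespoke: bool
    able_alone: bool = True
    coping_used: bool = False


@dataclass
class AgreementReport:
    """Per-classifier raw percent agreement over paired items."""

    per_classifier: dict[str, float]
    n_items: int


@dataclass
class TaskVocabulary:
    vfq48: tuple[str, ...]
    bespoke: tuple[str, ...]
    provisional: bool = True


def _data_text(name: str) -> str:
    return resources.files("visdemand.data").joinpath(name).read_text()


def schema_from_mapping(data: Mapping) -> list[ClassifierSpec]:
    specs = [
        ClassifierSpec(name=c["name"], categories=tuple(str(x) for x in c["categories"]))
        for c in data["classifiers"]
    ]
    names = [s.name for s in specs]
    if len(set(names)) != len(names):
        raise ValueError("classifier names must be unique across the schema")
    return specs


def schema_to_mapping(schema: Sequence[ClassifierSpec]) -> dict:
    return {
        "version": 1,
        "classifiers": [
            {"name": s.name, "categories": list(s.categories)} for s in schema
        ],
    }


def load_schema(path: str | None = None) -> list[ClassifierSpec]:
    """Load a coding schema from YAML; default is the shipped 14-classifier schema."""
    if path is None:
        data = yaml.safe_load(_data_text("scene_schema.yaml"))
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    return schema_from_mapping(data)


_DEFAULT_SCHEMA: list[ClassifierSpec] | None = None


def default_schema() -> list[ClassifierSpec]:
    global _DEFAULT_SCHEMA
    if _DEFAULT_SCHEMA is None:
        _DEFAULT_SCHEMA = load_schema()
    return list(_DEFAULT_SCHEMA)


def load_task_vocabulary(path: str | None = None) -> TaskVocabulary:
    """Load the task vocabulary; default is the shipped 48-item + bespoke file."""
    if path is None:
        data = yaml.safe_load(_data_text("task_vocabulary.yaml"))
    else:
        with open(path) as fh:
            data = yaml.safe_load(fh)
    vocab = TaskVocabulary(
        vfq48=tuple(data["vfq48"]),
        bespoke=tuple(data.get("bespoke", ())),
        provisional=bool(data.get("provisional", True)),
    )
    if len(vocab.vfq48) != 48:
        raise ValueError(f"expected 48 questionnaire items, got {len(vocab.vfq48)}")
    return vocab


def _norm(label: str) -> str:
    return re.sub(r"\s+", " ", label.strip()).casefold()


def validate_scene_code(
    code: SceneCode, schema: Sequence[ClassifierSpec] | None = None
) -> SceneCode:
    """Check a scene code against the schema; returns it unchanged if valid.

    Values match categories case-insensitively with whitespace collapsed
    and are canonicalized to the schema spelling.
    """
    schema = schema if schema is not None else default_schema()
    canonical: dict[str, str] = {}
    for spec in schema:
        if spec.name not in code.values:
            raise MissingClassifierError(
                f"snapshot {code.snapshot_id!r}: missing classifier {spec.name!r}"
            )
        value = code.values[spec.name]
        by_norm = {_norm(c): c for c in spec.categories}
        hit = by_norm.get(_norm(str(value)))
        if hit is None:
            raise SchemaValidationError(
                f"snapshot {code.snapshot_id!r}: value {value!r} not in "
                f"classifier {spec.name!r} categories {list(spec.categories)}"
            )
        canonical[spec.name] = hit
    code.values.update(canonical)
    return code


def bin_time_of_day(timestamp: _dt.time | str) -> str:
    """Assign a clock time to one of the four six-hour bins.

    Bins are lower-inclusive / upper-exclusive: 06:00 falls in "6-12",
    05:59 in "0-6".
    """
    if isinstance(timestamp, str):
        timestamp = _dt.time.fromisoformat(timestamp)
    h = timestamp.hour
    if 6 <= h < 12:
        return "6-12"
    if 12 <= h < 18:
        return "12-18"
    if 18 <= h < 24:
        return "18-24"
    return "0-6"


def simplify_difficulty(rating: str) -> str:
    """Collapse the six-point difficulty scale to a binary ability flag.

    Only "unable" denotes failure to complete the task alone; every other
    level (including "very difficult") maps to ``able_alone``.
    """
    norm = _norm(rating)
    if norm not in DIFFICULTY_LEVELS:
        raise SchemaValidationError(
            f"unknown difficulty level {rating!r}; expected one of {DIFFICULTY_LEVELS}"
        )
    return "unable_alone" if norm == "unable" else "able_alone"


def map_task(
    label: str, vocabulary: TaskVocabulary | None = None
) -> tuple[str, bool]:
    """Match a curated task label against the 48-item vocabulary.

    Matching is case-insensitive with whitespace collapsed. Returns the
    canonical label and an ``is_bespoke`` flag — True for any label outside
    the 48-item inventory (known bespoke labels are canonicalized too).
    """
    if not label or not label.strip():
        raise SchemaValidationError("empty task label")
    vocabulary = vocabulary or load_task_vocabulary()
    norm = _norm(label)
    for item in vocabulary.vfq48:
        if _norm(item) == norm:
            return item, False
    for item in vocabulary.bespoke:
        if _norm(item) == norm:
            return item, True
    return re.sub(r"\s+", " ", label.strip()), True


def percent_agreement(
    codes_a: Sequence[SceneCode], codes_b: Sequence[SceneCode]
) -> AgreementReport:
    """Raw per-classifier percent agreement between two coders.

    Items are paired by snapshot_id; both lists must cover the same
    snapshots and the same classifiers. Symmetric in its arguments.
    """
    if len(codes_a) != len(codes_b):
        raise PairingError(
            f"coder lists differ in length: {len(codes_a)} vs {len(codes_b)}"
        )
    if not codes_a:
        raise PairingError("empty coder lists")
    by_id_b = {c.snapshot_id: c for c in codes_b}
    if len(by_id_b) != len(codes_b) or len({c.snapshot_id for c in codes_a}) != len(codes_a):
        raise PairingError("duplicate snapshot_ids within a coder list")
    if set(by_id_b) != {c.snapshot_id for c in codes_a}:
        raise PairingError("coder lists cover different snapshot_ids")

    classifiers = list(codes_a[0].values)
    matches = {name: 0 for name in classifiers}
    for a in codes_a:
        b = by_id_b[a.snapshot_id]
        if set(a.values) != set(classifiers) or set(b.values) != set(classifiers):
            raise PairingError(
                f"snapshot {a.snapshot_id!r}: classifier sets differ between items"
            )
        for name in classifiers:
            if _norm(a.values[name]) == _norm(b.values[name]):
                matches[name] += 1
    n = len(codes_a)
    return AgreementReport(
        per_classifier={name: 100.0 * m / n for name, m in matches.items()},
        n_items=n,
    )


def cohen_kappa(
    codes_a: Sequence[SceneCode], codes_b: Sequence[SceneCode], classifier: str
) -> float:
    """Chance-corrected agreement for one classifier (optional extra)."""
    by_id_b = {c.snapshot_id: c for c in codes_b}
    pairs = [
        (_norm(a.values[classifier]), _norm(by_id_b[a.snapshot_id].values[classifier]))
        for a in codes_a
    ]
    n = len(pairs)
    cats = sorted({v for p in pairs for v in p})
    po = sum(1 for a, b in pairs if a == b) / n
    pe = sum(
        (sum(1 for a, _ in pairs if a == c) / n) * (sum(1 for _, b in pairs if b == c) / n)
        for c in cats
    )
    if pe == 1.0:
        return 1.0
    return (po - pe) / (1 - pe)


def read_scene_codes(
    path: str, schema: Sequence[ClassifierSpec] | None = None, validate: bool = True
) -> list[SceneCode]:
    """Load scene codes from CSV (snapshot_id + one column per classifier)."""
    schema = schema if schema is not None else default_schema()
    df = pd.read_csv(path, dtype=str)
    if "snapshot_id" not in df.columns:
        raise ValueError("scene-code CSV must have a snapshot_id column")
    codes = []
    names = [s.name for s in schema]
    for _, row in df.iterrows():
        values = {n: row[n] for n in names if n in df.columns}
        code = SceneCode(snapshot_id=str(row["snapshot_id"]), values=values)
        if validate:
            validate_scene_code(code, schema)
        codes.append(code)
    return codes


def write_scene_codes(codes: Iterable[SceneCode], path: str) -> None:
    rows = [{"snapshot_id": c.snapshot_id, **c.values} for c in codes]
    pd.DataFrame(rows).to_csv(path, index=False)


def read_task_records(
    path: str, vocabulary: TaskVocabulary | None = None
) -> list[TaskRecord]:
    """Load task records from CSV, re-mapping labels against the vocabulary."""
    vocabulary = vocabulary or load_task_vocabulary()
    df = pd.read_csv(path)
    records = []
    for row in df.itertuples(index=False):
        label, bespoke = map_task(str(row.task_label), vocabulary)
        records.append(
            TaskRecord(
                participant_id=str(row.participant_id),
                snapshot_id=str(row.snapshot_id),
                narrative=str(getattr(row, "narrative", "")),
                task_label=label,
                is_bespoke=bespoke,
                able_alone=bool(getattr(row, "able_alone", True)),
                coping_used=bool(getattr(row, "coping_used", False)),
            )
        )
    return records


def write_task_records(records: Iterable[TaskRecord], path: str) -> None:
    rows = [
        {
            "participant_id": r.participant_id,
            "snapshot_id": r.snapshot_id,
            "narrative": r.narrative,
            "task_label": r.task_label,
            "is_bespoke": r.is_bespoke,
            "able_alone": r.able_alone,
            "coping_used": r.coping_used,
        }
        for r in records
    ]
    pd.DataFrame(rows).to_csv(path, index=False)
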