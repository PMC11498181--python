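"""Domain types and on-disk table I/O for free-report experiments.

The atomic observation is one word slot of one trial: a participant saw an
image briefly, typed up to five words describing their experience, and rated
each word's confidence on a 1-5 scale (1 "Don't Know" ... 5 "Very Confident").
An empty slot is a permitted response and must carry confidence 1, mirroring
the instruction to leave the box empty and answer "Don't Know".

All tables are UTF-8 CSV/TSV with a header row:

* ``responses.csv``  — participant_id, image_id, trial_index, slot, word,
  confidence and (optionally) arrival_rank.  When arrival_rank is absent it
  is derived from row order: the r-th distinct participant to reach an image
  gets rank r.  The rank drives the first-ten rule downstream.
* ``frequency.tsv``  — word <TAB> per_billion occurrence count.
* ``categories.csv`` — word, image_id, category.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Iterable, Mapping

import pandas as pd

__all__ = [
    "CATEGORIES",
    "RESPONSE_COLUMNS",
    "ValidationError",
    "ResponseRecord",
    "Experiment",
    "FrequencyTable",
    "CategoryLabelSet",
    "read_responses",
    "write_responses",
    "read_frequency_table",
    "write_frequency_table",
    "read_categories",
    "write_categories",
]

#: the five word categories used in the content analysis
CATEGORIES = ("exist", "conceptual", "insertion", "confusion", "unrelated")

RESPONSE_COLUMNS = ["participant_id", "image_id", "trial_index", "slot", "word", "confidence"]
OPTIONAL_RESPONSE_COLUMNS = ["arrival_rank"]


class ValidationError(ValueError):
    """Raised when a table or record violates a documented invariant."""

    def __init__(self, message: str, line: int | None = None):
        if line is not None:
            message = f"line {line}: {message}"
        super().__init__(message)
        self.line = line


@dataclass(frozen=True)
class ResponseRecord:
    """One (participant, image, word slot) observation.

    ``arrival_rank`` is the order in which the participant reached the image
    relative to the image's other respondents (1 = first); the IA analysis
    keeps only ranks 1-10.
    """

    participant_id: str
    image_id: str
    trial_index: int
    slot: int
    raw_word: str
    confidence: int
    arrival_rank: int

    def validate(self, line: int | None = None) -> None:
        if self.confidence not in (1, 2, 3, 4, 5):
            raise ValidationError(
                f"confidence must be in 1..5, got {self.confidence!r}", line
            )
        if not 1 <= self.slot <= 5:
            raise ValidationError(f"slot must be in 1..5, got {self.slot!r}", line)
        if self.trial_index < 0:
            raise ValidationError(f"trial_index must be >= 0, got {self.trial_index!r}", line)
        if self.arrival_rank < 1:
            raise ValidationError(f"arrival_rank must be >= 1, got {self.arrival_rank!r}", line)
        if self.raw_word == "" and self.confidence != 1:
            raise ValidationError(
                "empty word requires confidence 1 ('Don't Know'), "
                f"got confidence {self.confidence}",
                line,
            )


@dataclass
class Experiment:
    """A named collection of response records under one stimulus condition."""

    name: str
    records: list[ResponseRecord] = field(default_factory=list)
    condition_tag: str = "intact"

    def validate(self) -> None:
        seen: set[tuple[str, str, int]] = set()
        ranks: dict[str, dict[str, int]] = {}
        for rec in self.records:
            rec.validate()
            key = (rec.participant_id, rec.image_id, rec.slot)
            if key in seen:
                raise ValidationError(
                    f"duplicate (participant, image, slot) triple {key}"
                )
            seen.add(key)
            ranks.setdefault(rec.image_id, {}).setdefault(rec.participant_id, rec.arrival_rank)
        for image_id, by_participant in ranks.items():
            got = sorted(by_participant.values())
            if got != list(range(1, len(got) + 1)):
                raise ValidationError(
                    f"image {image_id!r}: arrival ranks must be 1..R without gaps, got {got}"
                )

    @property
    def image_ids(self) -> list[str]:
        out: list[str] = []
        seen: set[str] = set()
        for rec in self.records:
            if rec.image_id not in seen:
                seen.add(rec.image_id)
                out.append(rec.image_id)
        return out

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(
            [
                (r.participant_id, r.image_id, r.trial_index, r.slot,
                 r.raw_word, r.confidence, r.arrival_rank)
                for r in self.records
            ],
            columns=RESPONSE_COLUMNS + OPTIONAL_RESPONSE_COLUMNS,
        )


@dataclass
class FrequencyTable:
    """Map word -> occurrences per billion words of text.

    The Zipf frequency of a word is log10 of its per-billion count, so a
    count of 1000 per billion is Zipf 3.
    """

    per_billion: dict[str, float] = field(default_factory=dict)

    def zipf(self, word: str) -> float:
        return math.log10(self.per_billion[word])

    def __contains__(self, word: str) -> bool:
        return word in self.per_billion

    def __len__(self) -> int:
        return len(self.per_billion)

    def words(self) -> list[str]:
        return list(self.per_billion)

    def validate(self) -> None:
        for word, count in self.per_billion.items():
            if not (count > 0 and math.isfinite(count)):
                raise ValidationError(
                    f"word {word!r}: per-billion count must be finite and > 0, got {count!r}"
                )


@dataclass
class CategoryLabelSet:
    """Map (word, image_id) -> one of the five word categories."""

    labels: dict[tuple[str, str], str] = field(default_factory=dict)

    def validate(self) -> None:
        for (word, image_id), cat in self.labels.items():
            if cat not in CATEGORIES:
                raise ValidationError(
                    f"({word!r}, {image_id!r}): unknown category {cat!r}; "
                    f"expected one of {CATEGORIES}"
                )

    def get(self, word: str, image_id: str) -> str | None:
        return self.labels.get((word, image_id))


# ---------------------------------------------------------------------------
# readers / writers


def _derive_arrival_ranks(df: pd.DataFrame) -> pd.Series:
    """Rank distinct participants per image by first appearance in the file."""
    ranks = pd.Series(0, index=df.index, dtype=int)
    counter: dict[str, dict[str, int]] = {}
    for idx, row in df.iterrows():
        per_image = counter.setdefault(row["image_id"], {})
        if row["participant_id"] not in per_image:
            per_image[row["participant_id"]] = len(per_image) + 1
        ranks.at[idx] = per_image[row["participant_id"]]
    return ranks


def read_responses(path: str | Path, name: str | None = None,
                   condition_tag: str = "intact") -> Experiment:
    """Read a responses.csv file into a validated :class:`Experiment`.

    Row order is preserved.  ``arrival_rank`` is taken from the file when the
    column is present, otherwise derived from row order per image.  Errors
    name the 1-based file line (header is line 1).
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    missing = [c for c in RESPONSE_COLUMNS if c not in df.columns]
    if missing:
        raise ValidationError(f"missing required columns {missing} in {path.name}")
    unknown = [c for c in df.columns
               if c not in RESPONSE_COLUMNS + OPTIONAL_RESPONSE_COLUMNS]
    if unknown:
        raise ValidationError(f"unknown columns {unknown} in {path.name}")

    if "arrival_rank" not in df.columns:
        df = df.assign(arrival_rank=_derive_arrival_ranks(df).astype(str))

    records: list[ResponseRecord] = []
    for idx, row in df.iterrows():
        line = int(idx) + 2  # header is line 1
        try:
            rec = ResponseRecord(
                participant_id=row["participant_id"],
                image_id=row["image_id"],
                trial_index=int(row["trial_index"]),
                slot=int(row["slot"]),
                raw_word=row["word"],
                confidence=int(row["confidence"]) if row["confidence"] != "" else 0,
                arrival_rank=int(row["arrival_rank"]),
            )
        except ValueError as err:
            raise ValidationError(f"malformed row: {err}", line) from err
        rec.validate(line=line)
        records.append(rec)

    exp = Experiment(name=name or path.stem, records=records, condition_tag=condition_tag)
    exp.validate()
    return exp


def write_responses(exp: Experiment, path: str | Path) -> Path:
    """Write an experiment to CSV such that reading it back reproduces it."""
    exp.validate()
    path = Path(path)
    exp.to_frame().to_csv(path, index=False, encoding="utf-8")
    return path


def read_frequency_table(path: str | Path) -> FrequencyTable:
    """Read a two-column ``word<TAB>per_billion`` TSV (header required).

    Duplicate words keep the last entry (a warning is emitted); non-positive
    counts are rejected because the Zipf value log10(count) must be finite.
    """
    import warnings

    path = Path(path)
    df = pd.read_csv(path, sep="\t", dtype={"word": str}, keep_default_na=False,
                     encoding="utf-8")
    if list(df.columns[:2]) != ["word", "per_billion"]:
        raise ValidationError(
            f"expected columns ['word', 'per_billion'], got {list(df.columns)}"
        )
    table: dict[str, float] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        count = float(row["per_billion"])
        if not (count > 0 and math.isfinite(count)):
            raise ValidationError(
                f"per-billion count for {row['word']!r} must be > 0, got {count}", line
            )
        if row["word"] in table:
            warnings.warn(f"duplicate word {row['word']!r} at line {line}; last wins")
        table[row["word"]] = count
    return FrequencyTable(per_billion=table)


def write_frequency_table(ft: FrequencyTable, path: str | Path) -> Path:
    ft.validate()
    path = Path(path)
    pd.DataFrame(
        {"word": list(ft.per_billion), "per_billion": list(ft.per_billion.values())}
    ).to_csv(path, sep="\t", index=False, encoding="utf-8")
    return path


def read_categories(path: str | Path) -> CategoryLabelSet:
    """Read a (word, image_id, category) CSV; unknown category strings are rejected."""
    path = Path(path)
    df = pd.read_csv(path, dtype=str, keep_default_na=False, encoding="utf-8")
    expected = ["word", "image_id", "category"]
    if list(df.columns[:3]) != expected:
        raise ValidationError(f"expected columns {expected}, got {list(df.columns)}")
    labels: dict[tuple[str, str], str] = {}
    for idx, row in df.iterrows():
        line = int(idx) + 2
        if row["category"] not in CATEGORIES:
            raise ValidationError(
                f"unknown category {row['category']!r}; expected one of {CATEGORIES}",
                line,
            )
        labels[(row["word"], row["image_id"])] = row["category"]
    out = CategoryLabelSet(labels=labels)
    out.validate()
    return out


def write_categories(labels: CategoryLabelSet, path: str | Path) -> Path:
    labels.validate()
    path = Path(path)
    pd.DataFrame(
        [(w, i, c) for (w, i), c in labels.labels.items()],
        columns=["word", "image_id", "category"],
    ).to_csv(path, index=False, encoding="utf-8")
    return path
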