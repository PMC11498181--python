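"""Word intersubjective-agreement (IA) scoring.

The IA of a word-image pair measures how specifically that word picks out
that image: ten respondents each contributed five words for every image, and
a word's score compares how often it recurs *within* the target image's
10 x 5 response matrix against how often it occurs in every *other* image's
matrix.  Formally, for a target word found in k >= 2 rows of the target
matrix:

* the within-image ratio is (k - 1)/9 — the number of additional rows
  containing the word, over the nine other rows;
* for each row containing the word, a between-image ratio is computed for
  every other image by deleting the corresponding row of that image's matrix
  and counting, out of the remaining nine rows, how many contain the word;
* the between ratios are binned (0/9 ... 9/9), turned into cumulative
  counts, and an ROC curve is built with the cumulative within ratio as
  true-positive rate and the cumulative between ratio as false-positive
  rate; the area under this curve is the row's AUC;
* the word IA is the mean AUC over the k rows containing the word.

A word reported by a single respondent for an image is "rarely reported"
and receives no score there.  Ratios are carried as exact integer ninths
(numerators 0-9) until the AUC step, so threshold ties are detected
exactly.  The trapezoidal integration of the binned curve makes the AUC
equal to the tie-aware rank statistic (#below + 0.5 #ties) / n_images — an
equality asserted by the test suite against :func:`word_ia_oracle`, an
independent brute-force enumeration.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from fractions import Fraction
from typing import Iterable, Literal, Mapping, Sequence

import numpy as np
import pandas as pd

from .io_model import Experiment, ValidationError

__all__ = [
    "ResponseMatrix",
    "RatioDistribution",
    "WordIAScore",
    "build_response_matrices",
    "scorable_words",
    "within_ratio",
    "between_ratios",
    "auc_from_curves",
    "word_ia",
    "word_ia_oracle",
    "compute_all_ia",
]

logger = logging.getLogger(__name__)

N_ROWS = 10
N_SLOTS = 5

RowMatching = Literal["index", "participant"]


class RareWordError(ValueError):
    """The target word is reported by fewer than two respondents."""


class UndefinedScoreError(ValueError):
    """No comparison images exist, so no AUC can be formed."""


@dataclass
class ResponseMatrix:
    """One image's 10-row (respondents, by arrival rank) x 5-column word grid.

    Cells hold processed lemmas or ``None`` for empty/dropped slots; within a
    row all present lemmas are distinct.  ``confidences`` mirrors the grid.
    """

    image_id: str
    words: list[list[str | None]]
    confidences: list[list[int | None]]
    row_participants: list[str]
    _row_sets: dict[str, frozenset[int]] | None = field(default=None, repr=False)

    def validate(self) -> None:
        if len(self.words) != N_ROWS:
            raise ValidationError(
                f"image {self.image_id!r}: expected {N_ROWS} rows, got {len(self.words)}"
            )
        for i, row in enumerate(self.words):
            if len(row) != N_SLOTS:
                raise ValidationError(
                    f"image {self.image_id!r} row {i}: expected {N_SLOTS} slots"
                )
            present = [w for w in row if w]
            if len(present) != len(set(present)):
                raise ValidationError(
                    f"image {self.image_id!r} row {i}: duplicate lemma within a row"
                )

    def row_sets(self) -> dict[str, frozenset[int]]:
        """Map word -> set of row indices containing it (cached)."""
        if self._row_sets is None:
            acc: dict[str, set[int]] = {}
            for i, row in enumerate(self.words):
                for w in row:
                    if w:
                        acc.setdefault(w, set()).add(i)
            self._row_sets = {w: frozenset(s) for w, s in acc.items()}
        return self._row_sets

    def rows_with(self, word: str) -> frozenset[int]:
        return self.row_sets().get(word, frozenset())

    def confidence_of(self, word: str, row: int) -> int | None:
        for slot, w in enumerate(self.words[row]):
            if w == word:
                return self.confidences[row][slot]
        return None


@dataclass
class RatioDistribution:
    """Histogram of between-image ratios over the ten possible ninths."""

    bins: tuple[int, ...]  # counts indexed by numerator 0..9
    n_images: int

    def __post_init__(self) -> None:
        if len(self.bins) != N_ROWS:
            raise ValidationError(f"expected {N_ROWS} bins, got {len(self.bins)}")
        if sum(self.bins) != self.n_images:
            raise ValidationError(
                f"bin counts sum to {sum(self.bins)}, expected n_images={self.n_images}"
            )

    def cumulative(self) -> np.ndarray:
        """Cumulative count of images with ratio >= t/9, for t = 9 down to 0."""
        return np.cumsum(np.asarray(self.bins)[::-1])


@dataclass
class WordIAScore:
    word: str
    image_id: str
    k: int
    within_ratio: Fraction
    per_row_auc: list[float]
    ia: float


# ---------------------------------------------------------------------------
# matrix construction


def _processed_frame(exp: Experiment | pd.DataFrame) -> pd.DataFrame:
    if isinstance(exp, Experiment):
        df = exp.to_frame().rename(columns={"word": "raw_word"})
        df["word"] = df["raw_word"]
        df["dropped"] = df["word"] == ""
        return df
    return exp


def build_response_matrices(
    exp: Experiment | pd.DataFrame,
) -> dict[str, ResponseMatrix]:
    """Assemble per-image response matrices from a preprocessed experiment.

    Only the first ten respondents per image (lowest ``arrival_rank``) enter
    the matrix; images with fewer than ten respondents are excluded with a
    logged warning, since the design requires ten respondents per image.
    """
    df = _processed_frame(exp)
    matrices: dict[str, ResponseMatrix] = {}
    for image_id, group in df.groupby("image_id", sort=False):
        by_rank = (
            group[["participant_id", "arrival_rank"]]
            .drop_duplicates("participant_id")
            .sort_values("arrival_rank", kind="stable")
        )
        if len(by_rank) < N_ROWS:
            logger.warning(
                "image %r has %d respondents (<%d); excluded from IA analysis",
                image_id, len(by_rank), N_ROWS,
            )
            continue
        keep = by_rank["participant_id"].head(N_ROWS).tolist()
        words = [[None] * N_SLOTS for _ in range(N_ROWS)]
        confs: list[list[int | None]] = [[None] * N_SLOTS for _ in range(N_ROWS)]
        row_of = {p: i for i, p in enumerate(keep)}
        for rec in group.itertuples(index=False):
            row = row_of.get(rec.participant_id)
            if row is None or getattr(rec, "dropped", False) or not rec.word:
                continue
            words[row][rec.slot - 1] = rec.word
            confs[row][rec.slot - 1] = int(rec.confidence)
        m = ResponseMatrix(
            image_id=image_id, words=words, confidences=confs, row_participants=keep
        )
        m.validate()
        matrices[image_id] = m
    return matrices


# ---------------------------------------------------------------------------
# per-pair scoring


def scorable_words(m: ResponseMatrix) -> set[str]:
    """Words reported by at least two respondents of this image."""
    return {w for w, rows in m.row_sets().items() if len(rows) >= 2}


def within_ratio(m: ResponseMatrix, word: str, row: int) -> Fraction:
    """Additional occurrences of ``word`` beyond the queried row, over nine."""
    rows = m.rows_with(word)
    if row not in rows:
        raise ValueError(f"word {word!r} not present in row {row} of {m.image_id!r}")
    if len(rows) < 2:
        raise RareWordError(f"word {word!r} reported once in image {m.image_id!r}")
    return Fraction(len(rows) - 1, 9)


def _between_numerator(
    other: ResponseMatrix,
    word: str,
    row_index: int,
    participant_id: str | None,
    row_matching: RowMatching,
) -> int:
    """Occurrences of ``word`` in ``other`` after deleting the corresponding row."""
    rows = other.rows_with(word)
    if row_matching == "participant" and participant_id is not None:
        if participant_id in other.row_participants:
            drop = other.row_participants.index(participant_id)
        else:
            drop = row_index
    else:
        drop = row_index
    return len(rows) - (1 if drop in rows else 0)


def between_ratios(
    all_m: Mapping[str, ResponseMatrix],
    target_image: str,
    word: str,
    row_index: int,
    row_matching: RowMatching = "index",
) -> RatioDistribution:
    """Distribution of the word's leave-one-row-out counts over all other images.

    For every non-target image, the row corresponding to the target row is
    removed and the occurrences of the word among the remaining nine rows
    are counted; counts are binned by numerator 0..9.
    """
    target = all_m[target_image]
    participant = target.row_participants[row_index]
    bins = [0] * N_ROWS
    n = 0
    for image_id, other in all_m.items():
        if image_id == target_image:
            continue
        bins[_between_numerator(other, word, row_index, participant, row_matching)] += 1
        n += 1
    return RatioDistribution(bins=tuple(bins), n_images=n)


def auc_from_curves(within: Fraction | int, between: RatioDistribution) -> float:
    """AUC of the ROC built from cumulative within- vs between-image ratios.

    Thresholds sweep t = 9/9 down to 0/9.  At threshold t the true-positive
    rate is 1 if the within ratio >= t/9 (the within "distribution" is a
    single value) and the false-positive rate is the fraction of other
    images whose between ratio >= t/9.  The point (0, 0) is prepended and
    the curve is integrated by the trapezoid rule, which resolves threshold
    ties the same way the tie-aware rank statistic does.
    """
    if between.n_images < 1:
        raise UndefinedScoreError("no comparison images: AUC undefined")
    c = within.numerator * (9 // within.denominator) if isinstance(within, Fraction) else int(within)
    cum = between.cumulative()  # images with ratio >= t/9, t = 9..0
    fpr = np.concatenate([[0.0], cum / between.n_images])
    tpr = np.concatenate([[0.0], [1.0 if c >= t else 0.0 for t in range(9, -1, -1)]])
    return float(np.trapezoid(tpr, fpr))


def word_ia(
    all_m: Mapping[str, ResponseMatrix],
    target_image: str,
    word: str,
    row_matching: RowMatching = "index",
) -> WordIAScore:
    """IA score of one word-image pair: mean per-row AUC over the k rows.

    The between distribution is rebuilt for every row containing the word,
    because the deleted row index differs from row to row.
    """
    target = all_m[target_image]
    rows = sorted(target.rows_with(word))
    if len(rows) < 2:
        raise RareWordError(
            f"word {word!r} reported by {len(rows)} respondent(s) in {target_image!r}"
        )
    w = Fraction(len(rows) - 1, 9)
    aucs = [
        auc_from_curves(w, between_ratios(all_m, target_image, word, r, row_matching))
        for r in rows
    ]
    return WordIAScore(
        word=word,
        image_id=target_image,
        k=len(rows),
        within_ratio=w,
        per_row_auc=aucs,
        ia=float(np.mean(aucs)),
    )


def word_ia_oracle(
    all_m: Mapping[str, ResponseMatrix], target_image: str, word: str
) -> float:
    """Brute-force IA by direct enumeration; no binning, no curves.

    For each target row containing the word, every other image's matrix is
    scanned cell by cell: the row at the same index is skipped, occurrences
    in the remaining rows are counted, and explicit below/equal/above
    tallies against the within count give the tie-aware rank AUC
    (below + 0.5 equal) / n_other.  Exists solely to cross-check
    :func:`word_ia`.
    """
    target = all_m[target_image]
    target_rows = [
        i for i, row in enumerate(target.words) if any(cell == word for cell in row)
    ]
    if len(target_rows) < 2:
        raise RareWordError(f"word {word!r} unscorable in image {target_image!r}")
    within_count = len(target_rows) - 1
    others = [m for img, m in all_m.items() if img != target_image]
    if not others:
        raise UndefinedScoreError("no comparison images")
    aucs = []
    for r in target_rows:
        below = equal = 0
        for other in others:
            count = 0
            for i, row in enumerate(other.words):
                if i == r:
                    continue
                if any(cell == word for cell in row):
                    count += 1
            if count < within_count:
                below += 1
            elif count == within_count:
                equal += 1
        aucs.append((below + 0.5 * equal) / len(others))
    return sum(aucs) / len(aucs)


def compute_all_ia(
    exp: Experiment | pd.DataFrame | Mapping[str, ResponseMatrix],
    row_matching: RowMatching = "index",
) -> pd.DataFrame:
    """Score every scorable word-image pair of a preprocessed experiment.

    Returns a tidy table with one row per pair: word, image_id, k (number of
    rows reporting the word), within_ratio, ia.  The same word scored for
    different images yields independent rows.
    """
    if isinstance(exp, Mapping):
        matrices = dict(exp)
    else:
        matrices = build_response_matrices(exp)
    if len(set(matrices)) != len(matrices):
        raise ValidationError("duplicate image ids")
    out = []
    for image_id, m in matrices.items():
        for word in sorted(scorable_words(m)):
            s = word_ia(matrices, image_id, word, row_matching)
            out.append((s.word, s.image_id, s.k, float(s.within_ratio), s.ia))
    return pd.DataFrame(out, columns=["word", "image_id", "k", "within_ratio", "ia"])
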