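"""Free-report word preprocessing: normalize, correct, lemmatize, dedupe.

The chain mirrors how free verbal reports are cleaned before agreement
scoring:

1. **normalize** — lowercase, strip, collapse internal whitespace to a
   single hyphen, and spell out bare integers 0-100 ("2" -> "two");
2. **correct**  — a spell-checking provider proposes corrections which are
   collected into an auditable :class:`CorrectionLedger`; only entries
   marked accepted are applied (the original workflow reviewed each
   suggestion by hand — e.g. "holiaday" -> "holiday" accepted while
   "red-dot" -> "reddit" rejected — so acceptance defaults to False,
   with an optional conservative auto-accept heuristic);
3. **lemmatize** — a lemmatizer proposes lemmas into a :class:`LemmaLedger`;
   proposals are auto-accepted unless the lemma is suspiciously short for a
   hyphenated source (the "t-shirt" -> "t" rejection class);
4. **dedupe** — within one trial a participant's words must be unique, so
   later repetitions of a lemma are dropped, as are empty slots.

Providers are pluggable callables so any spell checker or lemmatizer can be
swapped in; built-ins based on a frequency dictionary are provided.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Callable, Iterable, Mapping, Protocol

import pandas as pd

from .io_model import Experiment, FrequencyTable, ResponseRecord, ValidationError

__all__ = [
    "ProcessedWord",
    "LedgerEntry",
    "CorrectionLedger",
    "LemmaLedger",
    "normalize_token",
    "propose_corrections",
    "propose_lemmas",
    "apply_ledger",
    "dedupe_trials",
    "preprocess",
    "PreprocessResult",
    "FrequencySpellChecker",
    "RuleLemmatizer",
    "read_ledger",
    "write_ledger",
]

logger = logging.getLogger(__name__)

PROCESSED_COLUMNS = [
    "participant_id", "image_id", "trial_index", "slot", "raw_word",
    "word", "confidence", "arrival_rank", "dropped", "drop_reason",
]

_ONES = ["zero", "one", "two", "three", "four", "five", "six", "seven",
         "eight", "nine", "ten", "eleven", "twelve", "thirteen", "fourteen",
         "fifteen", "sixteen", "seventeen", "eighteen", "nineteen"]
_TENS = {20: "twenty", 30: "thirty", 40: "forty", 50: "fifty",
         60: "sixty", 70: "seventy", 80: "eighty", 90: "ninety"}


def _int_to_words(n: int) -> str:
    """English name of an integer 0-100 ('42' -> 'forty-two')."""
    if n < 20:
        return _ONES[n]
    if n == 100:
        return "one-hundred"
    tens, ones = divmod(n, 10)
    word = _TENS[tens * 10]
    return f"{word}-{_ONES[ones]}" if ones else word


@dataclass(frozen=True)
class ProcessedWord:
    """One token's trajectory through the preprocessing chain."""

    raw: str
    normalized: str
    corrected: str
    lemma: str
    dropped: bool = False
    drop_reason: str | None = None  # 'empty' | 'duplicate-in-trial'


@dataclass
class LedgerEntry:
    token: str
    replacement: str | None
    accepted: bool = False


@dataclass
class CorrectionLedger:
    """Audit trail of spell-checker suggestions; only accepted ones apply."""

    entries: dict[str, LedgerEntry] = field(default_factory=dict)

    def accept(self, token: str) -> None:
        self.entries[token].accepted = True

    def reject(self, token: str) -> None:
        self.entries[token].accepted = False

    def resolve(self, token: str) -> str:
        """The replacement for ``token`` if accepted, else the token itself."""
        e = self.entries.get(token)
        if e is None or not e.accepted or e.replacement is None:
            return token
        if e.replacement == "":
            raise ValidationError(f"ledger replacement for {token!r} is empty")
        return e.replacement


class LemmaLedger(CorrectionLedger):
    """Same audit structure, for lemmatization proposals."""


# ---------------------------------------------------------------------------
# providers


class SpellingProvider(Protocol):
    def __call__(self, token: str) -> str | None:
        """Return a suggested correction, or None if the token looks fine."""


class LemmaProvider(Protocol):
    def __call__(self, token: str) -> str:
        """Return the lemma of the token (the token itself if already a lemma)."""


def _edits1(word: str) -> set[str]:
    letters = "abcdefghijklmnopqrstuvwxyz"
    splits = [(word[:i], word[i:]) for i in range(len(word) + 1)]
    deletes = {a + b[1:] for a, b in splits if b}
    transposes = {a + b[1] + b[0] + b[2:] for a, b in splits if len(b) > 1}
    replaces = {a + c + b[1:] for a, b in splits if b for c in letters}
    inserts = {a + c + b for a, b in splits for c in letters}
    return deletes | transposes | replaces | inserts


class FrequencySpellChecker:
    """Dictionary-backed spell checker over a word-frequency table.

    A token absent from the dictionary is flagged and the highest-frequency
    candidate within edit distance 2 is suggested (distance-1 candidates
    preferred).  Hyphenated tokens are accepted when all their parts are
    known.  ``None`` means the token looks fine or nothing close was found.
    """

    def __init__(self, table: FrequencyTable | Mapping[str, float]):
        self.counts = dict(table.per_billion if isinstance(table, FrequencyTable) else table)

    def __call__(self, token: str) -> str | None:
        if not token or token in self.counts:
            return None
        if "-" in token and all(p in self.counts for p in token.split("-") if p):
            return None
        e1 = _edits1(token)
        known1 = [w for w in e1 if w in self.counts]
        if known1:
            return max(known1, key=self.counts.get)
        known2 = [w for c in e1 for w in _edits1(c) if w in self.counts]
        if known2:
            return max(known2, key=self.counts.get)
        return None


class RuleLemmatizer:
    """Suffix-stripping English lemmatizer validated against a vocabulary.

    Handles regular plural/verbal inflections (-s, -es, -ies, -ing, -ed) and
    a small irregular table; a stripped stem is only returned when it occurs
    in the vocabulary, so unknown words pass through unchanged.
    """

    _IRREGULAR = {
        "men": "man", "women": "woman", "children": "child", "feet": "foot",
        "teeth": "tooth", "mice": "mouse", "geese": "goose", "people": "person",
        "ran": "run", "went": "go", "better": "good", "left": "leave",
    }

    def __init__(self, vocabulary: Iterable[str]):
        self.known = set(vocabulary)

    def _candidates(self, token: str) -> list[str]:
        cands: list[str] = []
        if token.endswith("ies") and len(token) > 4:
            cands.append(token[:-3] + "y")
        if token.endswith("es") and len(token) > 3:
            cands.append(token[:-2])
        if token.endswith("s") and not token.endswith(("ss", "us", "is")) and len(token) > 2:
            cands.append(token[:-1])
        if token.endswith("ing") and len(token) > 4:
            stem = token[:-3]
            cands += [stem + "e", stem]
            if len(stem) > 2 and stem[-1] == stem[-2]:
                cands.append(stem[:-1])
        if token.endswith("ed") and len(token) > 3:
            stem = token[:-2]
            cands += [stem + "e" if not stem.endswith("e") else stem, stem]
            if len(stem) > 2 and stem[-1] == stem[-2]:
                cands.append(stem[:-1])
        return cands

    def __call__(self, token: str) -> str:
        if token in self._IRREGULAR:
            return self._IRREGULAR[token]
        for cand in self._candidates(token):
            if cand in self.known:
                return cand
        return token


# ---------------------------------------------------------------------------
# operations


def normalize_token(raw: str) -> str:
    """Lowercase, hyphenate internal whitespace, spell out integers 0-100.

    Total on all strings; the empty string maps to itself (it is dropped
    later with reason ``empty``).
    """
    token = "-".join(raw.strip().lower().split())
    # isascii guard: unicode digits like '¹' pass isdigit but not int()
    if token.isascii() and token.isdigit() and 0 <= int(token) <= 100:
        return _int_to_words(int(token))
    return token


def propose_corrections(
    tokens: Iterable[str], provider: SpellingProvider
) -> CorrectionLedger:
    """Run the spell provider over a token set; nothing is applied yet.

    Every flagged token gets a ledger entry with ``accepted=False``; provider
    failures are recorded with ``replacement=None`` and logged.
    """
    ledger = CorrectionLedger()
    for token in sorted(set(tokens)):
        try:
            suggestion = provider(token)
        except Exception as err:  # provider failure is not fatal
            logger.warning("spell provider failed on %r: %s", token, err)
            ledger.entries[token] = LedgerEntry(token, None, accepted=False)
            continue
        if suggestion is not None and suggestion != token:
            ledger.entries[token] = LedgerEntry(token, suggestion, accepted=False)
    return ledger


def auto_accept_corrections(
    ledger: CorrectionLedger, table: FrequencyTable, max_edit_distance: int = 2
) -> CorrectionLedger:
    """Conservative auto-accept: suggestion known to the dictionary and close.

    Stands in for the manual review of the original workflow; entries it
    leaves rejected can still be accepted by hand or via a ledger file.
    """
    for entry in ledger.entries.values():
        if entry.replacement and entry.replacement in table:
            if _edit_distance_le(entry.token, entry.replacement, max_edit_distance):
                entry.accepted = True
    return ledger


def _edit_distance_le(a: str, b: str, k: int) -> bool:
    if abs(len(a) - len(b)) > k:
        return False
    prev = list(range(len(b) + 1))
    for i, ca in enumerate(a, 1):
        cur = [i] + [0] * len(b)
        for j, cb in enumerate(b, 1):
            cur[j] = min(prev[j] + 1, cur[j - 1] + 1, prev[j - 1] + (ca != cb))
        prev = cur
    return prev[-1] <= k


def propose_lemmas(tokens: Iterable[str], provider: LemmaProvider) -> LemmaLedger:
    """Collect lemma proposals differing from their token.

    The default-accept rule is applied: proposals are accepted unless the
    lemma is at most two characters while the source token is hyphenated
    (catching degenerate splits like "t-shirt" -> "t").  Ledger files can
    override either way.
    """
    ledger = LemmaLedger()
    for token in sorted(set(tokens)):
        lemma = provider(token)
        if lemma == token:
            continue
        accepted = not (len(lemma) <= 2 and "-" in token)
        ledger.entries[token] = LedgerEntry(token, lemma, accepted=accepted)
    return ledger


def apply_ledger(exp: Experiment, ledger: CorrectionLedger) -> Experiment:
    """Apply accepted ledger entries to every record's word; idempotent.

    Idempotence holds when no accepted replacement is itself a ledger key
    mapping elsewhere (enforced here by resolving only once).
    """
    new_records = [
        replace(rec, raw_word=ledger.resolve(rec.raw_word)) for rec in exp.records
    ]
    return Experiment(name=exp.name, records=new_records, condition_tag=exp.condition_tag)


def dedupe_trials(df: pd.DataFrame) -> pd.DataFrame:
    """Enforce within-trial uniqueness on a processed table.

    Within each (participant, image) trial only the first occurrence (lowest
    slot) of each lemma survives; later duplicates are dropped with reason
    ``duplicate-in-trial`` and empty tokens with reason ``empty``.
    """
    df = df.copy()
    for (_, _), idx in df.groupby(["participant_id", "image_id"], sort=False).groups.items():
        seen: set[str] = set()
        for i in sorted(idx, key=lambda i: df.at[i, "slot"]):
            if df.at[i, "dropped"]:
                continue
            word = df.at[i, "word"]
            if word == "":
                df.at[i, "dropped"] = True
                df.at[i, "drop_reason"] = "empty"
            elif word in seen:
                df.at[i, "dropped"] = True
                df.at[i, "drop_reason"] = "duplicate-in-trial"
            else:
                seen.add(word)
    return df


@dataclass
class PreprocessResult:
    """Processed table plus the audit ledgers and drop accounting."""

    frame: pd.DataFrame
    corrections: CorrectionLedger
    lemmas: LemmaLedger
    drop_counts: dict[str, int]

    @property
    def surviving(self) -> pd.DataFrame:
        return self.frame[~self.frame["dropped"]]


def preprocess(
    exp: Experiment,
    spell_provider: SpellingProvider | None = None,
    lemma_provider: LemmaProvider | None = None,
    corrections: CorrectionLedger | None = None,
    lemmas: LemmaLedger | None = None,
    auto_accept: FrequencyTable | None = None,
) -> PreprocessResult:
    """Run the full normalize -> correct -> lemmatize -> dedupe chain.

    Ledgers passed in are used as-is; otherwise they are built from the
    providers (corrections all-rejected unless ``auto_accept`` supplies a
    dictionary for the conservative heuristic).  The chain is idempotent:
    feeding the surviving words back through yields the same table.
    """
    normalized = {rec.raw_word: normalize_token(rec.raw_word) for rec in exp.records}
    norm_tokens = {t for t in normalized.values() if t}

    if corrections is None:
        corrections = (
            propose_corrections(norm_tokens, spell_provider)
            if spell_provider
            else CorrectionLedger()
        )
        if auto_accept is not None:
            auto_accept_corrections(corrections, auto_accept)
    corrected = {t: corrections.resolve(t) for t in norm_tokens}

    if lemmas is None:
        lemmas = (
            propose_lemmas(set(corrected.values()), lemma_provider)
            if lemma_provider
            else LemmaLedger()
        )

    rows = []
    for rec in exp.records:
        norm = normalized[rec.raw_word]
        corr = corrected.get(norm, norm)
        lemma = lemmas.resolve(corr)
        rows.append((
            rec.participant_id, rec.image_id, rec.trial_index, rec.slot,
            rec.raw_word, lemma, rec.confidence, rec.arrival_rank, False, None,
        ))
    df = pd.DataFrame(rows, columns=PROCESSED_COLUMNS)
    df = dedupe_trials(df)

    drop_counts = df.loc[df["dropped"], "drop_reason"].value_counts().to_dict()
    drop_counts["surviving"] = int((~df["dropped"]).sum())
    drop_counts["total"] = len(df)
    logger.info("preprocessing drop report: %s", drop_counts)
    return PreprocessResult(
        frame=df, corrections=corrections, lemmas=lemmas, drop_counts=drop_counts
    )


# ---------------------------------------------------------------------------
# ledger I/O


def write_ledger(ledger: CorrectionLedger, path: str | Path) -> Path:
    path = Path(path)
    pd.DataFrame(
        [(e.token, "" if e.replacement is None else e.replacement, e.accepted)
         for e in ledger.entries.values()],
        columns=["token", "replacement", "accepted"],
    ).to_csv(path, index=False, encoding="utf-8")
    return path


def read_ledger(path: str | Path, kind: str = "correction") -> CorrectionLedger:
    df = pd.read_csv(path, dtype={"token": str, "replacement": str},
                     keep_default_na=False, encoding="utf-8")
    cls = LemmaLedger if kind == "lemma" else CorrectionLedger
    ledger = cls()
    for row in df.itertuples(index=False):
        accepted = str(row.accepted).strip().lower() in ("true", "1", "yes")
        ledger.entries[row.token] = LedgerEntry(
            row.token, row.replacement or None, accepted
        )
    return ledger
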