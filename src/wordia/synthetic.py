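"""Synthetic free-report experiments with known generative structure.

The generator emulates the design of the masked-scene free-report study the
pipeline analyses: ~388 images, each seen by ten different respondents, 21
trials per participant, five unique words plus a 1-5 confidence rating per
trial.  Every emitted token carries a latent category label:

* ``exist``      — a word from the image's private content pool (with
  probability ``specificity``) or from the frequency-weighted shared
  vocabulary (otherwise); specificity is the knob that makes reports more
  or less image-diagnostic;
* ``conceptual`` — an abstract/sentiment word from a shared pool;
* ``insertion``  — a gist-congruent word for an item absent from the image;
* ``confusion``  — a word from an alternative (wrong) gist of the image;
* ``unrelated``  — a frequency-weighted draw from the whole vocabulary.

Word base frequencies follow a Zipf power law (rank^-exponent), and all
pools are sampled frequency-weighted, so common words recur across images —
the lexical structure behind the negative IA-frequency correlation the
analysis probes.  Confidence is a rounded, clamped normal draw centred on a
per-category mean, which lets recovery tests detect injected confidence
gaps between categories.

Everything is deterministic given the config seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Mapping

import numpy as np
import pandas as pd

from .io_model import (
    CATEGORIES,
    CategoryLabelSet,
    Experiment,
    FrequencyTable,
    ResponseRecord,
    ValidationError,
)

__all__ = [
    "SimulationConfig",
    "GroundTruth",
    "build_vocabulary",
    "generate_assignment",
    "simulate_experiment",
]


class ConfigError(ValueError):
    """A simulation config violates a structural constraint."""


@dataclass
class SimulationConfig:
    """Generative parameters of one synthetic experiment.

    Defaults reproduce the study's design scale: 388 images, ten respondents
    per image, 21 trials per participant (so 185 participants suffice), a
    Zipf-distributed vocabulary, existing-word dominance among reports, and
    higher confidence for existing than inserted words (gap 0.5 on the
    1-5 scale).
    """

    n_images: int = 388
    n_participants: int | None = None  # ceil(respondents * images / trials)
    trials_per_participant: int = 21
    respondents_per_image: int = 10
    vocab_size: int = 2000
    zipf_exponent: float = 1.0
    top_per_billion: float = 10 ** 7.5
    content_words_per_image: int = 10
    gist_words_per_image: int = 6
    altgist_words_per_image: int = 6
    conceptual_pool_size: int = 30
    specificity: float = 0.9
    category_rates: dict[str, float] = field(default_factory=lambda: {
        "exist": 0.70, "conceptual": 0.15, "insertion": 0.05,
        "confusion": 0.05, "unrelated": 0.05,
    })
    confidence_means: dict[str, float] = field(default_factory=lambda: {
        "exist": 4.2, "conceptual": 4.0, "insertion": 3.7,
        "confusion": 3.5, "unrelated": 3.5,
    })
    confidence_sd: float = 0.7
    empty_slot_rate: float = 0.02
    typo_rate: float = 0.0
    max_resample: int = 30
    seed: int = 0
    condition_tag: str = "intact"
    name: str = "synthetic"

    def __post_init__(self) -> None:
        if self.n_participants is None:
            self.n_participants = math.ceil(
                self.respondents_per_image * self.n_images / self.trials_per_participant
            )
        self.validate()

    def validate(self) -> None:
        if self.zipf_exponent < 0:
            raise ConfigError(f"zipf_exponent must be >= 0, got {self.zipf_exponent}")
        if self.vocab_size < 10:
            raise ConfigError("vocab_size must be >= 10")
        if not 0.0 <= self.specificity <= 1.0:
            raise ConfigError("specificity must lie in [0, 1]")
        if set(self.category_rates) != set(CATEGORIES):
            raise ConfigError(
                f"category_rates must cover exactly {CATEGORIES}, "
                f"got {tuple(self.category_rates)}"
            )
        if abs(sum(self.category_rates.values()) - 1.0) > 1e-12:
            raise ConfigError("category_rates must sum to 1 within 1e-12")
        if self.trials_per_participant > self.n_images:
            raise ConfigError(
                "trials_per_participant cannot exceed n_images "
                "(no image repeats within a participant)"
            )
        needed = math.ceil(
            self.respondents_per_image * self.n_images / self.trials_per_participant
        )
        if self.n_participants < needed:
            raise ConfigError(
                f"capacity infeasible: {self.n_images} images x "
                f"{self.respondents_per_image} respondents needs at least "
                f"{needed} participants with {self.trials_per_participant} "
                f"trials each; got {self.n_participants}"
            )


@dataclass
class GroundTruth:
    """Latent structure of a simulated experiment, for recovery tests."""

    image_pools: dict[str, dict[str, tuple[str, ...]]]  # image -> pool name -> words
    token_categories: pd.DataFrame  # participant_id, image_id, slot, word, category
    word_ranks: dict[str, int]

    def label_set(self) -> CategoryLabelSet:
        """Collapse token labels to one category per (word, image) by majority.

        Ties break by the fixed category order, mimicking a single judge
        assigning one label per pair.
        """
        labels: dict[tuple[str, str], str] = {}
        grouped = self.token_categories.groupby(
            ["word", "image_id"], sort=False
        )["category"]
        for (word, image_id), cats in grouped:
            counts = cats.value_counts()
            best = max(CATEGORIES, key=lambda c: (counts.get(c, 0), -CATEGORIES.index(c)))
            labels[(word, image_id)] = best
        return CategoryLabelSet(labels=labels)


# ---------------------------------------------------------------------------


_CONSONANTS = list("bcdfghjklmnprstvwz")
_VOWELS = list("aeiou")


def _pseudo_words(n: int, rng: np.random.Generator) -> list[str]:
    """Generate n unique pronounceable pseudo-words (CV-syllable strings)."""
    words: list[str] = []
    seen: set[str] = set()
    while len(words) < n:
        syllables = rng.integers(2, 5)
        w = "".join(
            rng.choice(_CONSONANTS) + rng.choice(_VOWELS) for _ in range(syllables)
        )
        if w not in seen:
            seen.add(w)
            words.append(w)
    return words


def build_vocabulary(cfg: SimulationConfig) -> tuple[FrequencyTable, list[str]]:
    """Zipf-distributed vocabulary: rank-r word gets count ∝ r^-exponent.

    Counts are scaled so the top-ranked word has ``top_per_billion``
    occurrences per billion.  Deterministic given the config seed.
    """
    rng = np.random.default_rng(cfg.seed)
    words = _pseudo_words(cfg.vocab_size, rng)
    ranks = np.arange(1, cfg.vocab_size + 1, dtype=float)
    counts = cfg.top_per_billion * ranks ** (-cfg.zipf_exponent)
    table = FrequencyTable(per_billion=dict(zip(words, counts)))
    return table, words


def generate_assignment(cfg: SimulationConfig) -> dict[str, list[str]]:
    """Balanced participant -> image-sequence assignment.

    A seeded shuffled image deck is dealt round-robin, wrapping as needed,
    until every participant holds ``trials_per_participant`` images.  Every
    image thus reaches at least ``respondents_per_image`` distinct
    participants (some reach more; the first-ten rule truncates downstream),
    and no participant sees an image twice.
    """
    cfg.validate()
    rng = np.random.default_rng(cfg.seed + 1)
    images = [f"img{i:04d}" for i in range(1, cfg.n_images + 1)]
    deck = list(rng.permutation(images))
    participants = [f"p{i:04d}" for i in range(1, cfg.n_participants + 1)]
    assignment: dict[str, list[str]] = {}
    pos = 0
    for p in participants:
        seq: list[str] = []
        while len(seq) < cfg.trials_per_participant:
            img = deck[pos % len(deck)]
            pos += 1
            if img not in seq:  # cannot trigger while trials <= n_images, kept as a guard
                seq.append(img)
        assignment[p] = seq
    counts: dict[str, int] = {}
    for seq in assignment.values():
        for img in seq:
            counts[img] = counts.get(img, 0) + 1
    short = {i: c for i, c in counts.items() if c < cfg.respondents_per_image}
    if short:
        raise ConfigError(f"assignment left images under-covered: {short}")
    return assignment


def _weighted_subset(
    rng: np.random.Generator, words: list[str], weights: np.ndarray, size: int,
    exclude: set[str] = frozenset(),
) -> tuple[str, ...]:
    """Frequency-weighted sample without replacement, avoiding ``exclude``."""
    mask = np.fromiter((w not in exclude for w in words), bool, len(words))
    p = weights * mask
    p = p / p.sum()
    idx = rng.choice(len(words), size=size, replace=False, p=p)
    return tuple(words[i] for i in sorted(idx))


def simulate_experiment(
    cfg: SimulationConfig,
) -> tuple[Experiment, GroundTruth, FrequencyTable]:
    """Generate a full synthetic experiment plus its latent ground truth.

    Each trial emits exactly five slots.  A slot is left empty (confidence
    1, the "Don't Know" convention) at ``empty_slot_rate`` or when a
    duplicate word cannot be resampled within ``max_resample`` tries;
    otherwise a category is drawn from ``category_rates``, a word from the
    matching pool (resampled within the same category on within-trial
    duplication, keeping token category frequencies faithful to the
    configured rates), and a confidence from the discretized normal centred
    on that category's mean.
    """
    table, words = build_vocabulary(cfg)
    weights = np.array([table.per_billion[w] for w in words])
    weights = weights / weights.sum()
    word_ranks = {w: r for r, w in enumerate(words, 1)}
    assignment = generate_assignment(cfg)
    rng = np.random.default_rng(cfg.seed + 2)

    conceptual_pool = _weighted_subset(rng, words, weights, cfg.conceptual_pool_size)
    image_pools: dict[str, dict[str, tuple[str, ...]]] = {}
    image_ids = sorted({img for seq in assignment.values() for img in seq})
    for img in image_ids:
        content = _weighted_subset(rng, words, weights, cfg.content_words_per_image)
        gist = _weighted_subset(
            rng, words, weights, cfg.gist_words_per_image, exclude=set(content)
        )
        altgist = _weighted_subset(
            rng, words, weights, cfg.altgist_words_per_image,
            exclude=set(content) | set(gist),
        )
        image_pools[img] = {"content": content, "gist": gist, "altgist": altgist}

    cat_names = list(CATEGORIES)
    cat_p = np.array([cfg.category_rates[c] for c in cat_names])
    pool_weights_cache: dict[tuple[str, ...], np.ndarray] = {}

    def _draw_from(pool: tuple[str, ...]) -> str:
        p = pool_weights_cache.get(pool)
        if p is None:
            p = np.array([table.per_billion[w] for w in pool])
            p = p / p.sum()
            pool_weights_cache[pool] = p
        return pool[rng.choice(len(pool), p=p)]

    def _draw_word(category: str, img: str) -> str:
        pools = image_pools[img]
        if category == "exist":
            if rng.random() < cfg.specificity:
                return _draw_from(pools["content"])
            return words[rng.choice(len(words), p=weights)]
        if category == "conceptual":
            return _draw_from(conceptual_pool)
        if category == "insertion":
            return _draw_from(pools["gist"])
        if category == "confusion":
            return _draw_from(pools["altgist"])
        return words[rng.choice(len(words), p=weights)]  # unrelated

    def _typo(word: str) -> str:
        i = int(rng.integers(0, len(word)))
        c = str(rng.choice(_CONSONANTS + _VOWELS))
        return word[:i] + c + word[i:]

    records: list[ResponseRecord] = []
    truth_rows: list[tuple[str, str, int, str, str]] = []
    arrival: dict[str, int] = {}

    for participant, seq in assignment.items():
        for trial_index, img in enumerate(seq):
            arrival[img] = arrival.get(img, 0) + 1
            rank = arrival[img]
            used: set[str] = set()
            for slot in range(1, 6):
                if rng.random() < cfg.empty_slot_rate:
                    records.append(ResponseRecord(
                        participant, img, trial_index, slot, "", 1, rank
                    ))
                    continue
                category = cat_names[rng.choice(len(cat_names), p=cat_p)]
                word = None
                for _ in range(cfg.max_resample):
                    cand = _draw_word(category, img)
                    if cand not in used:
                        word = cand
                        break
                if word is None:
                    records.append(ResponseRecord(
                        participant, img, trial_index, slot, "", 1, rank
                    ))
                    continue
                used.add(word)
                conf = int(np.clip(
                    round(rng.normal(cfg.confidence_means[category], cfg.confidence_sd)),
                    1, 5,
                ))
                raw = word
                if cfg.typo_rate > 0 and rng.random() < cfg.typo_rate:
                    raw = _typo(word)
                records.append(ResponseRecord(
                    participant, img, trial_index, slot, raw, conf, rank
                ))
                truth_rows.append((participant, img, slot, word, category))

    exp = Experiment(name=cfg.name, records=records, condition_tag=cfg.condition_tag)
    exp.validate()
    truth = GroundTruth(
        image_pools=image_pools,
        token_categories=pd.DataFrame(
            truth_rows, columns=["participant_id", "image_id", "slot", "word", "category"]
        ),
        word_ranks=word_ranks,
    )
    return exp, truth, table
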