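"""Small constructed datasets: toy response matrices for demonstration,
verification and randomized cross-checking of the IA computation."""

from __future__ import annotations

import numpy as np

from .ia import N_ROWS, N_SLOTS, ResponseMatrix

__all__ = ["make_matrix", "random_matrices", "hand_worked_toy"]


def make_matrix(image_id: str, placements: dict[str, list[int]],
                confidence: int = 3) -> ResponseMatrix:
    """Build a full 10x5 matrix placing each word in the given 0-based rows.

    Words are packed left-to-right within each row; placing more than five
    words in one row is an error, as is listing a row twice for one word.
    """
    words: list[list[str | None]] = [[None] * N_SLOTS for _ in range(N_ROWS)]
    confs: list[list[int | None]] = [[None] * N_SLOTS for _ in range(N_ROWS)]
    next_slot = [0] * N_ROWS
    for word, rows in placements.items():
        for r in rows:
            s = next_slot[r]
            if s >= N_SLOTS:
                raise ValueError(f"row {r} of {image_id!r} holds more than {N_SLOTS} words")
            words[r][s] = word
            confs[r][s] = confidence
            next_slot[r] += 1
    m = ResponseMatrix(
        image_id=image_id,
        words=words,
        confidences=confs,
        row_participants=[f"{image_id}-p{i}" for i in range(N_ROWS)],
    )
    m.validate()
    return m


def random_matrices(rng: np.random.Generator, n_images: int | None = None,
                    vocab: int = 30) -> dict[str, ResponseMatrix]:
    """A random small dataset (3-8 images by default) over a sparse vocabulary.

    Each row holds 0-5 distinct words drawn uniformly, producing plenty of
    repeated words and AUC threshold ties — the regime where curve-based and
    rank-based IA computations could disagree if either mishandled ties.
    """
    n_images = n_images or int(rng.integers(3, 9))
    words = [f"w{i}" for i in range(vocab)]
    out: dict[str, ResponseMatrix] = {}
    for i in range(n_images):
        grid = []
        for _ in range(N_ROWS):
            k = int(rng.integers(0, N_SLOTS + 1))
            picks = list(rng.choice(vocab, size=k, replace=False))
            grid.append([words[j] for j in picks] + [None] * (N_SLOTS - k))
        m = ResponseMatrix(
            image_id=f"img{i}",
            words=grid,
            confidences=[[3 if w else None for w in row] for row in grid],
            row_participants=[f"img{i}-p{r}" for r in range(N_ROWS)],
        )
        m.validate()
        out[m.image_id] = m
    return out


def hand_worked_toy() -> dict[str, ResponseMatrix]:
    """Three images where the target word's IA is 0.625 by hand.

    The target word sits in rows 0 and 2 of image A (k=2, within ratio 1/9)
    and rows 0 and 1 of image B; image C never mentions it.  Deleting A's
    row 0 from B leaves one occurrence (a tie with the within count, AUC
    (1 + 0.5)/2 = 0.75); deleting row 2 leaves two (above, AUC 0.5);
    the mean is 0.625.
    """
    return {
        "A": make_matrix("A", {"target": [0, 2], "fillerA": [4, 5]}),
        "B": make_matrix("B", {"target": [0, 1], "fillerB": [3, 6]}),
        "C": make_matrix("C", {"fillerC": [0, 1]}),
    }
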