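"""IA metric: analytic cases, the hand-worked toy, oracle equivalence,
and the metric's structural invariants."""

from __future__ import annotations

from fractions import Fraction

import numpy as np
import pytest

from wordia.ia import (
    RareWordError,
    RatioDistribution,
    UndefinedScoreError,
    auc_from_curves,
    between_ratios,
    build_response_matrices,
    compute_all_ia,
    scorable_words,
    within_ratio,
    word_ia,
    word_ia_oracle,
)
from wordia.io_model import Experiment, ResponseRecord

from conftest import make_matrix, random_dataset


def dist(counts_by_numerator: dict[int, int], n_other: int) -> RatioDistribution:
    bins = [0] * 10
    for num, c in counts_by_numerator.items():
        bins[num] = c
    return RatioDistribution(bins=tuple(bins), n_images=n_other)


class TestMatrixConstruction:
    @staticmethod
    def exp_with_respondents(n: int) -> Experiment:
        records = []
        for p in range(n):
            for slot, w in enumerate(["dog", "cat"], 1):
                records.append(ResponseRecord(f"p{p}", "i1", 0, slot, w, 3, p + 1))
        return Experiment("t", records)

    def test_first_ten_rule(self):
        ms = build_response_matrices(self.exp_with_respondents(12))
        m = ms["i1"]
        assert m.row_participants == [f"p{i}" for i in range(10)]

    def test_under_ten_respondents_excluded(self, caplog):
        import logging

        with caplog.at_level(logging.WARNING):
            ms = build_response_matrices(self.exp_with_respondents(9))
        assert ms == {}
        assert "excluded" in caplog.text

    def test_exactly_ten_included(self):
        ms = build_response_matrices(self.exp_with_respondents(10))
        assert set(ms) == {"i1"}
        assert ms["i1"].rows_with("dog") == frozenset(range(10))


class TestScorableWords:
    def test_boundaries(self):
        m = make_matrix("A", {"once": [0], "twice": [1, 2], "filler": [3]})
        assert scorable_words(m) == {"twice"}

    def test_empty_cells_ignored(self):
        m = make_matrix("A", {"w": [0, 1]})
        assert scorable_words(m) == {"w"}


class TestWithinRatio:
    def test_values(self):
        m = make_matrix("A", {"all": list(range(10)), "two": [0, 1],
                              "three": [2, 3, 4]})
        assert within_ratio(m, "all", 0) == Fraction(9, 9)
        assert within_ratio(m, "two", 0) == Fraction(1, 9)
        for row in (2, 3, 4):
            assert within_ratio(m, "three", row) == Fraction(2, 9)

    def test_rare_word_and_absent_row_rejected(self):
        m = make_matrix("A", {"once": [0], "two": [1, 2]})
        with pytest.raises(RareWordError):
            within_ratio(m, "once", 0)
        with pytest.raises(ValueError):
            within_ratio(m, "two", 5)


class TestBetweenRatios:
    def test_absent_word_all_mass_at_zero(self):
        ms = {"A": make_matrix("A", {"w": [0, 1]}),
              "B": make_matrix("B", {"x": [0, 1]}),
              "C": make_matrix("C", {"y": [2]})}
        d = between_ratios(ms, "A", "w", 0)
        assert d.bins[0] == 2 and d.n_images == 2

    def test_row_removal_shifts_count(self):
        ms = {"A": make_matrix("A", {"w": [1, 2]}),
              "B": make_matrix("B", {"w": [1, 2]})}
        # B holds the word in rows 1 and 2: removing row 0 leaves 2 counts,
        # removing row 1 leaves only 1
        assert between_ratios(ms, "A", "w", 0).bins[2] == 1
        assert between_ratios(ms, "A", "w", 1).bins[1] == 1

    def test_n_images_is_other_count(self):
        ms = {k: make_matrix(k, {"w": [0, 1]}) for k in "ABC"}
        assert between_ratios(ms, "A", "w", 0).n_images == 2


class TestAucFromCurves:
    def test_perfect_separation(self):
        assert auc_from_curves(Fraction(9, 9), dist({0: 5}, 5)) == 1.0

    def test_complete_ties_chance_level(self):
        assert auc_from_curves(Fraction(1, 9), dist({1: 4}, 4)) == 0.5

    def test_mixed_tie_rank_form(self):
        # between values {2/9, 0/9} against within 1/9: (1 below + 0 ties)/2
        assert auc_from_curves(Fraction(1, 9), dist({2: 1, 0: 1}, 2)) == 0.5

    def test_zero_comparisons_undefined(self):
        with pytest.raises(UndefinedScoreError):
            auc_from_curves(Fraction(1, 9), dist({}, 0))

    @pytest.mark.parametrize("within", range(1, 10))
    def test_equals_tie_aware_rank_statistic(self, within):
        rng = np.random.default_rng(within)
        for _ in range(50):
            bins = rng.multinomial(rng.integers(1, 40), np.ones(10) / 10)
            d = RatioDistribution(bins=tuple(int(b) for b in bins), n_images=int(bins.sum()))
            below = sum(d.bins[:within])
            equal = d.bins[within]
            expected = (below + 0.5 * equal) / d.n_images
            assert auc_from_curves(Fraction(within, 9), d) == pytest.approx(
                expected, abs=1e-12
            )


class TestWordIA:
    def test_hand_worked_toy(self, toy_three_images):
        score = word_ia(toy_three_images, "A", "target")
        assert score.k == 2
        assert score.within_ratio == Fraction(1, 9)
        assert sorted(score.per_row_auc) == [0.5, 0.75]
        assert score.ia == pytest.approx(0.625, abs=1e-15)
        assert word_ia_oracle(toy_three_images, "A", "target") == pytest.approx(
            0.625, abs=1e-15
        )

    def test_unique_word_everywhere_else_absent_scores_one(self):
        ms = {"A": make_matrix("A", {"w": list(range(10))}),
              "B": make_matrix("B", {"x": [0, 1]}),
              "C": make_matrix("C", {"y": [0, 1]})}
        assert word_ia(ms, "A", "w").ia == 1.0

    def test_identical_saturated_matrices_chance(self):
        ms = {"A": make_matrix("A", {"w": list(range(10))}),
              "B": make_matrix("B", {"w": list(range(10))})}
        assert word_ia(ms, "A", "w").ia == 0.5

    def test_rare_word_rejected(self, toy_three_images):
        with pytest.raises(RareWordError):
            word_ia(toy_three_images, "C", "target")


class TestOracleEquivalence:
    def test_randomized_datasets(self):
        """Curve-based IA equals brute-force rank IA to 1e-12 everywhere."""
        rng = np.random.default_rng(2024)
        checked = 0
        for _ in range(150):
            ms = random_dataset(rng)
            for image_id, m in ms.items():
                for word in scorable_words(m):
                    a = word_ia(ms, image_id, word).ia
                    b = word_ia_oracle(ms, image_id, word)
                    assert abs(a - b) < 1e-12
                    checked += 1
        assert checked > 1000


class TestInvariants:
    def test_bounds_and_maximum_condition(self):
        rng = np.random.default_rng(5)
        for _ in range(30):
            ms = random_dataset(rng, n_images=4)
            for image_id, m in ms.items():
                for word in scorable_words(m):
                    s = word_ia(ms, image_id, word)
                    assert 0.0 <= s.ia <= 1.0
                    within = s.within_ratio.numerator * (9 // s.within_ratio.denominator)
                    strictly_below = all(
                        sum(1 for i, row in enumerate(other.words)
                            if i != r and word in row) < within
                        for r in sorted(m.rows_with(word))
                        for oid, other in ms.items() if oid != image_id
                    )
                    assert (s.ia == 1.0) == strictly_below

    def test_permuting_other_images_leaves_ia_unchanged(self, toy_three_images):
        forward = word_ia(toy_three_images, "A", "target").ia
        shuffled = dict(reversed(list(toy_three_images.items())))
        assert word_ia(shuffled, "A", "target").ia == forward

    def test_adding_occurrence_elsewhere_never_increases_ia(self):
        base = {"A": make_matrix("A", {"w": [0, 1, 2]}),
                "B": make_matrix("B", {"w": [5]}),
                "C": make_matrix("C", {"x": [0, 1]})}
        more = {"A": make_matrix("A", {"w": [0, 1, 2]}),
                "B": make_matrix("B", {"w": [5, 6]}),
                "C": make_matrix("C", {"x": [0, 1]})}
        assert word_ia(more, "A", "w").ia <= word_ia(base, "A", "w").ia

    def test_adding_occurrence_to_target_never_decreases_within(self):
        m3 = make_matrix("A", {"w": [0, 1, 2]})
        m4 = make_matrix("A", {"w": [0, 1, 2, 3]})
        assert within_ratio(m4, "w", 0) >= within_ratio(m3, "w", 0)


class TestComputeAll:
    def test_row_count_equals_scorable_sum(self, small_sim):
        from wordia.preprocessing import preprocess

        _, exp, _, _ = small_sim
        frame = preprocess(exp).frame
        matrices = build_response_matrices(frame)
        scores = compute_all_ia(matrices)
        expected = sum(len(scorable_words(m)) for m in matrices.values())
        assert len(scores) == expected
        assert scores["ia"].between(0, 1).all()

    def test_all_unique_words_yield_empty_table(self):
        records = []
        for img in ("i1", "i2"):
            for p in range(10):
                records.append(ResponseRecord(
                    f"p{p}", img, 0, 1, f"unique-{img}-{p}", 3, p + 1
                ))
        exp = Experiment("t", records)
        assert compute_all_ia(exp).empty

    def test_participant_row_matching_mode_runs(self, toy_three_images):
        s = word_ia(toy_three_images, "A", "target", row_matching="participant")
        assert 0.0 <= s.ia <= 1.0
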