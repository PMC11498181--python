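"""Preprocessing chain: normalization, ledgers, lemmas, dedupe, idempotence."""

from __future__ import annotations

import re

import pandas as pd
import pytest
from hypothesis import given, settings, strategies as st

from wordia.io_model import Experiment, FrequencyTable, ResponseRecord
from wordia.preprocessing import (
    CorrectionLedger,
    FrequencySpellChecker,
    LedgerEntry,
    LemmaLedger,
    RuleLemmatizer,
    apply_ledger,
    auto_accept_corrections,
    dedupe_trials,
    normalize_token,
    preprocess,
    propose_corrections,
    propose_lemmas,
    read_ledger,
    write_ledger,
)


def make_exp(words: list[str], participant="p1", image="i1") -> Experiment:
    return Experiment("t", [
        ResponseRecord(participant, image, 0, slot, w, 1 if w == "" else 3, 1)
        for slot, w in enumerate(words, 1)
    ])


class TestNormalize:
    @pytest.mark.parametrize("raw, expected", [
        ("Red Dot", "red-dot"),
        ("2", "two"),
        ("", ""),
        ("  Sky  ", "sky"),
        ("ice   cream", "ice-cream"),
        ("T-Shirt", "t-shirt"),
        ("0", "zero"),
        ("15", "fifteen"),
        ("42", "forty-two"),
        ("100", "one-hundred"),
        ("101", "101"),          # outside the 0-100 conversion range
        ("2nd", "2nd"),          # mixed alphanumerics pass through
        ("DOG", "dog"),
    ])
    def test_examples(self, raw, expected):
        assert normalize_token(raw) == expected

    @settings(max_examples=200, deadline=None)
    @given(st.text(max_size=30))
    def test_total_and_idempotent(self, raw):
        out = normalize_token(raw)
        assert normalize_token(out) == out
        assert out == out.lower()
        assert " " not in out


class TestCorrectionLedger:
    def test_flagged_token_proposed_not_applied(self):
        ledger = propose_corrections(
            {"holiaday"}, lambda t: "holiday" if t == "holiaday" else None
        )
        assert ledger.entries["holiaday"].replacement == "holiday"
        assert not ledger.entries["holiaday"].accepted

    def test_clean_token_yields_empty_ledger(self):
        assert propose_corrections({"dog"}, lambda t: None).entries == {}

    def test_questionable_suggestion_defaults_rejected(self):
        # the review of the original workflow rejected "red-dot" -> "reddit"
        ledger = propose_corrections({"red-dot"}, lambda t: "reddit")
        assert ledger.entries["red-dot"].replacement == "reddit"
        assert not ledger.entries["red-dot"].accepted
        exp = apply_ledger(make_exp(["red-dot"]), ledger)
        assert exp.records[0].raw_word == "red-dot"

    def test_provider_failure_recorded(self):
        def boom(t):
            raise RuntimeError("provider down")

        ledger = propose_corrections({"word"}, boom)
        assert ledger.entries["word"].replacement is None

    def test_accepted_entry_applied_and_idempotent(self):
        ledger = CorrectionLedger({"holiaday": LedgerEntry("holiaday", "holiday", True)})
        once = apply_ledger(make_exp(["holiaday", "dog"]), ledger)
        assert [r.raw_word for r in once.records] == ["holiday", "dog"]
        twice = apply_ledger(once, ledger)
        assert twice.records == once.records

    def test_empty_replacement_rejected(self):
        ledger = CorrectionLedger({"x": LedgerEntry("x", "", True)})
        with pytest.raises(Exception, match="empty"):
            apply_ledger(make_exp(["x"]), ledger)

    def test_ledger_file_roundtrip(self, tmp_path):
        ledger = CorrectionLedger({
            "holiaday": LedgerEntry("holiaday", "holiday", True),
            "red-dot": LedgerEntry("red-dot", "reddit", False),
        })
        back = read_ledger(write_ledger(ledger, tmp_path / "l.csv"))
        assert back.entries == ledger.entries

    def test_auto_accept_requires_known_and_close(self):
        table = FrequencyTable({"holiday": 1e4, "reddit": 1e3})
        ledger = propose_corrections(
            {"holiaday", "xqzvwy"},
            {"holiaday": "holiday", "xqzvwy": "reddit"}.get,
        )
        auto_accept_corrections(ledger, table)
        assert ledger.entries["holiaday"].accepted          # 1 edit, in table
        assert not ledger.entries["xqzvwy"].accepted        # far from suggestion


class TestLemmas:
    def test_inflected_form_proposed_and_accepted(self):
        ledger = propose_lemmas({"loving"}, {"loving": "love"}.get)
        entry = ledger.entries["loving"]
        assert entry.replacement == "love" and entry.accepted

    def test_degenerate_hyphen_split_auto_rejected(self):
        ledger = propose_lemmas({"t-shirt"}, {"t-shirt": "t"}.get)
        entry = ledger.entries["t-shirt"]
        assert entry.replacement == "t" and not entry.accepted

    def test_fixed_point_omitted(self):
        assert propose_lemmas({"dog"}, lambda t: t).entries == {}

    @pytest.mark.parametrize("token, lemma", [
        ("dogs", "dog"), ("boxes", "box"), ("berries", "berry"),
        ("running", "run"), ("loving", "love"), ("jumped", "jump"),
        ("men", "man"), ("glass", "glass"), ("unknownword", "unknownword"),
    ])
    def test_rule_lemmatizer(self, token, lemma):
        vocab = {"dog", "box", "berry", "run", "love", "jump", "man", "glass"}
        assert RuleLemmatizer(vocab)(token) == lemma


class TestDedupe:
    def test_repeated_lemma_keeps_lowest_slot(self):
        result = preprocess(make_exp(["dog", "cat", "dog", "sky", "sea"]))
        df = result.frame
        assert df.loc[df.slot == 3, "dropped"].item()
        assert df.loc[df.slot == 3, "drop_reason"].item() == "duplicate-in-trial"
        assert list(df.loc[~df.dropped, "word"]) == ["dog", "cat", "sky", "sea"]

    def test_distinct_trial_unchanged(self):
        result = preprocess(make_exp(["a", "b", "c", "d", "e"]))
        assert not result.frame.dropped.any()

    def test_lemmatize_then_dedupe(self):
        # [run, running] lemmatizes to [run, run]; the second is dropped
        result = preprocess(
            make_exp(["run", "running"]),
            lemma_provider=RuleLemmatizer({"run"}),
        )
        df = result.frame
        assert list(df.word) == ["run", "run"]
        assert list(df.dropped) == [False, True]

    def test_empty_words_dropped_with_reason(self):
        result = preprocess(make_exp(["dog", "", "cat"]))
        df = result.frame
        assert df.loc[df.slot == 2, "drop_reason"].item() == "empty"


class TestPipeline:
    def test_count_conservation(self, small_sim):
        _, exp, _, freq = small_sim
        result = preprocess(
            exp,
            spell_provider=FrequencySpellChecker(freq),
            lemma_provider=RuleLemmatizer(freq.words()),
            auto_accept=freq,
        )
        d = result.drop_counts
        dropped = sum(v for k, v in d.items() if k not in ("surviving", "total"))
        assert d["surviving"] + dropped == d["total"] == len(exp.records)

    def test_idempotence_on_simulated_data(self, small_sim):
        _, exp, _, freq = small_sim
        providers = dict(
            spell_provider=FrequencySpellChecker(freq),
            lemma_provider=RuleLemmatizer(freq.words()),
            auto_accept=freq,
        )
        first = preprocess(exp, **providers).surviving
        again = Experiment("again", [
            ResponseRecord(r.participant_id, r.image_id, r.trial_index,
                           r.slot, r.word, r.confidence, r.arrival_rank)
            for r in first.itertuples(index=False)
        ])
        second = preprocess(again, **providers).surviving
        assert list(second.word) == list(first.word)
        assert list(second.slot) == list(first.slot)

    def test_typo_injection_corrected_by_spell_path(self):
        from wordia.synthetic import SimulationConfig, simulate_experiment

        cfg = SimulationConfig(n_images=10, trials_per_participant=5,
                               typo_rate=0.3, seed=5)
        exp, truth, freq = simulate_experiment(cfg)
        raw_words = {r.raw_word for r in exp.records if r.raw_word}
        assert any(w not in freq for w in raw_words), "typos were injected"
        result = preprocess(
            exp, spell_provider=FrequencySpellChecker(freq), auto_accept=freq
        )
        surviving = set(result.surviving.word)
        known = sum(w in freq for w in surviving)
        assert known / len(surviving) > 0.95

    @settings(max_examples=50, deadline=None)
    @given(st.lists(
        st.text(alphabet="abcdefghij -AB2", min_size=0, max_size=10),
        min_size=1, max_size=5,
    ))
    def test_surviving_token_alphabet(self, raws):
        exp = Experiment("alpha", [
            ResponseRecord("p1", "i1", 0, slot, w, 1 if w.strip() == "" else 3, 1)
            for slot, w in enumerate(raws, 1)
        ])
        surviving = preprocess(exp).surviving
        for word in surviving.word:
            assert re.fullmatch(r"[^\sA-Z]+", word), word
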