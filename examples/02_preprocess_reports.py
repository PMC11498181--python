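"""Clean raw free reports: normalize, spell-correct via ledger, lemmatize, dedupe.

Shows the audit-trail workflow: the spell checker and lemmatizer only
*propose*; an explicit accept/reject decision (here scripted, originally a
manual review) controls what is applied.
"""

from wordia import (
    Experiment,
    FrequencyTable,
    FrequencySpellChecker,
    ResponseRecord,
    RuleLemmatizer,
    normalize_token,
    preprocess,
)

print("normalization:", {r: normalize_token(r) for r in ["Red Dot", "2", "  Sky "]})

# a single participant's trial, with a typo and an inflected repeat
words = ["holiaday", "beach", "Palm Tree", "waves", "wave"]
exp = Experiment("demo", [
    ResponseRecord("p1", "img1", 0, slot, w, 4, 1)
    for slot, w in enumerate(words, 1)
])

table = FrequencyTable({"holiday": 1.2e4, "beach": 8e3, "palm": 5e3,
                        "tree": 2e4, "wave": 9e3, "palm-tree": 1e2})
result = preprocess(
    exp,
    spell_provider=FrequencySpellChecker(table),
    lemma_provider=RuleLemmatizer(table.words()),
    auto_accept=table,  # accept suggestions that land in the dictionary
)

print("\nslot  raw          final      dropped  reason")
for row in result.frame.itertuples(index=False):
    print(f"{row.slot:>4}  {row.raw_word:<12} {row.word:<10} "
          f"{str(bool(row.dropped)):<8} {row.drop_reason or ''}")
print("\ndrop report:", result.drop_counts)

# 'holiaday' was corrected to 'holiday' (suggestion found in the dictionary,
# one edit away); 'waves' lemmatized to 'wave', which duplicates slot 5's
# 'wave' within the trial, so the later slot is dropped.
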