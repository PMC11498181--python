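"""Word IA on a hand-checkable 3-image toy, with the brute-force cross-check.

The IA of a word-image pair is an ROC AUC: the word's within-image
recurrence (extra reports / 9) is compared against its leave-one-row-out
occurrence in every other image, once per row that reported it.
"""

from wordia import hand_worked_toy, word_ia, word_ia_oracle

matrices = hand_worked_toy()
score = word_ia(matrices, "A", "target")

print(f"word {score.word!r} in image {score.image_id!r}")
print(f"  reported by k = {score.k} of 10 respondents")
print(f"  within-image ratio = {score.within_ratio}")
print(f"  per-row AUCs = {score.per_row_auc}")
print(f"  word IA = {score.ia}")
print(f"  brute-force oracle = {word_ia_oracle(matrices, 'A', 'target')}")

# Row 0's comparison in image B leaves one occurrence (a tie with the
# within count -> AUC 0.75 against B and C); row 2's leaves two (above the
# within count -> AUC 0.5); the word IA is their mean, 0.625.
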