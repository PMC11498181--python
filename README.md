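# wordia

Intersubjective-agreement (IA) analysis of free verbal reports of briefly
presented scenes.

## The problem

In free-report perception experiments, an image is flashed for tens of
milliseconds, backward-masked, and each of ten respondents types five words
describing what they experienced, rating each word's confidence on a 1–5
scale ("Don't Know" … "Very Confident"). The word IA statistic asks, for
every reported word, *how specifically does this word pick out this image* —
a candidate measure of how rich the underlying percept was, and one whose
behaviour (does it track stimulus degradation? does it instead track word
frequency?) is itself a research question. `wordia` is for researchers who
want to compute IA on such data, run the standard downstream analyses, and
stress-test the metric against simulated experiments with known ground
truth.

## The statistic

For a target word *w* reported in *k* ≥ 2 of the ten rows of image *I*'s
10 × 5 response matrix (words reported by a single respondent are "rarely
reported" and unscorable):

- **within-image ratio** — (*k* − 1)/9, the word's extra occurrences across
  the other nine rows;
- **between-image ratios** — for each row *r* that reported *w* and every
  other image *J*: delete row *r* from *J*'s matrix and count the rows among
  the remaining nine containing *w*, over nine;
- bin the between ratios (0/9 … 9/9), form cumulative counts, and build an
  ROC curve whose true-positive rate is the cumulative within ratio and
  whose false-positive rate is the cumulative between ratio; the row's
  score is the area under this curve (equivalently, the tie-aware rank
  statistic (#below + ½·#ties)/#other-images — the package computes both and
  tests their equality);
- **word IA** = mean AUC over the *k* rows. IA ∈ [0, 1]; 1 means no other
  image ever approaches the word's within-image recurrence.

Downstream, the package provides Pearson correlations of IA with Zipf word
frequency (log₁₀ occurrences per billion) and with mean confidence — each
with a default Bayes factor (uniform prior on ρ) — category proportions of
existing/conceptual/insertion/confusion/unrelated words among scored pairs,
and one-way ANOVAs with a BIC-approximated BF₁₀.

A synthetic-experiment generator reproduces the design (388 images, ten
respondents per image, 21 trials per participant, five unique words +
confidence per trial) with controllable report specificity, Zipf-distributed
vocabulary, category mixture and per-category confidence, so the whole
pipeline can be validated by parameter recovery without any human data.

## Worked example

```python
from wordia import hand_worked_toy, word_ia, word_ia_oracle

matrices = hand_worked_toy()   # 3 images, 10x5 matrices
score = word_ia(matrices, "A", "target")
print(score.k, score.within_ratio, score.per_row_auc, score.ia)
print(word_ia_oracle(matrices, "A", "target"))
```

prints

```
2 1/9 [0.75, 0.5] 0.625
0.625
```

The word was reported by two of image A's ten respondents (within ratio
1/9). Against image B — which contains the word in two rows — deleting the
first reporting row leaves one occurrence (a tie: AUC 0.75 over images B
and C), deleting the other leaves two (above the within count: AUC 0.5);
the word IA is their mean, 0.625, confirmed by the brute-force oracle.

At scale (`examples/04_frequency_confidence_stats.py`, 60 simulated
images):

```
scored 442 word-image pairs over 60 images; mean IA = 0.726
IA vs Zipf frequency: r(440) = -0.595, p = 9.5e-44, BF10 = 2.59e+40
confidence by category: F(3, 438) = 21.1, p = 9e-13, BF10 (BIC approx.) = 9.46e+08
  exist        mean confidence 4.15
  ...
```

The negative IA–frequency correlation (common words are shared across
images, hence less diagnostic) and the higher confidence of existing over
inserted words are recovered from the generator's injected structure.

More narrative scripts live in `examples/`; a thin CLI
(`wordia simulate|preprocess|ia|run`) drives the same library for on-disk
workflows.

## Real data

The pipeline ingests any responses table in the documented CSV dialect
(`participant_id,image_id,trial_index,slot,word,confidence`) plus a
word-frequency TSV, so deposited datasets from free-report studies can be
scored by pointing `PipelineConfig` (or `wordia run`) at the files with
`simulate: false`. Word-category analyses additionally need a
(word, image, category) label table, which for real data comes from human
judgment.
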