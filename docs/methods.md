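# Methods

## The word IA model

The package scores free verbal reports collected under a fixed design: each
image is described by exactly ten respondents (its *response matrix*, ten
rows by five word slots), and each respondent's five words within a trial
are unique after preprocessing. Word IA for a (word, image) pair is defined
only when the word appears in k ≥ 2 rows; it is the mean, over those k
rows, of an ROC AUC comparing

- the within-image ratio (k − 1)/9 — a single value acting as the
  "signal" distribution — against
- the distribution of leave-one-row-out between-image ratios: for every
  other image, the row with the same index as the target row is removed and
  occurrences of the word among the remaining nine rows are counted.

The ROC is built from cumulative counts over the ten possible ratios
(0/9 … 9/9), sweeping the threshold from 9/9 down to 0/9 with (0, 0)
prepended, and integrated by the trapezoid rule. With a one-point signal
distribution this AUC equals the tie-aware rank statistic
(#below + ½·#ties)/#comparisons. The equality is not assumed: the package
implements both routes — the binned-curve computation as the production
path (`wordia.ia.word_ia`) and a brute-force enumeration with explicit
below/equal/above tallies (`wordia.ia.word_ia_oracle`) — and the test suite
asserts agreement to 1 × 10⁻¹² for every scorable pair across more than a
thousand randomized datasets.

Numerical choices: ratios are carried as exact integer ninths
(`fractions.Fraction` numerators 0–9) until the AUC step, so threshold ties
are detected exactly with no float-equality hazard. Rows are ordered by
arrival rank (the order in which participants reached the image), with file
order as the tiebreak. "Corresponding row" in the between-image step means
*same row index* after arrival ordering; a `row_matching="participant"`
switch instead removes the row of the same participant where present
(falling back to the index) for sensitivity analysis. When more than ten
participants responded to an image, only the first ten by arrival rank are
analysed; images with fewer than ten respondents are excluded with a logged
warning, since every between-image comparison assumes complete ten-row
matrices.

Degenerate inputs: a word reported once raises a rare-word error rather
than returning a score; a dataset with a single image raises an
undefined-score error (there is nothing to compare against); an experiment
in which every word is unique yields an empty score table.

## Preprocessing

Raw words pass through normalize → correct → lemmatize → dedupe, in that
fixed order (normalization first, so the spell checker sees hyphenated
lowercase tokens). Normalization lowercases, strips, collapses internal
whitespace runs to single hyphens (existing hyphens preserved) and converts
bare ASCII integers 0–100 to English number words; mixed alphanumerics such
as "2nd" are left to the spell-correction path.

Spelling and lemmatization are *provider contracts* (any callable with the
right shape), because the original workflow reviewed every suggestion by
hand. Proposals land in ledgers — (token, replacement, accepted) tables that
round-trip through CSV — and only accepted entries are applied. Spell
suggestions default to rejected; an optional conservative heuristic
auto-accepts a suggestion that is both present in the frequency dictionary
and within edit distance 2 of the token. Lemma proposals default to
accepted unless the lemma has length ≤ 2 while the source token is
hyphenated, which captures the degenerate-split class (e.g. a hyphenated
compound lemmatized to its first letter). Built-in providers are supplied:
a Norvig-style spell checker over the frequency table (highest-frequency
candidate within edit distance 2, distance 1 preferred; hyphenated tokens
whose parts are all known pass) and a suffix-rule English lemmatizer
(-s/-es/-ies/-ing/-ed plus a small irregular table) that only returns stems
found in its vocabulary. They are straightforward components adequate for
synthetic and lightly noisy data, not industrial NLP; ledger files let users
substitute any external tool's output.

Deduplication enforces within-trial uniqueness after lemmatization: the
lowest slot of each lemma survives, later repeats are dropped with reason
`duplicate-in-trial`, empty tokens with reason `empty`. Counts are
conserved and reported (input = surviving + dropped, per reason). The full
chain is idempotent on its own output, which the suite checks on simulated
data; idempotence of the auto-accept heuristic relies on accepted
corrections landing inside the dictionary, which holds by construction.

## The synthetic generator

`SimulationConfig` defaults encode the emulated design: 388 images, ten
respondents per image, 21 trials per participant (hence 185 participants —
the ceiling of 3880/21), five word slots with confidence 1–5, and a
vocabulary of 2000 pseudo-words whose per-billion counts follow a Zipf
power law (rank⁻¹, top word 10⁷·⁵ per billion; exponent 0 — uniform — is
allowed, negatives rejected). Assignment deals a seeded shuffled image deck
round-robin, wrapping until every participant holds 21 distinct images;
every image therefore reaches at least ten distinct respondents and
over-covered images are truncated downstream by the first-ten rule.

Each non-empty slot draws a latent category from `category_rates`
(defaults: exist .70, conceptual .15, insertion .05, confusion .05,
unrelated .05), then a word, frequency-weighted, from the matching pool:
the image's private content pool (10 words) with probability `specificity`
— else the whole vocabulary — for exist; a shared 30-word abstract pool for
conceptual; per-image gist-associate and alternative-gist pools (6 words
each, disjoint from the content pool) for insertion and confusion; the full
vocabulary for unrelated. Within-trial duplicates are resampled *within the
same category* (up to 30 tries, then the slot is emitted empty with
confidence 1), so emitted token category frequencies stay multinomial at
the configured rates. Confidence is a normal draw centred on the category's
mean (defaults: exist 4.2, conceptual 4.0, insertion 3.7, confusion 3.5,
unrelated 3.5; sd 0.7) rounded and clamped to 1–5 — note the clamp
compresses realized gaps below the injected ones. Slots are also left empty
("Don't Know") at rate 0.02, a modest allowance for respondents who cannot
produce five words. An optional typo-injection rate exercises the
spell-correction path; words are otherwise emitted clean.

What the generator emulates — and does not. It reproduces the report
*statistics* the IA analysis is sensitive to: word sharing across images
driven by frequency and content overlap, category-dependent confidence,
ten-respondent matrices. It contains no model of perception, masking or
exposure duration; "richer" versus "degraded" viewing enters only through
the specificity and category-rate knobs, and the mapping "degradation ≈
lower specificity" is a modeling convention for sensitivity tests, not a
claim about vision. Passing recovery tests therefore shows the *pipeline*
measures what it claims on data with known structure; it does not by itself
validate IA as a richness measure on human data.

A structural consequence worth naming: scorability (≥ 2 of 10 respondents
reporting the word) is category-dependent. Unrelated words, drawn from the
whole vocabulary, almost never repeat within an image, so their share among
*scored* words (~0.2%) is far below their share among emitted tokens (5%) —
the same funnelling real datasets show. Recovery of injected category rates
is therefore asserted at the token level (multinomial, 3 standard errors),
while the proportion tabulation over scored words is checked against an
independent count of the same ground-truth labels.

## Statistics

Pearson r, its two-sided p and 95% CI come from scipy. The correlation
BF₁₀ integrates the exact sampling density of r given ρ and n (the
hypergeometric form) over a uniform prior on (−1, 1) — the κ = 1
stretched-beta default — using 400-node Gauss–Legendre quadrature on the
log kernel; the suite cross-checks it against an independent closed-form
implementation (pingouin) to 10⁻⁴ relative tolerance. The one-way ANOVA
reports the classical F and p plus a BIC-approximated BF₁₀
(exp((BIC₀ − BIC₁)/2) under Gaussian likelihoods); it is labelled
`bf10_approx` everywhere because it is not the integrated Bayes factor of
JASP-style software, and agreement beyond order of magnitude should not be
expected. Post-hoc pairwise comparisons use the pooled within-group error
with Bonferroni correction. For two groups, F equals the squared pooled
t — asserted to 10⁻¹⁰ in the suite.

Unit-of-analysis choices: correlations and the confidence ANOVA operate on
word-image pairs (each scorable pair contributes one IA, one Zipf value,
one mean confidence over its reporting rows); per-image category
proportions divide by the number of scored words in that image, and the
experiment-level summary is the unweighted mean over images. Words missing
from the frequency table are excluded from the IA-frequency correlation
with a logged count.

## Problem sizes

The validation campaign (tests and `scripts/acceptance.py`) runs the full
design scale — 388 images, ten respondents, five seed replicates per
condition — for the recovery analyses, which completes in well under a
minute per replicate; oracle-equivalence sweeps use 1,000 randomized 3-8
image datasets over a 30-word vocabulary, the regime dense in the AUC
threshold ties that distinguish correct from naive tie handling. These
sizes were chosen to make every property measurable with comfortable
statistical margins while keeping a full run interactive.

## Known limitations

- The built-in spell checker and lemmatizer are deliberately simple; heavy
  real-world noise (multi-word corrections, context-dependent lemmas) needs
  external providers feeding ledgers.
- The BIC Bayes factor is an approximation; report it as such.
- The generator's category pools are static per image; it does not model
  respondent-level idiosyncrasy (vocabulary, verbosity) beyond sampling
  noise, so between-participant variance components are not recoverable.
- `label_set()` collapses token-level ground-truth categories to one label
  per (word, image) by majority with a fixed-order tiebreak, mirroring a
  single judge; token-level analyses should use `token_categories`
  directly.
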