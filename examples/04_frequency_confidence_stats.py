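"""Score a simulated experiment and run the downstream statistics.

Computes every word-image IA score, then: the IA vs Zipf-frequency Pearson
correlation (with its default Bayes factor), the category composition of
scored words, and the confidence-by-category ANOVA.
"""

from wordia import (
    SimulationConfig,
    anova_oneway,
    attach_zipf,
    build_response_matrices,
    category_proportions,
    compute_all_ia,
    confidence_per_word_image,
    pearson_with_bf,
    preprocess,
    simulate_experiment,
)

cfg = SimulationConfig(n_images=60, trials_per_participant=12, seed=11)
exp, truth, freq = simulate_experiment(cfg)
matrices = build_response_matrices(preprocess(exp).frame)
scores = compute_all_ia(matrices)
print(f"scored {len(scores)} word-image pairs over {scores.image_id.nunique()} "
      f"images; mean IA = {scores.ia.mean():.3f}")

joined = attach_zipf(scores, freq)
c = pearson_with_bf(joined["ia"], joined["zipf"])
print(f"\nIA vs Zipf frequency: r({c.n - 2}) = {c.r:.3f}, "
      f"p = {c.p_two_sided:.2g}, BF10 = {c.bf10:.3g}")
# negative r: words shared across many images (the frequent ones) are less
# diagnostic of any single image

labels = truth.label_set()
props = category_proportions(scores, labels)
print("\nmean per-image proportions among scored words:")
print(props.summary.round(3).to_string())

conf = confidence_per_word_image(matrices, scores)
merged = scores.merge(conf, on=["word", "image_id"])
merged["category"] = [labels.get(w, i) for w, i in zip(merged.word, merged.image_id)]
res = anova_oneway(merged["mean_confidence"], merged["category"])
print(f"\nconfidence by category: F({res.df_between}, {res.df_within}) = "
      f"{res.f:.1f}, p = {res.p:.2g}, BF10 (BIC approx.) = {res.bf10_approx:.3g}")
for cat, mean in sorted(res.group_means.items(), key=lambda kv: -kv[1]):
    print(f"  {cat:<12} mean confidence {mean:.2f}")
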