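"""Generate a synthetic free-report experiment and inspect its structure.

Builds a scaled-down version of the study design (30 images instead of 388,
ten respondents per image, five words + confidence per trial) and prints the
emitted token counts per latent category next to the configured rates.
"""

from wordia import SimulationConfig, simulate_experiment

cfg = SimulationConfig(n_images=30, trials_per_participant=10, seed=42)
exp, truth, freq = simulate_experiment(cfg)

print(f"participants: {cfg.n_participants}, images: {cfg.n_images}, "
      f"records: {len(exp.records)}")
print(f"vocabulary: {len(freq)} words, top Zipf = "
      f"{max(freq.zipf(w) for w in freq.words()):.2f}")

rates = truth.token_categories["category"].value_counts(normalize=True)
print("\ncategory        configured  emitted")
for cat, rate in cfg.category_rates.items():
    print(f"{cat:<15} {rate:>9.3f} {rates.get(cat, 0.0):>8.3f}")

# Emitted rates track the configured multinomial: each nonempty slot draws
# its category first, then a word from the matching pool.
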