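"""Static-context (bystander) evaluation with synthetic votes.

Generates the default 40-dialogue evaluation set (two dialogues per
context, four candidate responses each, the system's true response hidden
at position 0), simulates 11 evaluators voting for the most appropriate
candidate, and reports the voted-appropriateness summary: Rvoted counts,
tie-inclusive agreement percentages and the Pearson correlation between
the system's votes and the per-dialogue maximum.
"""

from recuerda import (
    FixtureConfig,
    agreement_percentages,
    default_kb,
    generate_evaluation_set,
    generate_profile,
    generate_votes,
    pearson,
    rvoted,
)

kb = default_kb()
profile = generate_profile(seed=3)
dialogues = generate_evaluation_set(kb, profile, FixtureConfig(seed=3))
votes = generate_votes(dialogues, n_evaluators=11, seed=3)
print(f"{len(dialogues)} dialogues, 11 evaluators\n")

results = [rvoted(d, v) for d, v in zip(dialogues, votes)]
print("first five dialogues (Rvoted per candidate, Rmax):")
for res in results[:5]:
    print(f"  {res.dialogue_id:22s} {res.counts}  Rmax={res.rmax}")

pct = agreement_percentages(dialogues, votes)
for label, p in zip(["system", "cand-1", "cand-2", "cand-3"], pct):
    print(f"agreement with most-voted, {label}: {p:.1f}%")

corr = pearson([r.counts[0] for r in results], [r.rmax for r in results])
print(f"\nPearson r (system Rvoted vs Rmax): {corr.r:.3f} "
      f"(p={corr.p_value:.2g}, n={corr.n})")
print("A high share of dialogues where the system's response is the most "
      "voted, and a positive r, indicate appropriate responses.")
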