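"""Quote-tweet mutation: QT/RT profiles, commentary prediction, evaluation.

Builds per-user mutation profiles from the training periods (QT:RT ratio and
quote history), predicts added commentary for held-out Period III quote
events with the nearest-neighbour retrieval generator, and scores the
predictions by embedding cosine similarity against the true commentary.
"""

import misinfosim as m
from misinfosim.mutation import split_quote_text

# a posting-heavy, quote-happy world: the 25/20 QT eligibility thresholds
# require substantial per-user quote history on both sides of the split
cfg = m.SyntheticConfig(
    n_users=200, n_communities=4, posts_per_user=80.0,
    qt_fraction_range=(0.5, 0.9), seed=7,
)
world = m.generate_world(cfg)
periods = m.PeriodSpec.default()
log = m.generate_engagement_log(world, periods.full_window, seed=8)

profiles = m.build_mutation_profiles(log, periods)
eligible = [p for p in profiles.values() if p.eligible]
print(f"{len(profiles)} users with reshare history; {len(eligible)} eligible "
      f"(>= 25 training QTs and >= 20 evaluation QTs)")

embedder = m.HashingEmbedder(seed=0)
generator = m.NearestNeighbourGenerator(embedder)

predictions, truths = [], []
evaluation = log.in_window(periods.period_iii)
for prof in eligible[:20]:
    for r in evaluation.records:
        if r.user_id == prof.user and r.type == "quote":
            true_ac, parent_text = split_quote_text(r.text)
            predictions.append(generator.generate(prof.qt_history, parent_text))
            truths.append(true_ac)

score = m.evaluate_commentary(predictions, truths, embedder)
print(f"{len(predictions)} held-out quote events; "
      f"mean commentary cosine similarity: {score:.3f}")

prof = eligible[0]
text, mutated = m.mutate(generator, prof, "t00p t01n t02p")
print(f"example mutation by {prof.user} (QM={prof.qm:.2f}): {text!r}")
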