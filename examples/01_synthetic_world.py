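"""Generate a synthetic engagement world and inspect its structure.

Creates a community-structured user population with heavy-tailed follower
counts and simulates two months of posting and resharing.  The printed
reshare rate is per exposure (follower x post pair), and the degree summary
shows the heavy tail the follow graph plants.
"""

import numpy as np

import misinfosim as m

cfg = m.SyntheticConfig(n_users=200, n_communities=4, seed=7)
world = m.generate_world(cfg)
log = m.generate_engagement_log(world, m.PeriodSpec.default().training_window, seed=8)

n_posts = sum(r.type == "post" for r in log.records)
n_reshares = len(log) - n_posts
exposures = sum(
    len(world.followers_of(r.user_id)) for r in log.records if r.type == "post"
)
followers = sorted(len(world.followers_of(u)) for u in world.users)

print(f"users: {cfg.n_users} in {cfg.n_communities} communities")
print(f"posts: {n_posts}, reshares: {n_reshares} "
      f"({100 * n_reshares / exposures:.1f}% of {exposures} exposures)")
print(f"follower counts: median {followers[len(followers) // 2]}, max {followers[-1]}")

# the planted rule: reshare probability rises with preference-topic affinity
f, o = sorted(world.follow_graph)[0]
aligned = world.true_reshare_prob(f, o, world.preference[f])
opposed = world.true_reshare_prob(f, o, -world.preference[f])
print(f"planted reshare probability for {f}: aligned topic {aligned:.3f} "
      f"vs opposed topic {opposed:.4f}")
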