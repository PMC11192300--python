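"""Build the information-flow network and partition it into communities.

Edges point originator -> resharer and exist only where the log shows at
least one reshare; the snowball step grows a bounded subnetwork around a
seed user by total reshare involvement; Leiden partitions the result and
c-TF-IDF labels each community by its most distinctive vocabulary.
"""

import misinfosim as m

cfg = m.SyntheticConfig(n_users=200, n_communities=4, seed=7)
world = m.generate_world(cfg)
log = m.generate_engagement_log(world, m.PeriodSpec.default().training_window, seed=8)

network = m.infer_edges(log)
print(f"information-flow network: {network.n_nodes} nodes, {network.n_edges} edges")

hub = max(network.nodes, key=network.follower_count)
selected, sub = m.snowball_subnetwork(network, {hub}, set(network.nodes), target_size=50)
print(f"snowball from {hub}: kept {sub.n_nodes} users, {sub.n_edges} edges")

partition = m.detect_communities(network, resolution=1.0, seed=0)
labels = m.label_communities(log, partition, top_k=3)
for c in partition.communities:
    print(f"community {c}: {partition.sizes[c]} users, label terms {labels[c]}")
# label terms are synthetic topic-vocabulary tokens (t<dim><sign>): distinct
# communities surface distinct dimensions of the latent topic space
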