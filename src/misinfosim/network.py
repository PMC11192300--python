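"""Information-flow network construction, subnetwork selection and communities.

The directed edge i -> j exists when user j has reshared at least one post
authored by user i; its weight |R_ij| is the number of distinct such posts.
Information flows along the edge direction (originator -> resharer), so the
"followers" of i are exactly the users j with an edge i -> j: the people the
engagement history shows actually relay i's content, whether or not a
platform follow relationship exists.
"""

from __future__ import annotations

import csv
import json
import logging
import math
import re
from collections import Counter, defaultdict
from dataclasses import dataclass, field
from datetime import datetime
from pathlib import Path
from typing import Iterable

import igraph as ig
import leidenalg
import numpy as np

from .log import EngagementLog

logger = logging.getLogger(__name__)


@dataclass
class InfoFlowNetwork:
    """Directed, integer-weighted information-flow graph.

    ``weights[(i, j)]`` is |R_ij|, the number of distinct posts authored by i
    that j reshared; an edge exists iff its weight is positive, so the edge
    indicator never needs separate bookkeeping.
    """

    nodes: list[str]
    weights: dict[tuple[str, str], int]

    def __post_init__(self) -> None:
        self._followers: dict[str, list[str]] = defaultdict(list)
        self._followees: dict[str, list[str]] = defaultdict(list)
        for (i, j), w in self.weights.items():
            if w <= 0:
                raise ValueError(f"edge ({i}, {j}) has non-positive weight {w}")
            if i == j:
                raise ValueError(f"self-loop on {i}")
            self._followers[i].append(j)
            self._followees[j].append(i)
        for d in (self._followers, self._followees):
            for u in d:
                d[u].sort()
        self._node_set = set(self.nodes)

    def __contains__(self, user: str) -> bool:
        return user in self._node_set

    @property
    def n_nodes(self) -> int:
        return len(self.nodes)

    @property
    def n_edges(self) -> int:
        return len(self.weights)

    def weight(self, i: str, j: str) -> int:
        return self.weights.get((i, j), 0)

    def has_edge(self, i: str, j: str) -> bool:
        return (i, j) in self.weights

    def followers(self, user: str) -> list[str]:
        """Users who reshare ``user``'s posts (edge user -> follower)."""
        return self._followers.get(user, [])

    def followees(self, user: str) -> list[str]:
        """Users whose posts ``user`` reshares."""
        return self._followees.get(user, [])

    def follower_count(self, user: str) -> int:
        return len(self._followers.get(user, ()))

    def followee_count(self, user: str) -> int:
        return len(self._followees.get(user, ()))

    def subgraph(self, users: Iterable[str]) -> "InfoFlowNetwork":
        keep = set(users)
        return InfoFlowNetwork(
            nodes=sorted(keep),
            weights={(i, j): w for (i, j), w in self.weights.items() if i in keep and j in keep},
        )

    # ------------------------------------------------------------------ io

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["src", "dst", "weight"])
            for (i, j) in sorted(self.weights):
                w.writerow([i, j, self.weights[(i, j)]])

    @classmethod
    def read_csv(cls, path: str | Path) -> "InfoFlowNetwork":
        weights: dict[tuple[str, str], int] = {}
        nodes: set[str] = set()
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                weights[(row["src"], row["dst"])] = int(row["weight"])
                nodes.update((row["src"], row["dst"]))
        return cls(nodes=sorted(nodes), weights=weights)


def infer_edges(
    log: EngagementLog, window: tuple[datetime, datetime] | None = None
) -> InfoFlowNetwork:
    """Build the information-flow network from reshare events.

    For every ordered user pair (i, j) the edge weight is the number of
    distinct posts authored by i inside ``window`` and reshared by j inside
    ``window`` (quotes count as reshares; self-reshares create no edge).
    Reshares whose parent post is absent from the log are skipped, counted
    and reported via a warning.
    """
    sub = log.in_window(window) if window is not None else log
    pairs: set[tuple[str, str, str]] = set()
    nodes: set[str] = set()
    skipped = 0
    for r in sub.records:
        nodes.add(r.user_id)
        if not r.is_reshare:
            continue
        parent = sub.get(r.parent_post_id)
        if parent is None:
            skipped += 1
            continue
        author = parent.user_id
        nodes.add(author)
        if author == r.user_id:
            continue  # self-reshares carry no inter-user pathway
        pairs.add((author, r.user_id, parent.post_id))
    if skipped:
        logger.warning("skipped %d reshares referencing posts outside the log/window", skipped)
    weights = Counter((i, j) for i, j, _ in pairs)
    return InfoFlowNetwork(nodes=sorted(nodes), weights=dict(weights))


def snowball_subnetwork(
    network: InfoFlowNetwork,
    seed_set: Iterable[str],
    candidate_pool: Iterable[str],
    target_size: int,
) -> tuple[list[str], InfoFlowNetwork]:
    """Grow a bounded subnetwork around a seed set by modified snowball sampling.

    Starting from the seed users, every candidate outside the current set is
    scored by its total reshare involvement with the set — incoming plus
    outgoing weights, equally weighted — and the best-scoring candidate is
    added; scores are refreshed and the process repeats until ``target_size``
    users are selected.  Ties break on lexicographically smallest user id.

    Returns the selected users (seed users first, then in order of addition)
    and the induced subnetwork.
    """
    selected = sorted(set(seed_set))
    pool = set(candidate_pool)
    if not set(selected) <= pool:
        raise ValueError("seed set must be contained in the candidate pool")
    if not pool <= set(network.nodes):
        raise ValueError("candidate pool contains users absent from the network")
    if target_size < len(selected):
        raise ValueError(f"target_size {target_size} smaller than seed set {len(selected)}")
    if target_size > len(pool):
        raise ValueError(f"target_size {target_size} exceeds candidate pool {len(pool)}")

    in_set = set(selected)
    # score(u) = sum_{j in selected} |R_ju| + |R_uj|; maintained incrementally
    score: dict[str, float] = {}
    for u in pool - in_set:
        score[u] = sum(network.weight(j, u) + network.weight(u, j) for j in in_set)
    while len(selected) < target_size:
        best = min(score, key=lambda u: (-score[u], u))
        selected.append(best)
        in_set.add(best)
        del score[best]
        for u in score:
            score[u] += network.weight(best, u) + network.weight(u, best)
    return selected, network.subgraph(selected)


@dataclass
class CommunityPartition:
    """Assignment of every network node to exactly one community."""

    community_of: dict[str, int]
    labels: dict[int, list[str]] = field(default_factory=dict)

    @property
    def sizes(self) -> dict[int, int]:
        out: dict[int, int] = defaultdict(int)
        for c in self.community_of.values():
            out[c] += 1
        return dict(out)

    @property
    def communities(self) -> list[int]:
        return sorted(set(self.community_of.values()))

    def members(self, community: int) -> list[str]:
        return sorted(u for u, c in self.community_of.items() if c == community)

    def write_csv(self, path: str | Path) -> None:
        with open(path, "w", newline="") as fh:
            w = csv.writer(fh)
            w.writerow(["user_id", "community_id"])
            for u in sorted(self.community_of):
                w.writerow([u, self.community_of[u]])

    @classmethod
    def read_csv(cls, path: str | Path) -> "CommunityPartition":
        out: dict[str, int] = {}
        with open(path, newline="") as fh:
            for row in csv.DictReader(fh):
                out[row["user_id"]] = int(row["community_id"])
        return cls(community_of=out)

    def write_labels_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump({str(k): v for k, v in self.labels.items()}, fh, indent=2)


def detect_communities(
    network: InfoFlowNetwork, resolution: float = 1.0, seed: int = 0
) -> CommunityPartition:
    """Partition the network into communities with the Leiden algorithm.

    The directed graph is symmetrized (weights summed across the two
    directions) before optimization, the standard projection for
    modularity-style community detection; directionality is retained only for
    simulation.  Deterministic for a fixed seed.
    """
    if network.n_nodes == 0:
        raise ValueError("empty network")
    sym: dict[tuple[str, str], float] = defaultdict(float)
    for (i, j), w in network.weights.items():
        a, b = (i, j) if i < j else (j, i)
        sym[(a, b)] += w
    index = {u: k for k, u in enumerate(network.nodes)}
    g = ig.Graph(
        n=network.n_nodes,
        edges=[(index[a], index[b]) for (a, b) in sym],
        edge_attrs={"weight": list(sym.values())},
    )
    part = leidenalg.find_partition(
        g,
        leidenalg.RBConfigurationVertexPartition,
        weights="weight",
        resolution_parameter=resolution,
        seed=seed,
    )
    community_of = {u: part.membership[index[u]] for u in network.nodes}
    return CommunityPartition(community_of=community_of)


_TOKEN_RE = re.compile(r"[^0-9a-z]+")


def tokenize(text: str) -> list[str]:
    """Lowercase, split on non-alphanumerics, drop tokens shorter than 2."""
    return [t for t in _TOKEN_RE.split(text.lower()) if len(t) >= 2]


def label_communities(
    log: EngagementLog,
    partition: CommunityPartition,
    top_k: int = 10,
    sample_per_community: int = 10_000,
    seed: int = 0,
) -> dict[int, list[str]]:
    """Label communities by class-based TF-IDF over sampled member posts.

    For community c and term t the score is ``tf(t, c) * log(1 + A / f(t))``
    where tf counts t in c's pooled sample, f(t) counts t across all
    communities' samples, and A is the average term count per community.
    Original posts and quote commentary are used as documents (retweets
    duplicate their parent's text).  Returns the ``top_k`` terms per
    community and stores them on the partition.
    """
    rng = np.random.default_rng(seed)
    docs_by_comm: dict[int, list[str]] = defaultdict(list)
    for r in log.records:
        if r.type == "retweet":
            continue
        c = partition.community_of.get(r.user_id)
        if c is not None:
            docs_by_comm[c].append(r.text)

    tf: dict[int, Counter] = {}
    for c in partition.communities:
        docs = docs_by_comm.get(c, [])
        if not docs:
            logger.warning("community %d has no posts; empty label", c)
            tf[c] = Counter()
            continue
        if len(docs) > sample_per_community:
            idx = rng.choice(len(docs), size=sample_per_community, replace=False)
            docs = [docs[i] for i in sorted(idx)]
        counts: Counter = Counter()
        for d in docs:
            counts.update(tokenize(d))
        tf[c] = counts

    overall: Counter = Counter()
    for counts in tf.values():
        overall.update(counts)
    n_comm = max(len(tf), 1)
    avg_terms = sum(overall.values()) / n_comm  # A: average term count per community

    labels: dict[int, list[str]] = {}
    for c, counts in tf.items():
        scored = sorted(
            counts.items(),
            key=lambda kv: (-kv[1] * math.log(1.0 + avg_terms / overall[kv[0]]), kv[0]),
        )
        labels[c] = [t for t, _ in scored[:top_k]]
    partition.labels = labels
    return labels


def ctfidf_scores(
    term_counts: dict[int, Counter],
) -> dict[int, dict[str, float]]:
    """Raw class-based TF-IDF scores for pre-counted community vocabularies."""
    overall: Counter = Counter()
    for counts in term_counts.values():
        overall.update(counts)
    avg_terms = sum(overall.values()) / max(len(term_counts), 1)
    return {
        c: {t: n * math.log(1.0 + avg_terms / overall[t]) for t, n in counts.items()}
        for c, counts in term_counts.items()
    }
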