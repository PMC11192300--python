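"""Synthetic social worlds with planted community and topic structure.

Real engagement histories of misinformation-sharing networks are not
redistributable, so the pipeline is exercised end-to-end on generated data
that reproduces the statistical structure the method assumes: users grouped
into communities, heavy-tailed follower counts, per-user latent topic
preferences, and reshare decisions whose probability rises with the affinity
between a follower's preference and the post topic.  The generator also
exposes the ground-truth reshare probabilities, enabling parameter-recovery
tests that real data can never support.

Synthetic "text" is a token string derived deterministically from a post's
latent topic vector (a topic-specific vocabulary), so the hashing embedder
can invert it and text-sensitive components remain testable without any
pretrained language model.
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict
from datetime import datetime, timedelta
from pathlib import Path
from typing import Callable

import numpy as np
import yaml

from .log import EngagementLog, EngagementRecord


def _sigmoid(x: float) -> float:
    return 1.0 / (1.0 + np.exp(-x))


@dataclass
class SyntheticConfig:
    """Knobs of the generative world; defaults are the package's stated world.

    ``base_logit`` sets the baseline reshare odds (−3 ≈ 4.7%) and ``affinity``
    (λ) scales how strongly a follower's preference–topic alignment shifts
    those odds.  ``degree_exponent`` is the Pareto tail index of per-user
    popularity weights; ``None`` disables degree heterogeneity.
    """

    n_users: int = 500
    n_communities: int = 5
    latent_dim: int = 8
    within_community_follow_prob: float = 0.05
    across_community_follow_prob: float = 0.02
    degree_exponent: float | None = 2.5
    posts_per_user: float = 40.0
    base_logit: float = -5.5
    affinity: float = 6.0
    preference_noise: float = 0.2
    post_topic_noise: float = 0.1
    qt_fraction_range: tuple[float, float] = (0.0, 0.3)
    reshare_delay_hours: float = 6.0
    seed: int = 0

    def validate(self) -> None:
        if self.n_users < 1:
            raise ValueError("n_users must be positive")
        if self.n_communities < 1 or self.n_communities > self.n_users:
            raise ValueError("n_communities must be in [1, n_users]")
        if self.latent_dim < 1:
            raise ValueError("latent_dim must be positive")
        for name in ("within_community_follow_prob", "across_community_follow_prob"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} must lie in [0, 1], got {p}")
        if self.degree_exponent is not None and self.degree_exponent <= 0:
            raise ValueError("degree_exponent must be positive or None")
        if self.posts_per_user < 0:
            raise ValueError("posts_per_user must be non-negative")
        if self.reshare_delay_hours <= 0:
            raise ValueError("reshare_delay_hours must be positive")
        if self.preference_noise < 0 or self.post_topic_noise < 0:
            raise ValueError("noise levels must be non-negative")
        lo, hi = self.qt_fraction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError(f"qt_fraction_range must be an interval in [0, 1], got {self.qt_fraction_range}")

    def to_yaml(self, path: str | Path) -> None:
        d = asdict(self)
        d["qt_fraction_range"] = list(self.qt_fraction_range)
        with open(path, "w") as fh:
            yaml.safe_dump(d, fh)

    @classmethod
    def from_yaml(cls, path: str | Path) -> "SyntheticConfig":
        with open(path) as fh:
            d = yaml.safe_load(fh)
        if "qt_fraction_range" in d:
            d["qt_fraction_range"] = tuple(d["qt_fraction_range"])
        return cls(**d)


def text_from_topic(topic: np.ndarray, max_dims: int = 6, scale: int = 6) -> str:
    """Deterministic token string encoding a topic vector.

    Each latent dimension owns two vocabulary tokens (positive / negative
    sign); the ``max_dims`` largest-magnitude components contribute their
    token repeated proportionally to the component magnitude.
    """
    order = np.argsort(-np.abs(topic), kind="stable")[:max_dims]
    tokens: list[str] = []
    for k in order:
        v = float(topic[k])
        if v == 0.0:
            continue
        tok = f"t{k:02d}{'p' if v > 0 else 'n'}"
        tokens.extend([tok] * max(1, round(scale * abs(v))))
    return " ".join(tokens) if tokens else "t00p"


@dataclass
class SeedPost:
    """A post used to seed the cascade simulator."""

    author: str
    text: str
    topic: np.ndarray
    label: str | None = None


@dataclass
class SyntheticWorld:
    """Generative ground truth: who can see whom, and who reshares what."""

    config: SyntheticConfig
    users: list[str]
    community_of: dict[str, int]
    preference: dict[str, np.ndarray]
    topic_centroids: np.ndarray  # (K, d), unit rows
    follow_graph: set[tuple[str, str]]  # (follower, followee): follower sees followee's posts
    qt_fraction: dict[str, float]
    _followers_of: dict[str, list[str]] = field(default_factory=dict, repr=False)

    def __post_init__(self) -> None:
        if not self._followers_of:
            out: dict[str, list[str]] = {u: [] for u in self.users}
            for f, o in sorted(self.follow_graph):
                out[o].append(f)
            self._followers_of = out

    def followers_of(self, user: str) -> list[str]:
        """Users who see ``user``'s posts."""
        return self._followers_of.get(user, [])

    def true_reshare_prob(self, follower: str, originator: str, topic: np.ndarray) -> float:
        """P(follower reshares a post with this topic) — logistic in affinity."""
        z = self.config.base_logit + self.config.affinity * float(
            self.preference[follower] @ topic
        )
        return float(_sigmoid(z))

    def write_follow_graph_csv(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            fh.write("src,dst\n")
            for f, o in sorted(self.follow_graph):
                fh.write(f"{f},{o}\n")


def generate_world(config: SyntheticConfig) -> SyntheticWorld:
    """Sample a world: block-structured follow graph plus latent preferences.

    The follow graph is a degree-corrected stochastic block model — the
    within/across block probabilities are scaled per-followee by a Pareto
    popularity weight, producing heavy-tailed follower counts.  Preferences
    are unit vectors scattered around the (orthonormalized) community
    centroid.
    """
    config.validate()
    rng = np.random.default_rng(config.seed)
    n, k, d = config.n_users, config.n_communities, config.latent_dim
    users = [f"u{i:05d}" for i in range(n)]
    comm = np.arange(n) % k
    community_of = {u: int(c) for u, c in zip(users, comm)}

    raw = rng.standard_normal((d, k))
    if k <= d:  # orthonormal centroids: maximally separated topics
        q, _ = np.linalg.qr(raw)
        centroids = q[:, :k].T
    else:
        centroids = raw.T / np.linalg.norm(raw.T, axis=1, keepdims=True)

    prefs = centroids[comm] + config.preference_noise * rng.standard_normal((n, d))
    prefs /= np.linalg.norm(prefs, axis=1, keepdims=True)
    preference = {u: prefs[i] for i, u in enumerate(users)}

    if config.degree_exponent is not None:
        w = rng.pareto(config.degree_exponent, size=n) + 1.0
        w /= w.mean()
    else:
        w = np.ones(n)

    same = comm[:, None] == comm[None, :]
    base = np.where(same, config.within_community_follow_prob, config.across_community_follow_prob)
    # edge (follower i, followee j): popular followees attract more followers
    p_edge = np.clip(base * w[None, :], 0.0, 1.0)
    np.fill_diagonal(p_edge, 0.0)
    adj = rng.random((n, n)) < p_edge
    follow_graph = {(users[i], users[j]) for i, j in zip(*np.nonzero(adj))}

    lo, hi = config.qt_fraction_range
    qt_fraction = {u: float(q) for u, q in zip(users, rng.uniform(lo, hi, size=n))}

    return SyntheticWorld(
        config=config,
        users=users,
        community_of=community_of,
        preference=preference,
        topic_centroids=centroids,
        follow_graph=follow_graph,
        qt_fraction=qt_fraction,
    )


def generate_engagement_log(
    world: SyntheticWorld,
    window: tuple[datetime, datetime],
    seed: int,
    reshare_prob_override: float | Callable[[str, str, np.ndarray], float] | None = None,
) -> EngagementLog:
    """Simulate posting and resharing over a time window.

    Every user authors a Poisson number of posts with topics near their
    preference; every follower of the author sees each post and reshares it
    with the world's true reshare probability (override available for edge
    cases), choosing quote over retweet with their personal QT fraction.
    Quote commentary prepends the quoter's preference vocabulary to the
    parent text, giving mutation evaluation a meaningful ground truth.
    """
    if not world.users:
        raise ValueError("empty world")
    cfg = world.config
    rng = np.random.default_rng(seed)
    start, end = window
    span = (end - start).total_seconds()
    if span <= 0:
        raise ValueError("window must have positive length")

    pref_matrix = np.stack([world.preference[u] for u in world.users])
    user_index = {u: i for i, u in enumerate(world.users)}

    records: list[EngagementRecord] = []
    post_topics: dict[str, np.ndarray] = {}
    counter = 0

    def _ts(lo: float, hi: float) -> datetime:
        return start + timedelta(seconds=float(rng.uniform(lo, hi)))

    for u in world.users:
        n_posts = rng.poisson(cfg.posts_per_user)
        for _ in range(n_posts):
            topic = world.preference[u] + cfg.post_topic_noise * rng.standard_normal(cfg.latent_dim)
            topic /= np.linalg.norm(topic)
            post_ts = _ts(0.0, span)
            post_id = f"p{counter:07d}"
            post_topics[post_id] = topic
            counter += 1
            records.append(
                EngagementRecord(
                    post_id=post_id,
                    parent_post_id=None,
                    user_id=u,
                    originator_id=u,
                    type="post",
                    timestamp=post_ts,
                    text=text_from_topic(topic),
                )
            )
            followers = world.followers_of(u)
            if not followers:
                continue
            if reshare_prob_override is None:
                idx = np.array([user_index[f] for f in followers])
                z = cfg.base_logit + cfg.affinity * (pref_matrix[idx] @ topic)
                probs = 1.0 / (1.0 + np.exp(-z))
            elif callable(reshare_prob_override):
                probs = np.array([reshare_prob_override(f, u, topic) for f in followers])
            else:
                probs = np.full(len(followers), float(reshare_prob_override))
            draws = rng.random(len(followers))
            offset = (post_ts - start).total_seconds()
            for f, p, x in zip(followers, probs, draws):
                if x >= p:
                    continue
                is_qt = rng.random() < world.qt_fraction[f]
                base_text = text_from_topic(topic)
                if is_qt:
                    # commentary drifts around the quoter's preference so the
                    # mutation evaluator has a non-constant target per user
                    cvec = world.preference[f] + cfg.preference_noise * rng.standard_normal(
                        cfg.latent_dim
                    )
                    cvec /= np.linalg.norm(cvec)
                    commentary = text_from_topic(cvec, max_dims=3, scale=2)
                    text = f"{commentary}: {base_text}"
                else:
                    text = base_text
                # reshares trail their parent by a short exponential delay
                delay = rng.exponential(cfg.reshare_delay_hours * 3600.0)
                records.append(
                    EngagementRecord(
                        post_id=f"p{counter:07d}",
                        parent_post_id=post_id,
                        user_id=f,
                        originator_id=u,
                        type="quote" if is_qt else "retweet",
                        timestamp=start + timedelta(seconds=min(offset + delay, span)),
                        text=text,
                    )
                )
                counter += 1

    records.sort(key=lambda r: (r.timestamp, r.post_id))
    log = EngagementLog(records)
    # ground-truth topic per original post, for parameter-recovery tests
    log.post_topics = post_topics  # type: ignore[attr-defined]
    return log


def generate_seed_posts(
    world: SyntheticWorld,
    n: int,
    topics: list[np.ndarray | str] | None = None,
    author: str | None = None,
) -> list[SeedPost]:
    """Seed posts with chosen topics; author defaults to the most-followed user.

    ``topics`` entries may be latent vectors or community labels of the form
    ``"community-<k>"`` (resolved to that community's centroid); by default
    community centroids are cycled.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    k = world.config.n_communities
    known = [f"community-{i}" for i in range(k)]
    if author is None:
        author = max(world.users, key=lambda u: (len(world.followers_of(u)), u))
    if author not in set(world.users):
        raise ValueError(f"unknown author {author}")

    resolved: list[tuple[np.ndarray, str | None]] = []
    for i in range(n):
        t = topics[i % len(topics)] if topics else known[i % k]
        if isinstance(t, str):
            if t not in known:
                raise ValueError(f"unknown topic label {t!r}; known labels: {known}")
            vec = world.topic_centroids[int(t.split("-")[1])]
            resolved.append((vec, t))
        else:
            vec = np.asarray(t, dtype=float)
            vec = vec / np.linalg.norm(vec)
            resolved.append((vec, None))
    return [
        SeedPost(author=author, text=text_from_topic(vec), topic=vec, label=lab)
        for vec, lab in resolved
    ]
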