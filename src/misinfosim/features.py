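"""Feature construction for the infection model.

Each candidate transmission (follower f_j, originator u_k, tweet T_i) is
described by a fixed-length vector: behavioral statistics of both users,
a 24-dim summary of what u_k historically authored, a 24-dim summary of what
f_j historically reshared, and a 96-dim embedding of the tweet itself.  The
tweet-level embedding is deliberately larger than the user-level ones so the
model stays sensitive to the text that is actually spreading.

Text embedding is pluggable behind the :class:`Embedder` protocol.  The
default :class:`HashingEmbedder` maps token counts through a seeded random
projection to 384 dimensions — deterministic, dependency-free, and able to
invert the synthetic generator's topic vocabulary.  A production deployment
would substitute a pretrained sentence encoder of the same dimension.
"""

from __future__ import annotations

import hashlib
import logging
from dataclasses import dataclass
from datetime import datetime
from typing import Iterable, Protocol

import numpy as np

from .log import EngagementLog, RESHARE_TYPES
from .network import InfoFlowNetwork, tokenize

logger = logging.getLogger(__name__)

USER_STAT_NAMES = (
    "follower_count",
    "followee_count",
    "follower_followee_ratio",
    "retweeted_frequency",
    "retweeting_frequency",
    "qt_count",
    "rt_count",
)


@dataclass(frozen=True)
class UserStats:
    """Behavioral statistics of one user over a window."""

    follower_count: int
    followee_count: int
    follower_followee_ratio: float
    retweeted_frequency: float
    retweeting_frequency: float
    qt_count: int
    rt_count: int

    def as_array(self) -> np.ndarray:
        return np.array([getattr(self, n) for n in USER_STAT_NAMES], dtype=float)


def compute_user_stats(
    log: EngagementLog,
    network: InfoFlowNetwork,
    user: str,
    window: tuple[datetime, datetime] | None = None,
    profiles: dict[str, tuple[int, int]] | None = None,
) -> UserStats:
    """Tally a user's posting and resharing behavior.

    Follower/followee counts come from profile metadata when supplied
    (``profiles[user] = (followers, followees)``) and otherwise from the
    information-flow network's degrees.  ``retweeted_frequency`` is reshares
    received per post authored; ``retweeting_frequency`` is reshares made per
    followee post observed.
    """
    if user not in network:
        raise ValueError(f"user {user!r} not in network")
    sub = log.in_window(window) if window is not None else log
    if profiles is not None and user in profiles:
        follower_count, followee_count = profiles[user]
    else:
        follower_count = network.follower_count(user)
        followee_count = network.followee_count(user)

    n_authored = 0
    reshares_received = 0
    qt_count = rt_count = 0
    followees = set(network.followees(user))
    followee_posts_observed = 0
    active = False
    for r in sub.records:
        if r.user_id == user:
            active = True
            if r.type == "post":
                n_authored += 1
            elif r.type == "quote":
                qt_count += 1
            elif r.type == "retweet":
                rt_count += 1
        elif r.is_reshare and r.originator_id == user:
            reshares_received += 1
        if r.type == "post" and r.user_id in followees:
            followee_posts_observed += 1
    if not active:
        logger.warning("user %s absent from log; zero-activity stats", user)

    return UserStats(
        follower_count=follower_count,
        followee_count=followee_count,
        follower_followee_ratio=follower_count / max(followee_count, 1),
        retweeted_frequency=reshares_received / n_authored if n_authored else 0.0,
        retweeting_frequency=(qt_count + rt_count) / followee_posts_observed
        if followee_posts_observed
        else 0.0,
        qt_count=qt_count,
        rt_count=rt_count,
    )


class Embedder(Protocol):
    """Text → fixed-dimension vector; must be deterministic."""

    dimension: int

    def embed(self, text: str) -> np.ndarray: ...


class HashingEmbedder:
    """Seeded random-projection embedder over token counts.

    Every token owns a fixed Gaussian direction derived by hashing
    ``(seed, token)``; a text embeds to the count-weighted sum of its tokens'
    directions, normalized to unit length (zero vector for empty text).
    """

    def __init__(self, dimension: int = 384, seed: int = 0):
        self.dimension = dimension
        self.seed = seed
        self._cache: dict[str, np.ndarray] = {}

    def _token_vector(self, token: str) -> np.ndarray:
        vec = self._cache.get(token)
        if vec is None:
            digest = hashlib.blake2b(
                f"{self.seed}:{token}".encode(), digest_size=8
            ).digest()
            rng = np.random.default_rng(int.from_bytes(digest, "little"))
            vec = rng.standard_normal(self.dimension)
            self._cache[token] = vec
        return vec

    def embed(self, text: str) -> np.ndarray:
        tokens = tokenize(text)
        if not tokens:
            return np.zeros(self.dimension)
        out = np.zeros(self.dimension)
        for t in tokens:
            out += self._token_vector(t)
        norm = np.linalg.norm(out)
        return out / norm if norm > 0 else out

    def embed_many(self, texts: Iterable[str]) -> np.ndarray:
        return np.stack([self.embed(t) for t in texts])


@dataclass
class Reducer:
    """Linear reduction of embeddings to a smaller dimension.

    Fit as the exact optimum of a linear autoencoder (centre, project onto
    the top principal directions), so ``encode`` is an affine map and the
    reconstruction error is the minimum any linear encoder/decoder pair of
    this width can achieve.
    """

    mean: np.ndarray
    components: np.ndarray  # (output_dim, input_dim), orthonormal rows

    @property
    def input_dim(self) -> int:
        return self.components.shape[1]

    @property
    def output_dim(self) -> int:
        return self.components.shape[0]

    def encode(self, x: np.ndarray) -> np.ndarray:
        x = np.asarray(x, dtype=float)
        return (x - self.mean) @ self.components.T

    def decode(self, z: np.ndarray) -> np.ndarray:
        return np.asarray(z, dtype=float) @ self.components + self.mean

    def reconstruction_error(self, x: np.ndarray) -> float:
        x = np.atleast_2d(np.asarray(x, dtype=float))
        rec = self.decode(self.encode(x))
        return float(np.mean(np.sum((x - rec) ** 2, axis=1)))


def fit_reducer(embeddings: np.ndarray, output_dim: int, seed: int = 0) -> Reducer:
    """Fit the reduction on a pool of embeddings via SVD.

    ``seed`` is accepted for interface stability; the linear optimum is
    seed-free.  Component signs are fixed (largest-magnitude entry positive)
    so repeated fits agree bit-for-bit.
    """
    x = np.asarray(embeddings, dtype=float)
    if x.ndim != 2:
        raise ValueError("embeddings must be a 2-D array")
    n, d = x.shape
    if output_dim < 1 or output_dim > d:
        raise ValueError(f"output_dim must be in [1, {d}]")
    if n < output_dim:
        raise ValueError(f"need at least {output_dim} training vectors, got {n}")
    mean = x.mean(axis=0)
    _, _, vt = np.linalg.svd(x - mean, full_matrices=False)
    comps = vt[:output_dim]
    for i in range(comps.shape[0]):  # deterministic sign convention
        j = int(np.argmax(np.abs(comps[i])))
        if comps[i, j] < 0:
            comps[i] = -comps[i]
    return Reducer(mean=mean, components=comps)


def user_level_embedding(
    log: EngagementLog,
    user: str,
    role: str,
    embedder: Embedder,
    reducer: Reducer,
    window: tuple[datetime, datetime] | None = None,
) -> np.ndarray:
    """Mean reduced embedding of a user's history in one role.

    ``role="authored"`` pools texts the user wrote (original posts and quote
    commentary); ``role="reshared"`` pools the content of posts the user
    reshared.  Users with no history in the role get the zero vector.
    """
    if role not in ("authored", "reshared"):
        raise ValueError(f"role must be 'authored' or 'reshared', got {role!r}")
    sub = log.in_window(window) if window is not None else log
    if role == "authored":
        texts = [r.text for r in sub.records if r.user_id == user and r.type in ("post", "quote")]
    else:
        texts = [r.text for r in sub.records if r.user_id == user and r.type in RESHARE_TYPES]
    if not texts:
        return np.zeros(reducer.output_dim)
    reduced = reducer.encode(embedder.embed_many(texts))
    return reduced.mean(axis=0)


def build_feature_vector(
    fj_stats: UserStats,
    uk_stats: UserStats,
    uk_authored_mean: np.ndarray,
    fj_reshared_mean: np.ndarray,
    tweet_text: str,
    embedder: Embedder,
    reducer96: Reducer,
) -> np.ndarray:
    """Concatenate one transmission's features in the documented, stable order.

    Layout: [f_j stats (7), u_k stats (7), u_k authored-mean (24),
    f_j reshared-mean (24), tweet embedding (96)].
    """
    tweet96 = reducer96.encode(embedder.embed(tweet_text))
    parts = [
        fj_stats.as_array(),
        uk_stats.as_array(),
        np.asarray(uk_authored_mean, dtype=float),
        np.asarray(fj_reshared_mean, dtype=float),
        np.asarray(tweet96, dtype=float),
    ]
    expect = (7, 7, 24, 24, 96)
    for p, e in zip(parts, expect):
        if p.shape != (e,):
            raise ValueError(f"feature block of length {p.shape} where {e} expected")
    return np.concatenate(parts)


FEATURE_LENGTH = 7 + 7 + 24 + 24 + 96


class FeatureStore:
    """Precomputed per-user features enabling fast batch assembly.

    Fits the two reducers (384→24 user-level, 384→96 tweet-level) on the
    pooled embeddings of every text in the window, then caches each user's
    statistics vector and role means.  ``feature_matrix`` assembles rows for
    many (follower, originator, text) triples without re-embedding users.
    """

    def __init__(
        self,
        log: EngagementLog,
        network: InfoFlowNetwork,
        embedder: Embedder | None = None,
        window: tuple[datetime, datetime] | None = None,
        profiles: dict[str, tuple[int, int]] | None = None,
        user_dim: int = 24,
        tweet_dim: int = 96,
        seed: int = 0,
    ):
        self.embedder = embedder or HashingEmbedder(seed=seed)
        self.network = network
        sub = log.in_window(window) if window is not None else log
        texts = sorted({r.text for r in sub.records if r.text})
        if len(texts) < max(user_dim, tweet_dim):
            raise ValueError(
                f"only {len(texts)} distinct texts in window; need at least "
                f"{max(user_dim, tweet_dim)} to fit the reducers"
            )
        pool = self.embedder.embed_many(texts)
        self.reducer_user = fit_reducer(pool, user_dim, seed=seed)
        self.reducer_tweet = fit_reducer(pool, tweet_dim, seed=seed)
        self.user_dim = user_dim
        self.tweet_dim = tweet_dim
        self.feature_length = 14 + 2 * user_dim + tweet_dim

        self._stats: dict[str, np.ndarray] = {}
        self._authored: dict[str, np.ndarray] = {}
        self._reshared: dict[str, np.ndarray] = {}
        for u in network.nodes:
            self._stats[u] = compute_user_stats(sub, network, u, None, profiles).as_array()
            self._authored[u] = user_level_embedding(sub, u, "authored", self.embedder, self.reducer_user)
            self._reshared[u] = user_level_embedding(sub, u, "reshared", self.embedder, self.reducer_user)
        self._tweet_cache: dict[str, np.ndarray] = {}

    def tweet_embedding(self, text: str) -> np.ndarray:
        vec = self._tweet_cache.get(text)
        if vec is None:
            vec = self.reducer_tweet.encode(self.embedder.embed(text))
            self._tweet_cache[text] = vec
        return vec

    def has_user(self, user: str) -> bool:
        return user in self._stats

    def feature_row(self, follower: str, originator: str, tweet_text: str) -> np.ndarray:
        for u in (follower, originator):
            if u not in self._stats:
                raise KeyError(f"user {u!r} has no computed features")
        return np.concatenate(
            [
                self._stats[follower],
                self._stats[originator],
                self._authored[originator],
                self._reshared[follower],
                self.tweet_embedding(tweet_text),
            ]
        )

    def feature_matrix(
        self, followers: list[str], originator: str, tweet_text: str
    ) -> np.ndarray:
        """Rows for many followers of one (originator, tweet) pair."""
        if originator not in self._stats:
            raise KeyError(f"user {originator!r} has no computed features")
        tweet = self.tweet_embedding(tweet_text)
        k_block = np.concatenate([self._stats[originator], self._authored[originator], tweet])
        ud = self.user_dim
        rows = np.empty((len(followers), self.feature_length))
        for i, f in enumerate(followers):
            if f not in self._stats:
                raise KeyError(f"user {f!r} has no computed features")
            rows[i, :7] = self._stats[f]
            rows[i, 7:14] = k_block[:7]
            rows[i, 14 : 14 + ud] = k_block[7 : 7 + ud]
            rows[i, 14 + ud : 14 + 2 * ud] = self._reshared[f]
            rows[i, 14 + 2 * ud :] = k_block[7 + ud :]
        return rows
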