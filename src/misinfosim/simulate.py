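"""Stochastic SEI cascade simulation on the information-flow network.

Users are Susceptible (never infected), Exposed (infected — they will
reshare — but not yet infective) or Infective (have reshared, exposing
their followers).  The seed author is exposed at t = 0 carrying the seed
tweet.  Event loop: repeatedly pop the exposed user with the smallest
infection time, make them infective, and give each *susceptible* follower
one Bernoulli infection attempt with probability IP = IM(follower,
Orig(T), T) — note the probability is computed against the tweet's
originator, not the immediate sharer.  Newly infected users receive an
infection time t_parent + Exponential(1) and immediately draw whether their
eventual reshare is a quote tweet (mutation: new text, originator
reassigned to them) or a verbatim retweet (tweet carried unchanged).

With mutations disabled the distribution of the final infected set is
exactly the independent-cascade model's, which gives an enumerable oracle
on small graphs.
"""

from __future__ import annotations

import heapq
import json
import logging
from dataclasses import dataclass
from pathlib import Path
from typing import Protocol

import numpy as np
import pandas as pd

from .mutation import MutationModel, NullMutationModel
from .network import InfoFlowNetwork

logger = logging.getLogger(__name__)


class TransmissionModel(Protocol):
    """Anything that can score infection probabilities for a set of followers."""

    def ip_for_followers(
        self,
        followers: list[str],
        originator: str,
        tweet_text: str,
        sharer: str | None = None,
    ) -> np.ndarray: ...


@dataclass
class ConstantIPModel:
    """IP ≡ p for every edge and tweet."""

    p: float

    def ip_for_followers(self, followers, originator, tweet_text, sharer=None):
        return np.full(len(followers), self.p)


@dataclass
class PerFollowerIPModel:
    """IP depends only on the receiving follower."""

    probs: dict[str, float]
    default: float = 0.0

    def ip_for_followers(self, followers, originator, tweet_text, sharer=None):
        return np.array([self.probs.get(f, self.default) for f in followers])


@dataclass
class EdgeIPModel:
    """IP keyed by (sharer, follower) edge — the plain independent-cascade kernel."""

    probs: dict[tuple[str, str], float]
    default: float = 0.0

    def ip_for_followers(self, followers, originator, tweet_text, sharer=None):
        return np.array([self.probs.get((sharer, f), self.default) for f in followers])


class Intervention(Protocol):
    """Per-trial multiplicative transform of users' outgoing infection probability."""

    def sample_multipliers(self, rng: np.random.Generator) -> dict[str, float]: ...


@dataclass(frozen=True)
class Tweet:
    text: str
    originator: str


@dataclass(frozen=True)
class InfectionEvent:
    """One user's infection: when, from whom, carrying which tweet."""

    user: str
    time: float
    layer: int
    parent: str | None  # None for the seed
    tweet_text: str
    originator: str
    mutated: bool


@dataclass
class TrialResult:
    """Outcome of a single cascade trial."""

    events: list[InfectionEvent]
    seed: int | None = None

    @property
    def infected(self) -> list[str]:
        return [e.user for e in self.events]

    @property
    def n_infected(self) -> int:
        return len(self.events)

    @property
    def layer_counts(self) -> np.ndarray:
        if not self.events:
            return np.zeros(0, dtype=int)
        depth = max(e.layer for e in self.events)
        counts = np.zeros(depth + 1, dtype=int)
        for e in self.events:
            counts[e.layer] += 1
        return counts

    @property
    def tree(self) -> list[tuple[str, str]]:
        return [(e.parent, e.user) for e in self.events if e.parent is not None]

    @property
    def mutation_events(self) -> list[InfectionEvent]:
        return [e for e in self.events if e.mutated]


def run_trial(
    network: InfoFlowNetwork,
    infection_model: TransmissionModel,
    mutation_model: MutationModel | None,
    seed_text: str,
    source: str,
    seed: int | np.random.SeedSequence = 0,
    max_layers: int | None = None,
    intervention: Intervention | None = None,
    debug: bool = False,
) -> TrialResult:
    """Run one cascade from ``source`` posting ``seed_text``.

    ``max_layers`` truncates transmission: users at that layer are still
    infected and counted but expose no one (the seed is layer 0, so
    ``max_layers=1`` keeps only first-layer infections).  ``intervention``
    multiplies each user's outgoing probabilities; its randomness draws from
    a stream independent of the cascade's, so common-random-number
    comparisons across intervention settings stay paired.
    """
    if source not in network:
        raise ValueError(f"source user {source!r} not in network")
    mm = mutation_model or NullMutationModel()
    ss = seed if isinstance(seed, np.random.SeedSequence) else np.random.SeedSequence(seed)
    child_main, child_int = ss.spawn(2)
    rng = np.random.default_rng(child_main)
    multipliers = (
        intervention.sample_multipliers(np.random.default_rng(child_int))
        if intervention is not None
        else {}
    )

    state: dict[str, str] = {}  # default susceptible
    tweets: dict[str, Tweet] = {source: Tweet(seed_text, source)}
    layer: dict[str, int] = {source: 0}
    times: dict[str, float] = {source: 0.0}
    parents: dict[str, str | None] = {source: None}
    mutated_flag: dict[str, bool] = {source: False}
    state[source] = "E"
    heap: list[tuple[float, str]] = [(0.0, source)]
    events: list[InfectionEvent] = []
    attempts: set[tuple[str, str]] = set()
    n_nodes = network.n_nodes

    while heap:
        t_i, u_i = heapq.heappop(heap)
        if debug:
            assert state[u_i] == "E", f"popped user {u_i} in state {state[u_i]}"
        state[u_i] = "I"
        tw = tweets[u_i]
        events.append(
            InfectionEvent(
                user=u_i,
                time=t_i,
                layer=layer[u_i],
                parent=parents[u_i],
                tweet_text=tw.text,
                originator=tw.originator,
                mutated=mutated_flag[u_i],
            )
        )
        if debug:
            n_e = sum(1 for s in state.values() if s == "E")
            n_i = sum(1 for s in state.values() if s == "I")
            assert n_e + n_i + (n_nodes - len(state)) == n_nodes, "population not conserved"

        if max_layers is not None and layer[u_i] >= max_layers:
            continue
        out_mult = multipliers.get(u_i, 1.0)
        followers = [f for f in network.followers(u_i) if state.get(f, "S") == "S"]
        if not followers:
            continue
        ips = (
            np.asarray(
                infection_model.ip_for_followers(followers, tw.originator, tw.text, sharer=u_i),
                dtype=float,
            )
            * out_mult
        )
        for f, ip in zip(followers, ips):
            if not np.isfinite(ip):
                raise ValueError(f"non-finite infection probability on edge {u_i} -> {f}")
            if debug:
                assert (u_i, f) not in attempts, f"repeated attempt on ({u_i}, {f})"
                attempts.add((u_i, f))
                assert state.get(f, "S") == "S", f"attempt on non-susceptible {f}"
            x_ip = rng.random()
            if x_ip >= ip:
                continue
            state[f] = "E"
            delta = rng.exponential(1.0)
            times[f] = t_i + delta
            layer[f] = layer[u_i] + 1
            parents[f] = u_i
            qp = mm.qm(f)
            x_qp = rng.random()
            if x_qp < qp:
                text, ok = mm.mutate_for(f, tw.text, rng)
                tweets[f] = Tweet(text, f) if ok else tw
                mutated_flag[f] = ok
            else:
                tweets[f] = tw
                mutated_flag[f] = False
            heapq.heappush(heap, (times[f], f))

    if debug:
        assert all(s == "I" for s in state.values()), "exposed users left untriggered"
        for e in events:
            if e.parent is not None:
                assert layer[e.user] == layer[e.parent] + 1
                assert times[e.user] > times[e.parent]
    seed_int = int(ss.entropy) if isinstance(ss.entropy, int) and ss.entropy < 2**63 else None
    return TrialResult(events=events, seed=seed_int)


@dataclass
class EnsembleResult:
    """Aggregate of many independent trials of one scenario."""

    trials: list[TrialResult]
    base_seed: int | None = None

    @property
    def n_trials(self) -> int:
        return len(self.trials)

    @property
    def totals(self) -> np.ndarray:
        return np.array([t.n_infected for t in self.trials])

    @property
    def mean_total(self) -> float:
        return float(self.totals.mean())

    @property
    def var_total(self) -> float:
        return float(self.totals.var(ddof=1)) if self.n_trials > 1 else 0.0

    def _layer_matrix(self) -> np.ndarray:
        depth = max((len(t.layer_counts) for t in self.trials), default=0)
        mat = np.zeros((self.n_trials, depth), dtype=int)
        for i, t in enumerate(self.trials):
            c = t.layer_counts
            mat[i, : len(c)] = c
        return mat

    @property
    def layer_median(self) -> np.ndarray:
        return np.median(self._layer_matrix(), axis=0)

    @property
    def layer_band(self) -> tuple[np.ndarray, np.ndarray]:
        """68% percentile band (16th–84th) of per-layer infection counts."""
        mat = self._layer_matrix()
        return np.percentile(mat, 16, axis=0), np.percentile(mat, 84, axis=0)

    def write_json(self, path: str | Path) -> None:
        lo, hi = self.layer_band
        with open(path, "w") as fh:
            json.dump(
                {
                    "n_trials": self.n_trials,
                    "base_seed": self.base_seed,
                    "totals": self.totals.tolist(),
                    "mean_total": self.mean_total,
                    "var_total": self.var_total,
                    "layer_median": self.layer_median.tolist(),
                    "layer_band_low": lo.tolist(),
                    "layer_band_high": hi.tolist(),
                    "trees": [t.tree for t in self.trials],
                },
                fh,
            )


def run_ensemble(
    network: InfoFlowNetwork,
    infection_model: TransmissionModel,
    mutation_model: MutationModel | None,
    seed_text: str,
    source: str,
    n_trials: int = 1000,
    base_seed: int = 0,
    max_layers: int | None = None,
    intervention: Intervention | None = None,
    debug: bool = False,
) -> EnsembleResult:
    """Independent trials with per-trial seeds fanned out from ``base_seed``."""
    if n_trials < 1:
        raise ValueError("n_trials must be >= 1")
    children = np.random.SeedSequence(base_seed).spawn(n_trials)
    trials = [
        run_trial(
            network,
            infection_model,
            mutation_model,
            seed_text,
            source,
            seed=child,
            max_layers=max_layers,
            intervention=intervention,
            debug=debug,
        )
        for child in children
    ]
    return EnsembleResult(trials=trials, base_seed=base_seed)


def infection_rate(
    result: TrialResult | EnsembleResult,
    author_follower_count: int,
    include_seed: bool = False,
) -> float:
    """Infections per author follower — a scale-free virality measure.

    The seed's own (definitional) infection is excluded by default.  A zero
    follower count makes the rate undefined; NaN is returned with a warning.
    """
    if author_follower_count <= 0:
        logger.warning("author has no followers; infection rate undefined")
        return float("nan")
    total = result.mean_total if isinstance(result, EnsembleResult) else result.n_infected
    if not include_seed:
        total = total - 1
    return total / author_follower_count


def community_infection_rates(
    result: TrialResult | EnsembleResult,
    partition,
) -> tuple[dict[int, float], pd.DataFrame]:
    """Per-community infection rates and the community-to-community matrix.

    Rates are infections divided by community size (averaged over trials for
    an ensemble).  The matrix entry (source community, infected community)
    is the fraction of total non-seed infections transmitted along that
    pathway; entries sum to 1 whenever any non-seed infection occurred.
    """
    trials = result.trials if isinstance(result, EnsembleResult) else [result]
    comm_of = partition.community_of
    sizes = partition.sizes
    comms = partition.communities
    counts = {c: 0.0 for c in comms}
    matrix = pd.DataFrame(0.0, index=comms, columns=comms)
    for trial in trials:
        for e in trial.events:
            if e.user not in comm_of:
                raise ValueError(f"infected user {e.user!r} outside the partition")
            counts[comm_of[e.user]] += 1
            if e.parent is not None:
                matrix.loc[comm_of[e.parent], comm_of[e.user]] += 1
    n = len(trials)
    rates = {c: counts[c] / (n * sizes[c]) for c in comms}
    total_edges = float(matrix.values.sum())
    if total_edges > 0:
        matrix = matrix / total_edges
    return rates, matrix
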