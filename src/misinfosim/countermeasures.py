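"""Intervention experiments layered over the cascade simulator.

All interventions are probability transforms applied at predict time, never
graph surgery: quarantine zeroes a user's outgoing infection probabilities
(account blocking — the user can still *be* infected, they just cannot
transmit), and inoculation multiplies selected community members' outgoing
probabilities by (1 − reduction), emulating media-literacy / prebunking
campaigns whose measured effect is a ≈20% reduction in passing-on
likelihood.  A static-probability baseline model (one fixed rate for every
edge and tweet) provides the reference point that topic- and user-sensitive
infection models are compared against.
"""

from __future__ import annotations

import logging
from collections import Counter
from dataclasses import dataclass, field
from datetime import datetime

import numpy as np
import pandas as pd

from .log import EngagementLog
from .mutation import MutationModel
from .network import CommunityPartition, InfoFlowNetwork
from .simulate import EnsembleResult, TransmissionModel, run_ensemble

logger = logging.getLogger(__name__)


@dataclass
class QuarantineIntervention:
    """Blocked users emit zero infections."""

    blocked: frozenset[str]

    def sample_multipliers(self, rng: np.random.Generator) -> dict[str, float]:
        return {u: 0.0 for u in self.blocked}


@dataclass
class InoculationIntervention:
    """A fraction of a community has outgoing probabilities reduced ~20%.

    Per trial, ``floor(fraction * len(members))`` members are sampled
    uniformly (resampled each trial by default — campaign-membership
    uncertainty); each receives an independent reduction drawn uniformly
    from ``reduction_range`` and their outgoing IP is multiplied by
    (1 − reduction).  Set both range endpoints equal for an exact reduction.
    """

    members: list[str]
    fraction: float
    reduction_range: tuple[float, float] = (0.18, 0.22)
    resample_per_trial: bool = True
    _fixed: dict[str, float] | None = field(default=None, repr=False)

    def __post_init__(self) -> None:
        if not 0.0 <= self.fraction <= 1.0:
            raise ValueError("fraction must lie in [0, 1]")
        lo, hi = self.reduction_range
        if not (0.0 <= lo <= hi <= 1.0):
            raise ValueError("reduction_range must be an interval in [0, 1]")

    def sample_multipliers(self, rng: np.random.Generator) -> dict[str, float]:
        k = int(np.floor(self.fraction * len(self.members)))
        if k == 0:
            return {}
        if not self.resample_per_trial and self._fixed is not None:
            return self._fixed
        chosen_idx = rng.choice(len(self.members), size=k, replace=False)
        lo, hi = self.reduction_range
        reductions = rng.uniform(lo, hi, size=k) if hi > lo else np.full(k, lo)
        out = {self.members[i]: 1.0 - r for i, r in zip(chosen_idx, reductions)}
        if not self.resample_per_trial:
            self._fixed = out
        return out


def rank_spreaders(ensemble: EnsembleResult) -> list[str]:
    """Users ordered by how many infections they caused across all trials.

    A user's score is their total number of children in the infection trees;
    descending order, ties broken by lexicographically smallest id.
    """
    if not ensemble.trials:
        raise ValueError("empty ensemble")
    caused: Counter = Counter()
    for trial in ensemble.trials:
        for parent, _child in trial.tree:
            caused[parent] += 1
    users = {u for t in ensemble.trials for u in t.infected}
    return sorted(users, key=lambda u: (-caused[u], u))


def apply_quarantine(
    network: InfoFlowNetwork,
    infection_model: TransmissionModel,
    mutation_model: MutationModel | None,
    seed_text: str,
    source: str,
    ranking: list[str],
    top_k_grid: list[int],
    n_trials: int = 1000,
    base_seed: int = 0,
    max_layers: int | None = None,
) -> pd.DataFrame:
    """Sweep the number of blocked top-ranked spreaders; common random numbers.

    Every grid point reuses ``base_seed``, so trials are paired across
    settings and the total-infection curve is directly comparable.
    """
    if max(top_k_grid, default=0) > network.n_nodes:
        raise ValueError("top_k exceeds network size")
    rows = []
    for k in sorted(top_k_grid):
        intervention = QuarantineIntervention(blocked=frozenset(ranking[:k])) if k else None
        ens = run_ensemble(
            network, infection_model, mutation_model, seed_text, source,
            n_trials=n_trials, base_seed=base_seed, max_layers=max_layers,
            intervention=intervention,
        )
        lo, hi = np.percentile(ens.totals, [16, 84])
        rows.append({"top_k": k, "mean_total": ens.mean_total, "band_low": lo, "band_high": hi})
    return pd.DataFrame(rows)


def apply_inoculation(
    network: InfoFlowNetwork,
    infection_model: TransmissionModel,
    mutation_model: MutationModel | None,
    seed_text: str,
    source: str,
    partition: CommunityPartition,
    community: int,
    fraction_grid: list[float],
    reduction_range: tuple[float, float] = (0.18, 0.22),
    n_trials: int = 1000,
    base_seed: int = 0,
    max_layers: int | None = None,
    resample_per_trial: bool = True,
) -> pd.DataFrame:
    """Sweep the inoculated fraction of one community; common random numbers."""
    if community not in partition.sizes:
        raise ValueError(f"unknown community {community}; known: {partition.communities}")
    members = partition.members(community)
    rows = []
    for frac in sorted(fraction_grid):
        intervention = (
            InoculationIntervention(
                members=members,
                fraction=frac,
                reduction_range=reduction_range,
                resample_per_trial=resample_per_trial,
            )
            if frac > 0
            else None
        )
        ens = run_ensemble(
            network, infection_model, mutation_model, seed_text, source,
            n_trials=n_trials, base_seed=base_seed, max_layers=max_layers,
            intervention=intervention,
        )
        lo, hi = np.percentile(ens.totals, [16, 84])
        rows.append({"fraction": frac, "mean_total": ens.mean_total, "band_low": lo, "band_high": hi})
    return pd.DataFrame(rows)


def most_infectious_community(
    ensemble: EnsembleResult, partition: CommunityPartition
) -> int:
    """The community whose members caused the most infections — the default
    inoculation target."""
    caused: Counter = Counter()
    for trial in ensemble.trials:
        for parent, _child in trial.tree:
            caused[partition.community_of[parent]] += 1
    if not caused:
        return partition.communities[0]
    return min(caused, key=lambda c: (-caused[c], c))


@dataclass
class StaticBaselineModel:
    """One fixed infection probability for every edge and every tweet."""

    p: float

    def ip_for_followers(self, followers, originator, tweet_text, sharer=None):
        return np.full(len(followers), self.p)


def static_baseline(
    network: InfoFlowNetwork,
    log: EngagementLog,
    window: tuple[datetime, datetime] | None = None,
) -> StaticBaselineModel:
    """Fit the baseline: average reshare rate over all exposure pairs.

    p = (reshare events on in-window posts by the author's followers)
    ÷ (posts × followers-of-author exposure pairs).
    """
    sub = log.in_window(window) if window is not None else log
    resharers: dict[str, set[str]] = {}
    for r in sub.records:
        if r.is_reshare:
            resharers.setdefault(r.parent_post_id, set()).add(r.user_id)
    exposures = 0
    reshares = 0
    for r in sub.records:
        if r.type != "post" or r.user_id not in network:
            continue
        followers = network.followers(r.user_id)
        exposures += len(followers)
        reshares += sum(1 for f in followers if f in resharers.get(r.post_id, ()))
    if exposures == 0:
        raise ValueError("no exposure pairs in window; cannot fit static baseline")
    return StaticBaselineModel(p=reshares / exposures)


def topic_sweep(
    network: InfoFlowNetwork,
    infection_model: TransmissionModel,
    mutation_model: MutationModel | None,
    seed_posts,
    n_trials: int = 1000,
    base_seed: int = 0,
    max_layers: int | None = None,
) -> pd.DataFrame:
    """Simulate one ensemble per seed post; min-max normalize mean infections.

    Returns a tidy frame (label, mean_total, normalized, degenerate).  When
    all topics produce identical means the normalization is degenerate: the
    normalized column is all zeros and the flag is set.
    """
    seed_posts = list(seed_posts)
    if len(seed_posts) < 2:
        raise ValueError("need at least 2 seed posts for a topic sweep")
    rows = []
    for i, post in enumerate(seed_posts):
        ens = run_ensemble(
            network, infection_model, mutation_model, post.text, post.author,
            n_trials=n_trials, base_seed=base_seed, max_layers=max_layers,
        )
        rows.append({"label": post.label or f"topic-{i}", "mean_total": ens.mean_total})
    df = pd.DataFrame(rows)
    lo, hi = df["mean_total"].min(), df["mean_total"].max()
    degenerate = hi == lo
    if degenerate:
        logger.warning("all topics produced identical means; normalization degenerate")
        df["normalized"] = 0.0
    else:
        df["normalized"] = (df["mean_total"] - lo) / (hi - lo)
    df["degenerate"] = degenerate
    return df
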