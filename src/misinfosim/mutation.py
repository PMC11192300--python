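"""Information mutation: quote tweets as mutated strains of a cascade.

When a user reshares, they either retweet verbatim or quote-tweet — adding
commentary (AC) that their followers see prepended to the parent tweet (PT)
as ``AC + ": " + PT``.  In the epidemic reading a quote tweet is a mutation:
the tweet's text changes and its originator is reassigned to the quoter, so
downstream infection probabilities are recomputed against the new text and
author.  Whether a given reshare mutates is a Bernoulli draw with the
user's empirical QT:RT ratio (QM); what the commentary says is delegated to
a pluggable generator (a hosted language model in production, a
deterministic nearest-neighbour mock here).
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field
from typing import Protocol, Sequence

import numpy as np

from .features import Embedder
from .log import EngagementLog, PeriodSpec

logger = logging.getLogger(__name__)

#: Minimum Period I–II quote tweets for a user's generator to have context.
MIN_QT_HISTORY = 25
#: Minimum Period III quote tweets for a user to be evaluable.
MIN_QT_EVAL = 20

AC_PT_SEPARATOR = ": "


def compute_qm(qt_count: int, rt_count: int) -> float:
    """Empirical quote-tweet probability qt / (qt + rt); 0 on empty history."""
    if qt_count < 0 or rt_count < 0:
        raise ValueError("counts must be non-negative")
    total = qt_count + rt_count
    return qt_count / total if total else 0.0


@dataclass
class MutationProfile:
    """A user's reshare-style history.

    ``qt_history`` holds (parent text, added commentary) pairs from the
    training periods; ``eligible`` marks users with enough quote history for
    commentary generation *and* evaluation (≥25 training QTs, ≥20 evaluation
    QTs).  The QT/RT draw in simulation uses QM regardless of eligibility —
    the threshold gates text modeling, not the branching probability.
    """

    user: str
    qt_count: int
    rt_count: int
    qt_history: list[tuple[str, str]] = field(default_factory=list)
    eval_qt_count: int = 0

    @property
    def qm(self) -> float:
        return compute_qm(self.qt_count, self.rt_count)

    @property
    def eligible(self) -> bool:
        return self.qt_count >= MIN_QT_HISTORY and self.eval_qt_count >= MIN_QT_EVAL


def split_quote_text(text: str) -> tuple[str, str]:
    """Split an aggregated quote post into (commentary, parent text)."""
    if AC_PT_SEPARATOR in text:
        ac, pt = text.split(AC_PT_SEPARATOR, 1)
        return ac, pt
    return "", text


def build_mutation_profiles(
    log: EngagementLog, periods: PeriodSpec | None = None
) -> dict[str, MutationProfile]:
    """Count QT/RT behavior per user over the training periods.

    Training (Periods I–II) reshares populate counts and quote history;
    Period III quote counts feed the evaluation-eligibility threshold.
    """
    periods = periods or PeriodSpec.default()
    train = log.in_window(periods.training_window)
    evaluation = log.in_window(periods.period_iii)
    profiles: dict[str, MutationProfile] = {}

    def _profile(u: str) -> MutationProfile:
        if u not in profiles:
            profiles[u] = MutationProfile(user=u, qt_count=0, rt_count=0)
        return profiles[u]

    for r in train.records:
        if not r.is_reshare:
            continue
        p = _profile(r.user_id)
        if r.type == "quote":
            p.qt_count += 1
            parent = train.get(r.parent_post_id)
            ac, pt = split_quote_text(r.text)
            p.qt_history.append((parent.text if parent else pt, ac))
        else:
            p.rt_count += 1
    for r in evaluation.records:
        if r.type == "quote":
            _profile(r.user_id).eval_qt_count += 1
    return profiles


class CommentaryGenerator(Protocol):
    """Produces added commentary for a parent tweet, given user history."""

    def generate(self, history: Sequence[tuple[str, str]], parent_text: str) -> str: ...


@dataclass
class FixedCommentaryGenerator:
    """Always returns the same commentary — the simplest deterministic mock."""

    commentary: str = "mock commentary"

    def generate(self, history: Sequence[tuple[str, str]], parent_text: str) -> str:
        return self.commentary


class NearestNeighbourGenerator:
    """Retrieval mock: reuse the commentary of the most similar historical PT.

    Stands in for a few-shot-prompted language model; similarity is cosine in
    the embedder's space, ties broken by history order.
    """

    def __init__(self, embedder: Embedder):
        self.embedder = embedder

    def generate(self, history: Sequence[tuple[str, str]], parent_text: str) -> str:
        if not history:
            return ""
        target = self.embedder.embed(parent_text)
        best_ac, best_sim = "", -np.inf
        for pt, ac in history:
            v = self.embedder.embed(pt)
            denom = np.linalg.norm(target) * np.linalg.norm(v)
            sim = float(target @ v / denom) if denom > 0 else -np.inf
            if sim > best_sim:
                best_ac, best_sim = ac, sim
        return best_ac


def mutate(
    generator: CommentaryGenerator,
    profile: MutationProfile,
    parent_text: str,
    rng: np.random.Generator | None = None,
    context_size: int = 10,
) -> tuple[str, bool]:
    """Produce the aggregated mutated post ``AC + ": " + PT``.

    Returns ``(text, mutated)``.  Empty commentary or a generator failure
    falls back to the un-mutated parent text with ``mutated=False``.
    """
    history = profile.qt_history
    if rng is not None and len(history) > context_size:
        idx = sorted(rng.choice(len(history), size=context_size, replace=False))
        history = [history[i] for i in idx]
    try:
        ac = generator.generate(history, parent_text)
    except Exception:  # generator is third-party territory; degrade to a retweet
        logger.warning("commentary generator failed for %s; falling back to retweet", profile.user)
        return parent_text, False
    if not ac:
        return parent_text, False
    return f"{ac}{AC_PT_SEPARATOR}{parent_text}", True


def evaluate_commentary(
    predicted: Sequence[str], truth: Sequence[str], embedder: Embedder
) -> float:
    """Mean embedding cosine similarity between predicted and true commentary."""
    if len(predicted) != len(truth):
        raise ValueError("predicted and truth must be paired lists of equal length")
    sims: list[float] = []
    for p, t in zip(predicted, truth):
        vp, vt = embedder.embed(p), embedder.embed(t)
        denom = np.linalg.norm(vp) * np.linalg.norm(vt)
        if denom == 0:
            logger.warning("zero-norm embedding; pair skipped")
            continue
        sims.append(float(vp @ vt / denom))
    return float(np.mean(sims)) if sims else float("nan")


class MutationModel:
    """Per-user QM draw plus commentary generation, as used by the simulator."""

    def __init__(
        self,
        profiles: dict[str, MutationProfile],
        generator: CommentaryGenerator | None = None,
        context_size: int = 10,
    ):
        self.profiles = profiles
        self.generator = generator or FixedCommentaryGenerator()
        self.context_size = context_size

    def qm(self, user: str) -> float:
        p = self.profiles.get(user)
        return p.qm if p is not None else 0.0

    def mutate_for(
        self, user: str, parent_text: str, rng: np.random.Generator
    ) -> tuple[str, bool]:
        p = self.profiles.get(user) or MutationProfile(user=user, qt_count=0, rt_count=0)
        return mutate(self.generator, p, parent_text, rng, self.context_size)


class NullMutationModel(MutationModel):
    """Mutation-free dynamics: QM ≡ 0, every reshare is a verbatim retweet."""

    def __init__(self) -> None:
        super().__init__(profiles={})

    def qm(self, user: str) -> float:
        return 0.0


class AlwaysMutationModel(MutationModel):
    """QM ≡ 1 with a fixed-commentary generator; used to probe bookkeeping."""

    def __init__(self, commentary: str = "mut") -> None:
        super().__init__(profiles={}, generator=FixedCommentaryGenerator(commentary))

    def qm(self, user: str) -> float:
        return 1.0
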