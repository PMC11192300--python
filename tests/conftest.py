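"""Shared fixtures: hand-built toy logs and seeded synthetic worlds."""

from datetime import datetime, timedelta, timezone

import pytest

import misinfosim as m

UTC = timezone.utc
T0 = datetime(2021, 2, 10, tzinfo=UTC)


def rec(post_id, user, type="post", parent=None, originator=None, minutes=0, text="hello world"):
    return m.EngagementRecord(
        post_id=post_id,
        parent_post_id=parent,
        user_id=user,
        originator_id=originator or user,
        type=type,
        timestamp=T0 + timedelta(minutes=minutes),
        text=text,
    )


@pytest.fixture
def toy_log():
    """12 records among 4 users; every downstream hand tally refers to this.

    a authors p1, p2, p3; b authors p4; c authors p5.
    Reshares: b RT p1, b QT p2, c RT p1, c RT p4, d RT p4, a RT p5, b RT p3.
    """
    return m.EngagementLog(
        [
            rec("p1", "a", minutes=0, text="alpha beta"),
            rec("p2", "a", minutes=1, text="alpha gamma"),
            rec("p3", "a", minutes=2, text="beta delta"),
            rec("p4", "b", minutes=3, text="omega omega"),
            rec("p5", "c", minutes=4, text="sigma"),
            rec("r1", "b", "retweet", parent="p1", originator="a", minutes=5, text="alpha beta"),
            rec("r2", "b", "quote", parent="p2", originator="a", minutes=6, text="my take: alpha gamma"),
            rec("r3", "c", "retweet", parent="p1", originator="a", minutes=7, text="alpha beta"),
            rec("r4", "c", "retweet", parent="p4", originator="b", minutes=8, text="omega omega"),
            rec("r5", "d", "retweet", parent="p4", originator="b", minutes=9, text="omega omega"),
            rec("r6", "a", "retweet", parent="p5", originator="c", minutes=10, text="sigma"),
            rec("r7", "b", "retweet", parent="p3", originator="a", minutes=11, text="beta delta"),
        ]
    )


@pytest.fixture
def toy_network(toy_log):
    return m.infer_edges(toy_log)


@pytest.fixture(scope="session")
def small_world():
    cfg = m.SyntheticConfig(n_users=80, n_communities=3, posts_per_user=15.0, seed=42)
    return m.generate_world(cfg)


@pytest.fixture(scope="session")
def small_log(small_world):
    return m.generate_engagement_log(
        small_world, m.PeriodSpec.default().training_window, seed=43
    )


@pytest.fixture(scope="session")
def small_network(small_log):
    return m.infer_edges(small_log)


def chain_network(n=3):
    """n0 -> n1 -> ... -> n_{k-1}, unit weights."""
    nodes = [f"n{i}" for i in range(n)]
    weights = {(nodes[i], nodes[i + 1]): 1 for i in range(n - 1)}
    return m.InfoFlowNetwork(nodes=nodes, weights=weights), nodes


def star_network(n_followers=100):
    nodes = ["hub"] + [f"f{i:03d}" for i in range(n_followers)]
    weights = {("hub", f): 1 for f in nodes[1:]}
    return m.InfoFlowNetwork(nodes=nodes, weights=weights)
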