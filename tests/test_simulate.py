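"""SEI cascade dynamics: forced paths, exact oracles, ensemble statistics."""

import itertools

import numpy as np
import pytest
from scipy.stats import chisquare

import misinfosim as m

from conftest import chain_network, star_network


def ic_exact_distribution(nodes, edge_probs, source):
    """Exact independent-cascade outcome distribution by edge enumeration."""
    edges = sorted(edge_probs)
    dist: dict[frozenset, float] = {}
    for outcome in itertools.product([0, 1], repeat=len(edges)):
        prob = 1.0
        open_edges = set()
        for e, o in zip(edges, outcome):
            p = edge_probs[e]
            prob *= p if o else (1 - p)
            if o:
                open_edges.add(e)
        if prob == 0.0:
            continue
        reached = {source}
        frontier = [source]
        while frontier:
            u = frontier.pop()
            for (a, b) in open_edges:
                if a == u and b not in reached:
                    reached.add(b)
                    frontier.append(b)
        key = frozenset(reached)
        dist[key] = dist.get(key, 0.0) + prob
    return dist


@pytest.fixture
def six_node():
    nodes = ["s", "a", "b", "c", "d", "e"]
    probs = {
        ("s", "a"): 0.7, ("s", "b"): 0.4, ("a", "c"): 0.5, ("b", "c"): 0.3,
        ("c", "d"): 0.6, ("b", "e"): 0.5, ("d", "e"): 0.2, ("a", "b"): 0.25,
    }
    net = m.InfoFlowNetwork(nodes=nodes, weights={e: 1 for e in probs})
    return net, probs


class TestRunTrial:
    def test_isolated_seed_infects_only_itself(self):
        net = m.InfoFlowNetwork(nodes=["s", "x"], weights={("x", "s"): 1})
        trial = m.run_trial(net, m.ConstantIPModel(1.0), None, "t", "s", seed=0)
        assert trial.infected == ["s"]
        assert trial.layer_counts.tolist() == [1]

    def test_chain_with_certain_infection(self):
        net, nodes = chain_network(3)
        trial = m.run_trial(net, m.ConstantIPModel(1.0), m.NullMutationModel(), "t", nodes[0], seed=1)
        assert trial.infected == nodes
        assert [e.layer for e in trial.events] == [0, 1, 2]
        assert all(e.originator == nodes[0] for e in trial.events)
        times = [e.time for e in trial.events]
        assert times[0] == 0.0 and times[1] > 0 and times[2] > times[1]

    def test_unknown_source_rejected(self):
        net, nodes = chain_network(3)
        with pytest.raises(ValueError, match="ghost"):
            m.run_trial(net, m.ConstantIPModel(1.0), None, "t", "ghost", seed=0)

    def test_non_finite_probability_names_edge(self):
        net, nodes = chain_network(2)

        class BadModel:
            def ip_for_followers(self, followers, originator, tweet_text, sharer=None):
                return np.full(len(followers), np.nan)

        with pytest.raises(ValueError, match="n0 -> n1"):
            m.run_trial(net, BadModel(), None, "t", "n0", seed=0)

    def test_max_layers_truncates_transmission(self):
        net, nodes = chain_network(5)
        trial = m.run_trial(
            net, m.ConstantIPModel(1.0), None, "t", nodes[0], seed=0, max_layers=1
        )
        assert trial.n_infected == 2  # seed + first layer only

    def test_debug_mode_invariants_hold(self, small_network):
        src = max(small_network.nodes, key=small_network.follower_count)
        for s in range(20):
            trial = m.run_trial(
                small_network, m.ConstantIPModel(0.5), None, "t", src, seed=s, debug=True
            )
            users = trial.infected
            assert len(set(users)) == len(users)  # infected at most once
            by_user = {e.user: e for e in trial.events}
            for e in trial.events:
                if e.parent is not None:
                    assert e.layer == by_user[e.parent].layer + 1
                    assert e.time > by_user[e.parent].time


class TestIndependentCascadeEquivalence:
    def test_final_set_distribution_matches_exact_enumeration(self, six_node):
        """χ² goodness-of-fit of simulated outcome sets vs edge enumeration."""
        net, probs = six_node
        exact = ic_exact_distribution(net.nodes, probs, "s")
        model = m.EdgeIPModel(probs)
        n_trials = 5000
        counts: dict[frozenset, int] = {}
        ens = m.run_ensemble(net, model, m.NullMutationModel(), "t", "s",
                             n_trials=n_trials, base_seed=7)
        for trial in ens.trials:
            key = frozenset(trial.infected)
            counts[key] = counts.get(key, 0) + 1
        # merge rare outcomes so every expected count is >= 5
        keys = sorted(exact, key=lambda k: -exact[k])
        obs, exp = [], []
        rare_o = rare_e = 0.0
        for k in keys:
            e = exact[k] * n_trials
            o = counts.pop(k, 0)
            if e < 5:
                rare_e += e
                rare_o += o
            else:
                obs.append(o)
                exp.append(e)
        rare_o += sum(counts.values())  # simulated sets absent from the oracle
        if rare_e > 0:
            obs.append(rare_o)
            exp.append(rare_e)
        else:
            assert rare_o == 0
        assert abs(sum(exp) - sum(obs)) < 1e-6
        stat = chisquare(obs, exp)
        assert stat.pvalue > 0.001

    def test_mean_total_matches_exact_expectation(self, six_node):
        net, probs = six_node
        exact = ic_exact_distribution(net.nodes, probs, "s")
        expected_mean = sum(len(k) * p for k, p in exact.items())
        ens = m.run_ensemble(net, m.EdgeIPModel(probs), None, "t", "s",
                             n_trials=4000, base_seed=3)
        se = ens.totals.std(ddof=1) / np.sqrt(ens.n_trials)
        assert abs(ens.mean_total - expected_mean) < 3 * se


class TestTimingLaw:
    def test_layer_k_mean_time_is_k(self):
        """Infection times along a certain chain are sums of Exponential(1)."""
        net, nodes = chain_network(6)
        sums = np.zeros(6)
        n_trials = 2000
        for t in m.run_ensemble(net, m.ConstantIPModel(1.0), None, "t", nodes[0],
                                n_trials=n_trials, base_seed=11).trials:
            for e in t.events:
                sums[e.layer] += e.time
        means = sums / n_trials
        for k in range(1, 6):
            assert abs(means[k] - k) / k < 0.05


class TestEnsemble:
    def test_certain_infection_has_zero_width_bands(self):
        net = star_network(20)
        ens = m.run_ensemble(net, m.ConstantIPModel(1.0), None, "t", "hub",
                             n_trials=50, base_seed=0)
        lo, hi = ens.layer_band
        assert np.array_equal(lo, hi)
        assert ens.var_total == 0.0

    def test_zero_probability_gives_single_infection(self):
        net = star_network(20)
        ens = m.run_ensemble(net, m.ConstantIPModel(0.0), None, "t", "hub",
                             n_trials=50, base_seed=0)
        assert np.all(ens.totals == 1)

    def test_same_base_seed_reproduces_ensemble(self):
        net = star_network(30)
        kw = dict(n_trials=40, base_seed=9)
        e1 = m.run_ensemble(net, m.ConstantIPModel(0.3), None, "t", "hub", **kw)
        e2 = m.run_ensemble(net, m.ConstantIPModel(0.3), None, "t", "hub", **kw)
        assert [t.events for t in e1.trials] == [t.events for t in e2.trials]

    def test_star_layer_one_closed_form(self):
        n, p, n_trials = 50, 0.2, 2000
        net = star_network(n)
        ens = m.run_ensemble(net, m.ConstantIPModel(p), None, "t", "hub",
                             n_trials=n_trials, base_seed=4)
        layer1 = ens.totals - 1
        se = np.sqrt(n * p * (1 - p) / n_trials)
        assert abs(layer1.mean() - n * p) < 3 * se

    def test_invalid_trial_count(self):
        net = star_network(5)
        with pytest.raises(ValueError):
            m.run_ensemble(net, m.ConstantIPModel(0.1), None, "t", "hub", n_trials=0)

    def test_write_json(self, tmp_path):
        net = star_network(10)
        ens = m.run_ensemble(net, m.ConstantIPModel(0.5), None, "t", "hub",
                             n_trials=20, base_seed=0)
        path = tmp_path / "ens.json"
        ens.write_json(path)
        import json

        data = json.loads(path.read_text())
        assert data["n_trials"] == 20 and len(data["totals"]) == 20


class TestRates:
    def test_infection_rate_arithmetic(self):
        events = [
            m.InfectionEvent("s", 0.0, 0, None, "t", "s", False),
        ] + [
            m.InfectionEvent(f"u{i}", 1.0 + i, 1, "s", "t", "s", False) for i in range(10)
        ]
        trial = m.TrialResult(events=events)
        assert m.infection_rate(trial, 100) == pytest.approx(0.10)

    def test_zero_non_seed_infections(self):
        trial = m.TrialResult(events=[m.InfectionEvent("s", 0.0, 0, None, "t", "s", False)])
        assert m.infection_rate(trial, 50) == 0.0

    def test_zero_followers_is_nan(self):
        trial = m.TrialResult(events=[m.InfectionEvent("s", 0.0, 0, None, "t", "s", False)])
        assert np.isnan(m.infection_rate(trial, 0))

    def test_ensemble_mean_rate_matches_hand_computation(self):
        net = star_network(10)
        ens = m.run_ensemble(net, m.ConstantIPModel(0.5), None, "t", "hub",
                             n_trials=100, base_seed=2)
        hand = (ens.totals - 1).mean() / 10
        assert m.infection_rate(ens, 10) == pytest.approx(hand)


class TestCommunityRates:
    @pytest.fixture
    def toy_trial(self):
        # tree: s(c0) -> a(c0), s -> b(c1), b -> c(c1)
        events = [
            m.InfectionEvent("s", 0.0, 0, None, "t", "s", False),
            m.InfectionEvent("a", 0.5, 1, "s", "t", "s", False),
            m.InfectionEvent("b", 0.7, 1, "s", "t", "s", False),
            m.InfectionEvent("c", 1.2, 2, "b", "t", "s", False),
        ]
        part = m.CommunityPartition(
            community_of={"s": 0, "a": 0, "b": 1, "c": 1, "d": 1, "x": 0}
        )
        return m.TrialResult(events=events), part

    def test_rates_and_matrix_match_hand_tally(self, toy_trial):
        trial, part = toy_trial
        rates, matrix = m.community_infection_rates(trial, part)
        # community 0 = {s, a, x} (3 members, 2 infected); community 1 = {b,c,d}
        assert rates[0] == pytest.approx(2 / 3)
        assert rates[1] == pytest.approx(2 / 3)
        # edges: s->a (0->0), s->b (0->1), b->c (1->1): each 1/3 of infections
        assert matrix.loc[0, 0] == pytest.approx(1 / 3)
        assert matrix.loc[0, 1] == pytest.approx(1 / 3)
        assert matrix.loc[1, 1] == pytest.approx(1 / 3)
        assert matrix.values.sum() == pytest.approx(1.0)

    def test_concentrated_infections(self):
        part = m.CommunityPartition(
            community_of={f"u{i}": 0 for i in range(50)} | {f"v{i}": 1 for i in range(10)}
        )
        events = [m.InfectionEvent("u0", 0.0, 0, None, "t", "u0", False)] + [
            m.InfectionEvent(f"u{i}", float(i), 1, "u0", "t", "u0", False) for i in range(1, 5)
        ]
        rates, _ = m.community_infection_rates(m.TrialResult(events=events), part)
        assert rates[0] == pytest.approx(5 / 50)
        assert rates[1] == 0.0

    def test_user_outside_partition_rejected(self, toy_trial):
        trial, _ = toy_trial
        part = m.CommunityPartition(community_of={"s": 0})
        with pytest.raises(ValueError, match="outside"):
            m.community_infection_rates(trial, part)


class TestMutationBookkeeping:
    def test_always_mutate_reassigns_originator_and_text(self):
        net, nodes = chain_network(3)
        trial = m.run_trial(
            net, m.ConstantIPModel(1.0), m.AlwaysMutationModel("mut"), "seed text",
            nodes[0], seed=5,
        )
        events = {e.user: e for e in trial.events}
        assert events[nodes[1]].originator == nodes[1]
        assert events[nodes[1]].tweet_text == "mut: seed text"
        assert events[nodes[2]].originator == nodes[2]
        assert events[nodes[2]].tweet_text == "mut: mut: seed text"

    def test_qm_zero_equals_mutation_free_run(self):
        net = star_network(30)
        profiles = {f"f{i:03d}": m.MutationProfile(f"f{i:03d}", 0, 5) for i in range(30)}
        with_profiles = m.MutationModel(profiles)
        e1 = m.run_ensemble(net, m.ConstantIPModel(0.4), with_profiles, "t", "hub",
                            n_trials=30, base_seed=1)
        e2 = m.run_ensemble(net, m.ConstantIPModel(0.4), m.NullMutationModel(), "t", "hub",
                            n_trials=30, base_seed=1)
        assert [t.events for t in e1.trials] == [t.events for t in e2.trials]
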