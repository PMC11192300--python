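"""Exposure labeling, classifier training, calibration, α scaling, AUC."""

import numpy as np
import pandas as pd
import pytest

import misinfosim as m
from misinfosim.infection import ExposureDataset

from conftest import rec


def brute_force_auc(scores, labels):
    """Pairwise-comparison definition of AUC: P(score_pos > score_neg) + ½ ties."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    wins = ties = 0
    for p in pos:
        wins += np.sum(p > neg)
        ties += np.sum(p == neg)
    return (wins + 0.5 * ties) / (len(pos) * len(neg))


def synthetic_dataset(n, signal, seed=0, width=5):
    """Feature-label dataset with tunable signal-to-noise in feature 0."""
    rng = np.random.default_rng(seed)
    X = rng.standard_normal((n, width))
    logits = signal * X[:, 0]
    y = (rng.random(n) < 1 / (1 + np.exp(-logits))).astype(np.int8)
    prov = pd.DataFrame({"post_id": "p", "follower_id": "f", "originator_id": "o"}, index=range(n))
    return ExposureDataset(X=X, y=y, provenance=prov)


class TestExposureDataset:
    def test_printed_counts_give_037_percent(self):
        summary = m.ExposureSummary(n_rows=35_330_188, n_positives=130_432)
        assert summary.positive_rate_percent == 0.37

    def test_three_followers_two_posts_one_reshare(self):
        log = m.EngagementLog(
            [rec("p1", "a", text=f"w{i} unique text" if i else "base text") for i in [0]]
            + [
                rec("p2", "a", minutes=1, text="second post"),
                rec("r1", "b", "retweet", parent="p1", originator="a", minutes=2, text="base text"),
            ]
            + [rec(f"x{i}", "z", minutes=10 + i, text=f"filler text {i}") for i in range(6)]
        )
        net = m.InfoFlowNetwork(
            nodes=["a", "b", "c", "d", "z"],
            weights={("a", "b"): 1, ("a", "c"): 1, ("a", "d"): 1},
        )
        store = m.FeatureStore(log, net, user_dim=2, tweet_dim=3)
        ds = m.build_exposure_dataset(log, net, store)
        assert len(ds) == 6  # 2 posts x 3 followers
        assert ds.summary.n_positives == 1

    def test_rows_match_brute_force_double_loop(self, small_log, small_network):
        store = m.FeatureStore(small_log, small_network, seed=0)
        ds = m.build_exposure_dataset(small_log, small_network, store)
        reshared = {
            (r.parent_post_id, r.user_id) for r in small_log.records if r.is_reshare
        }
        expected = []
        for r in small_log.records:
            if r.type != "post":
                continue
            for f in small_network.followers(r.user_id):
                expected.append((r.post_id, f, r.user_id, (r.post_id, f) in reshared))
        got = [
            (p, f, o, bool(y))
            for (p, f, o), y in zip(ds.provenance.itertuples(index=False), ds.y)
        ]
        assert got == expected

    def test_empty_window_rejected(self, small_log, small_network):
        store = m.FeatureStore(small_log, small_network, seed=0)
        empty = m.EngagementLog([])
        with pytest.raises(ValueError, match="empty"):
            m.build_exposure_dataset(empty, small_network, store)

    def test_downsampling_keeps_all_positives(self):
        ds = synthetic_dataset(5000, signal=1.0)
        small, kappa = m.downsample_negatives(ds, 0.1, seed=0)
        assert small.summary.n_positives == ds.summary.n_positives
        assert kappa == 0.1
        assert len(small) < len(ds)


class TestTrainClassifier:
    def test_separable_data_high_auc(self):
        ds = synthetic_dataset(4000, signal=8.0)
        trained = m.train_classifier(ds, seed=0)
        raw = trained.raw_scores(ds.X[trained.test_idx])
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(ds.y[trained.test_idx], raw) >= 0.95

    def test_no_signal_gives_half_auc(self):
        ds = synthetic_dataset(20_000, signal=0.0)
        trained = m.train_classifier(ds, seed=0)
        raw = trained.raw_scores(ds.X[trained.test_idx])
        from sklearn.metrics import roc_auc_score

        assert roc_auc_score(ds.y[trained.test_idx], raw) == pytest.approx(0.5, abs=0.05)

    def test_split_is_twenty_eighty(self):
        ds = synthetic_dataset(1000, signal=1.0)
        trained = m.train_classifier(ds, seed=0)
        assert len(trained.train_idx) == 200
        assert len(trained.test_idx) == 800
        assert not set(trained.train_idx) & set(trained.test_idx)

    def test_deterministic(self):
        ds = synthetic_dataset(2000, signal=2.0)
        t1 = m.train_classifier(ds, seed=5)
        t2 = m.train_classifier(ds, seed=5)
        assert np.array_equal(t1.raw_scores(ds.X), t2.raw_scores(ds.X))

    def test_single_class_training_rejected(self):
        ds = synthetic_dataset(100, signal=0.0)
        ds.y[:] = 0
        with pytest.raises(ValueError, match="single class"):
            m.train_classifier(ds, seed=0)

    def test_random_search_runs(self):
        ds = synthetic_dataset(3000, signal=3.0)
        trained = m.train_classifier(ds, seed=0, search_budget=2)
        assert trained.raw_scores(ds.X[:5]).shape == (5,)


class TestCalibration:
    def test_identity_scores_recovered(self):
        rng = np.random.default_rng(0)
        s = rng.uniform(0, 1, 100_000)
        y = rng.uniform(0, 1, 100_000) < s
        curve = m.fit_calibration(s, y)
        grid = np.linspace(0.01, 0.99, 99)
        assert np.max(np.abs(curve.calibrate(grid) - grid)) < 0.02

    def test_all_negative_labels_give_zero(self):
        rng = np.random.default_rng(1)
        s = rng.uniform(0, 1, 5000)
        curve = m.fit_calibration(s, np.zeros(5000, dtype=int))
        assert curve.calibrate(np.linspace(0, 1, 50)).max() == 0.0

    def test_polynomial_is_monotone_nondecreasing(self):
        rng = np.random.default_rng(2)
        s = rng.uniform(0, 1, 20_000)
        y = rng.uniform(0, 1, 20_000) < s**2
        curve = m.fit_calibration(s, y)
        assert np.all(curve.coefficients >= 0)
        grid = curve.calibrate(np.linspace(0, 1, 500))
        assert np.all(np.diff(grid) >= -1e-12)

    def test_bin_rate_recovered_at_bin_centers(self):
        rng = np.random.default_rng(3)
        s = rng.uniform(0, 1, 50_000)
        y = rng.uniform(0, 1, 50_000) < s
        curve = m.fit_calibration(s, y)
        mids = (np.arange(100) + 0.5) / 100
        poly_at_centers = np.polynomial.polynomial.polyval(mids, curve.coefficients)
        assert np.mean(np.abs(poly_at_centers - curve.bin_rates)) < 0.02

    def test_few_observations_reduce_bins(self):
        rng = np.random.default_rng(4)
        s = rng.uniform(0, 1, 60)
        y = (rng.random(60) < s).astype(int)
        curve = m.fit_calibration(s, y, n_quantiles=100)
        assert curve.n_quantiles == 30

    def test_downsampling_prior_correction(self):
        """Rates estimated after negative downsampling match full-data truth."""
        rng = np.random.default_rng(5)
        s = rng.uniform(0, 1, 200_000) * 0.3  # rare-event regime
        y = (rng.random(200_000) < s).astype(int)
        keep = (y == 1) | (rng.random(200_000) < 0.25)
        curve = m.fit_calibration(s[keep], y[keep], neg_keep_fraction=0.25)
        grid = np.linspace(0.02, 0.28, 27)
        assert np.mean(np.abs(curve.calibrate(grid) - grid)) < 0.02

    def test_json_round_trip(self, tmp_path):
        rng = np.random.default_rng(6)
        s = rng.uniform(0, 1, 2000)
        y = (rng.random(2000) < s).astype(int)
        curve = m.fit_calibration(s, y)
        path = tmp_path / "cal.json"
        curve.to_json(path)
        back = m.CalibrationCurve.from_json(path)
        grid = np.linspace(0, 1, 100)
        assert np.array_equal(back.calibrate(grid), curve.calibrate(grid))


@pytest.fixture(scope="module")
def small_model(small_log, small_network):
    store = m.FeatureStore(small_log, small_network, seed=0)
    model, ds = m.train_infection_model(small_log, small_network, store, seed=0)
    return model, ds


class TestInfectionModel:
    def test_alpha_zero_means_no_infection(self, small_model):
        model, _ = small_model
        u, v = model.store.network.nodes[:2]
        zero = m.InfectionModel(model.store, model.classifier, model.calibration, alpha=0.0)
        assert zero.predict_ip(v, u, "t00p") == 0.0

    def test_alpha_three_triples_unless_clipped(self, small_model):
        model, ds = small_model
        p, f, o = ds.provenance.iloc[0]
        tweet = "t00p t01n t02p"
        one = m.InfectionModel(model.store, model.classifier, model.calibration, alpha=1.0)
        three = m.InfectionModel(model.store, model.classifier, model.calibration, alpha=3.0)
        ip1, ip3 = one.predict_ip(f, o, tweet), three.predict_ip(f, o, tweet)
        assert ip3 == pytest.approx(min(3 * ip1, 1.0))

    def test_prediction_in_unit_interval(self, small_model):
        model, ds = small_model
        sample = ds.provenance.sample(50, random_state=0)
        for p, f, o in sample.itertuples(index=False):
            ip = model.predict_ip(f, o, "t03p t01p")
            assert 0.0 <= ip <= 1.0

    def test_unknown_user_named(self, small_model):
        model, _ = small_model
        with pytest.raises(KeyError, match="nobody"):
            model.predict_ip("nobody", model.store.network.nodes[0], "x")

    def test_save_load_round_trip(self, small_model, tmp_path):
        model, ds = small_model
        model.save(tmp_path / "model")
        back = m.InfectionModel.load(tmp_path / "model", model.store)
        idx = ds.provenance.sample(20, random_state=1)
        for p, f, o in idx.itertuples(index=False):
            assert back.predict_ip(f, o, "t00p") == model.predict_ip(f, o, "t00p")


class TestAucOverTime:
    def test_perfect_classifier_scores_one(self):
        ds = synthetic_dataset(500, signal=50.0, seed=1)
        trained = m.train_classifier(ds, seed=0)
        # near-deterministic labels: AUC on the training slice itself
        aucs = m.evaluate_auc_over_time(trained, [ds])
        assert aucs[0] > 0.97

    def test_shuffled_labels_score_half(self):
        ds = synthetic_dataset(8000, signal=3.0, seed=2)
        trained = m.train_classifier(ds, seed=0)
        rng = np.random.default_rng(0)
        shuffled = ExposureDataset(X=ds.X, y=rng.permutation(ds.y), provenance=ds.provenance)
        aucs = m.evaluate_auc_over_time(trained, [shuffled])
        assert aucs[0] == pytest.approx(0.5, abs=0.05)

    def test_matches_pairwise_oracle_on_small_slices(self):
        ds = synthetic_dataset(2000, signal=2.0, seed=3)
        trained = m.train_classifier(ds, seed=0)
        slices = [
            ExposureDataset(ds.X[i : i + 400], ds.y[i : i + 400], ds.provenance.iloc[i : i + 400])
            for i in (0, 400, 800)
        ]
        aucs = m.evaluate_auc_over_time(trained, slices)
        for sl, auc in zip(slices, aucs):
            oracle = brute_force_auc(trained.raw_scores(sl.X), sl.y)
            assert auc == pytest.approx(oracle, abs=1e-12)

    def test_single_class_slice_is_nan(self):
        ds = synthetic_dataset(1000, signal=1.0, seed=4)
        trained = m.train_classifier(ds, seed=0)
        allneg = ExposureDataset(ds.X[:50], np.zeros(50, dtype=np.int8), ds.provenance.iloc[:50])
        aucs = m.evaluate_auc_over_time(trained, [allneg, ds])
        assert np.isnan(aucs[0]) and not np.isnan(aucs[1])
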