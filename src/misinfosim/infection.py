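"""Infection model: exposure labeling, boosted-tree training, calibration.

The model estimates IP = IM(f_j, u_k, T_i): the probability that follower
f_j reshares tweet T_i originated by u_k.  Training data assumes every
follower is exposed to every post of the accounts they follow, so each
(post, follower-of-author) pair contributes one row, labeled positive only
when that follower actually reshared that post.  Reshares are rare, so the
raw classifier scores are recalibrated to empirical probabilities via
quantile binning smoothed by a monotone polynomial, and finally scaled by a
global factor α that compensates for simulating a subnetwork rather than
the full platform.
"""

from __future__ import annotations

import json
import logging
import pickle
from dataclasses import dataclass
from datetime import datetime
from pathlib import Path

import numpy as np
import pandas as pd
from scipy.optimize import nnls
from sklearn.ensemble import HistGradientBoostingClassifier
from sklearn.metrics import roc_auc_score

from .features import FeatureStore
from .log import EngagementLog
from .network import InfoFlowNetwork

logger = logging.getLogger(__name__)


@dataclass(frozen=True)
class ExposureSummary:
    """Row/positive counts of an exposure-labeled dataset."""

    n_rows: int
    n_positives: int

    @property
    def positive_rate(self) -> float:
        return self.n_positives / self.n_rows if self.n_rows else 0.0

    @property
    def positive_rate_percent(self) -> float:
        """Positive rate as a percentage rounded to two decimals."""
        return round(100.0 * self.positive_rate, 2)

    def __str__(self) -> str:
        return (
            f"{self.n_rows} exposures, {self.n_positives} reshares "
            f"({self.positive_rate_percent}% positive rate)"
        )


@dataclass
class ExposureDataset:
    """Feature rows with reshare labels and (post, follower, originator) provenance."""

    X: np.ndarray
    y: np.ndarray
    provenance: pd.DataFrame  # columns: post_id, follower_id, originator_id

    def __len__(self) -> int:
        return len(self.y)

    @property
    def summary(self) -> ExposureSummary:
        return ExposureSummary(n_rows=len(self.y), n_positives=int(self.y.sum()))


def build_exposure_dataset(
    log: EngagementLog,
    network: InfoFlowNetwork,
    store: FeatureStore,
    window: tuple[datetime, datetime] | None = None,
) -> ExposureDataset:
    """One row per (post, follower-of-author) pair in the window.

    The label is 1 exactly when that follower reshared that post; absence of
    a reshare under the everyone-sees-everything exposure assumption is a
    negative event.
    """
    sub = log.in_window(window) if window is not None else log
    resharers: dict[str, set[str]] = {}
    for r in sub.records:
        if r.is_reshare:
            resharers.setdefault(r.parent_post_id, set()).add(r.user_id)

    blocks: list[np.ndarray] = []
    labels: list[np.ndarray] = []
    prov: list[tuple[str, str, str]] = []
    for r in sub.records:
        if r.type != "post" or r.user_id not in network:
            continue
        followers = network.followers(r.user_id)
        if not followers:
            continue
        blocks.append(store.feature_matrix(followers, r.user_id, r.text))
        got = resharers.get(r.post_id, set())
        labels.append(np.array([f in got for f in followers], dtype=np.int8))
        prov.extend((r.post_id, f, r.user_id) for f in followers)
    if not blocks:
        raise ValueError("no posts with followers in window; empty exposure dataset")
    ds = ExposureDataset(
        X=np.vstack(blocks),
        y=np.concatenate(labels),
        provenance=pd.DataFrame(prov, columns=["post_id", "follower_id", "originator_id"]),
    )
    logger.info("exposure dataset: %s", ds.summary)
    return ds


def downsample_negatives(
    dataset: ExposureDataset, keep_fraction: float, seed: int = 0
) -> tuple[ExposureDataset, float]:
    """Keep all positives and a fraction of negatives, for desk-scale runs.

    Returns the reduced dataset and ``keep_fraction`` itself, to be passed to
    :func:`fit_calibration` as ``neg_keep_fraction`` so the calibration step
    absorbs the induced prior shift.
    """
    rng = np.random.default_rng(seed)
    neg = np.flatnonzero(dataset.y == 0)
    pos = np.flatnonzero(dataset.y == 1)
    keep_neg = neg[rng.random(len(neg)) < keep_fraction]
    idx = np.sort(np.concatenate([pos, keep_neg]))
    return (
        ExposureDataset(
            X=dataset.X[idx],
            y=dataset.y[idx],
            provenance=dataset.provenance.iloc[idx].reset_index(drop=True),
        ),
        keep_fraction,
    )


@dataclass
class TrainedClassifier:
    """A fitted classifier plus the train/held-out partition indices."""

    clf: HistGradientBoostingClassifier
    train_idx: np.ndarray
    test_idx: np.ndarray

    def raw_scores(self, X: np.ndarray) -> np.ndarray:
        return self.clf.predict_proba(X)[:, 1]


def train_classifier(
    dataset: ExposureDataset,
    split_fraction_train: float = 0.2,
    seed: int = 0,
    hyperparams: dict | None = None,
    search_budget: int = 0,
) -> TrainedClassifier:
    """Fit a gradient-boosted tree classifier on a random train partition.

    By default 20% of rows train the model and the remaining 80% are held
    out (the held-out majority later feeds calibration).  ``search_budget``
    > 0 runs a seeded random search over a small hyperparameter space,
    scored by AUC on a third of the training partition.
    """
    n = len(dataset)
    rng = np.random.default_rng(seed)
    perm = rng.permutation(n)
    n_train = max(int(round(split_fraction_train * n)), 1)
    train_idx, test_idx = np.sort(perm[:n_train]), np.sort(perm[n_train:])
    y_train = dataset.y[train_idx]
    if len(np.unique(y_train)) < 2:
        raise ValueError(
            "training partition contains a single class; resample or enlarge the dataset"
        )

    params = dict(hyperparams or {})
    if search_budget > 0:
        params = _random_search(dataset, train_idx, search_budget, seed)
    clf = HistGradientBoostingClassifier(random_state=seed, **params)
    clf.fit(dataset.X[train_idx], y_train)
    return TrainedClassifier(clf=clf, train_idx=train_idx, test_idx=test_idx)


def _random_search(
    dataset: ExposureDataset, train_idx: np.ndarray, budget: int, seed: int
) -> dict:
    rng = np.random.default_rng(seed)
    inner = rng.permutation(len(train_idx))
    cut = max(len(inner) * 2 // 3, 1)
    fit_i, val_i = train_idx[inner[:cut]], train_idx[inner[cut:]]
    if len(np.unique(dataset.y[val_i])) < 2 or len(np.unique(dataset.y[fit_i])) < 2:
        logger.warning("single-class inner split; skipping hyperparameter search")
        return {}
    best, best_auc = {}, -np.inf
    for _ in range(budget):
        cand = {
            "learning_rate": float(10 ** rng.uniform(-2, -0.3)),
            "max_leaf_nodes": int(rng.integers(7, 64)),
            "min_samples_leaf": int(rng.integers(5, 50)),
            "max_iter": int(rng.integers(50, 200)),
        }
        clf = HistGradientBoostingClassifier(random_state=seed, **cand)
        clf.fit(dataset.X[fit_i], dataset.y[fit_i])
        auc = roc_auc_score(dataset.y[val_i], clf.predict_proba(dataset.X[val_i])[:, 1])
        if auc > best_auc:
            best, best_auc = cand, auc
    logger.info("random search best AUC %.3f with %s", best_auc, best)
    return best


@dataclass
class CalibrationCurve:
    """Quantile-binned empirical reshare rates smoothed by a monotone polynomial.

    Raw scores are mapped to their quantile position via the stored edges
    (a piecewise-linear empirical CDF), then through a degree-11 polynomial
    with non-negative coefficients — non-decreasing by construction — and
    clipped to [0, 1].
    """

    edges: np.ndarray  # strictly increasing raw-score quantiles
    levels: np.ndarray  # CDF level of each edge
    bin_rates: np.ndarray  # empirical positive rate per quantile bin
    coefficients: np.ndarray  # polynomial coefficients, increasing order, >= 0
    n_quantiles: int
    degree: int = 11

    def quantile_of(self, raw: np.ndarray) -> np.ndarray:
        return np.interp(np.asarray(raw, dtype=float), self.edges, self.levels)

    def calibrate(self, raw: np.ndarray) -> np.ndarray:
        q = self.quantile_of(raw)
        val = np.polynomial.polynomial.polyval(q, self.coefficients)
        return np.clip(val, 0.0, 1.0)

    def to_json(self, path: str | Path) -> None:
        with open(path, "w") as fh:
            json.dump(
                {
                    "edges": self.edges.tolist(),
                    "levels": self.levels.tolist(),
                    "bin_rates": self.bin_rates.tolist(),
                    "coefficients": self.coefficients.tolist(),
                    "n_quantiles": self.n_quantiles,
                    "degree": self.degree,
                },
                fh,
            )

    @classmethod
    def from_json(cls, path: str | Path) -> "CalibrationCurve":
        with open(path) as fh:
            d = json.load(fh)
        return cls(
            edges=np.array(d["edges"]),
            levels=np.array(d["levels"]),
            bin_rates=np.array(d["bin_rates"]),
            coefficients=np.array(d["coefficients"]),
            n_quantiles=d["n_quantiles"],
            degree=d["degree"],
        )


def fit_calibration(
    raw_scores: np.ndarray,
    labels: np.ndarray,
    n_quantiles: int = 100,
    degree: int = 11,
    neg_keep_fraction: float = 1.0,
) -> CalibrationCurve:
    """Map raw scores to empirical probabilities via 100 quantile bins.

    Observations are split into ``n_quantiles`` equal-count bins by raw
    score; each bin's empirical positive rate is regressed (non-negative
    least squares on the monomial basis of the bin's central quantile level)
    onto a degree-11 polynomial.  If negatives were downsampled upstream,
    ``neg_keep_fraction`` restores the bin rates to the original prior via
    the odds correction ``r -> κr / (κr + 1 - r)``.
    """
    raw = np.asarray(raw_scores, dtype=float)
    y = np.asarray(labels)
    if raw.shape != y.shape:
        raise ValueError("scores and labels must have equal length")
    if len(raw) < n_quantiles:
        n_quantiles = max(len(raw) // 2, 1)
        logger.warning("fewer observations than bins; reducing to %d bins", n_quantiles)

    order = np.argsort(raw, kind="stable")
    bins = np.array_split(order, n_quantiles)
    rates = np.array([y[b].mean() for b in bins])
    if neg_keep_fraction != 1.0:
        k = neg_keep_fraction
        rates = k * rates / (k * rates + (1.0 - rates))
    centers = (np.arange(n_quantiles) + 0.5) / n_quantiles

    V = np.vander(centers, degree + 1, increasing=True)
    coeffs, _ = nnls(V, rates)

    qs = np.linspace(0.0, 1.0, n_quantiles + 1)
    edges = np.quantile(raw, qs)
    keep = np.concatenate([[True], np.diff(edges) > 0])
    return CalibrationCurve(
        edges=edges[keep],
        levels=qs[keep],
        bin_rates=rates,
        coefficients=coeffs,
        n_quantiles=n_quantiles,
        degree=degree,
    )


@dataclass
class InfectionModel:
    """Classifier + calibration + α: the simulator's transmission kernel."""

    store: FeatureStore
    classifier: TrainedClassifier
    calibration: CalibrationCurve
    alpha: float = 1.0

    def raw_score(self, follower: str, originator: str, tweet_text: str) -> float:
        x = self.store.feature_row(follower, originator, tweet_text)
        return float(self.classifier.raw_scores(x[None, :])[0])

    def predict_ip(
        self, follower: str, originator: str, tweet_text: str, sharer: str | None = None
    ) -> float:
        """Calibrated, α-scaled infection probability, clipped to [0, 1]."""
        return float(
            self.ip_for_followers([follower], originator, tweet_text, sharer)[0]
        )

    def ip_for_followers(
        self,
        followers: list[str],
        originator: str,
        tweet_text: str,
        sharer: str | None = None,
    ) -> np.ndarray:
        if not followers:
            return np.zeros(0)
        try:
            X = self.store.feature_matrix(followers, originator, tweet_text)
        except KeyError as e:
            raise KeyError(f"cannot featurize: {e.args[0]}") from e
        raw = self.classifier.raw_scores(X)
        return np.clip(self.alpha * self.calibration.calibrate(raw), 0.0, 1.0)

    # ------------------------------------------------------------------ io

    def save(self, directory: str | Path) -> None:
        directory = Path(directory)
        directory.mkdir(parents=True, exist_ok=True)
        with open(directory / "classifier.pkl", "wb") as fh:
            pickle.dump(self.classifier, fh)
        self.calibration.to_json(directory / "calibration.json")
        with open(directory / "metadata.json", "w") as fh:
            json.dump({"alpha": self.alpha}, fh)

    @classmethod
    def load(cls, directory: str | Path, store: FeatureStore) -> "InfectionModel":
        directory = Path(directory)
        with open(directory / "classifier.pkl", "rb") as fh:
            classifier = pickle.load(fh)
        calibration = CalibrationCurve.from_json(directory / "calibration.json")
        with open(directory / "metadata.json") as fh:
            alpha = json.load(fh)["alpha"]
        return cls(store=store, classifier=classifier, calibration=calibration, alpha=alpha)


def evaluate_auc_over_time(
    classifier: TrainedClassifier, datasets: list[ExposureDataset]
) -> list[float]:
    """Discrimination (AUC-ROC) of raw scores on a sequence of time slices.

    Single-class slices are skipped with a warning and reported as NaN so
    positions stay aligned with the input slices.
    """
    out: list[float] = []
    for i, ds in enumerate(datasets):
        if len(np.unique(ds.y)) < 2:
            logger.warning("slice %d has a single class; skipped", i)
            out.append(float("nan"))
            continue
        out.append(float(roc_auc_score(ds.y, classifier.raw_scores(ds.X))))
    return out


def train_infection_model(
    log: EngagementLog,
    network: InfoFlowNetwork,
    store: FeatureStore,
    window: tuple[datetime, datetime] | None = None,
    alpha: float = 1.0,
    seed: int = 0,
    split_fraction_train: float = 0.2,
    search_budget: int = 0,
) -> tuple[InfectionModel, ExposureDataset]:
    """End-to-end convenience: exposure dataset → classifier → calibration → model."""
    dataset = build_exposure_dataset(log, network, store, window)
    trained = train_classifier(
        dataset, split_fraction_train=split_fraction_train, seed=seed,
        search_budget=search_budget,
    )
    raw = trained.raw_scores(dataset.X[trained.test_idx])
    curve = fit_calibration(raw, dataset.y[trained.test_idx])
    return InfectionModel(store=store, classifier=trained, calibration=curve, alpha=alpha), dataset
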