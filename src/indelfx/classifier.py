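"""Pathogenicity model: preprocessing plus a bagged neural-network ensemble.

The model is an ensemble of one hundred two-layer feed-forward networks
with ten hidden units each.  Every member is trained on a class-balanced
sample (all minority-class examples plus a uniform random undersample of
the majority class, without replacement), with 25% of its sample held out
as a validation set for early stopping.  The ensemble score is the mean of
member outputs and lies in [0, 1]; scores near one indicate likely
pathogenic variants.

Preprocessing is minimal: a per-feature two-sample Welch t-test keeps
features with P < 0.5, data are z-score normalized, and a principal-
component projection retaining at least 99% of variance is applied.  All
preprocessing parameters are fitted on training folds only.

Training uses full-batch resilient propagation (Rprop), which adapts a
per-weight step size from gradient signs only; it is insensitive to
gradient magnitude and deterministic given the seed.
"""

from __future__ import annotations

import json
from dataclasses import dataclass, field, asdict
from typing import Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.decomposition import PCA

#: Score cutoffs of the published reference model, for compatibility
#: reporting only.  Retrained models derive their own cutoffs with
#: :func:`indelfx.evaluation.threshold_at_fpr`.
PUBLISHED_THRESHOLDS = {0.10: 0.546, 0.05: 0.672, 0.01: 0.85}

MODEL_FORMAT_VERSION = 1


@dataclass
class ClassifierConfig:
    n_networks: int = 100
    hidden_units: int = 10
    val_fraction: float = 0.25
    max_epochs: int = 150
    patience: int = 10
    t_test_p: float = 0.5
    retained_variance: float = 0.99
    seed: int = 0


class Preprocessor:
    """t-test feature mask + z-scoring + variance-retaining projection."""

    def __init__(self, t_test_p: float = 0.5, retained_variance: float = 0.99):
        self.t_test_p = t_test_p
        self.retained_variance = retained_variance
        self.feature_names: Optional[tuple] = None
        self.selected_: Optional[np.ndarray] = None
        self.means_: Optional[np.ndarray] = None
        self.sds_: Optional[np.ndarray] = None
        self.components_: Optional[np.ndarray] = None
        self.explained_variance_ratio_: Optional[np.ndarray] = None

    def fit(self, X, y) -> "Preprocessor":
        X, names = _as_matrix(X)
        y = np.asarray(y)
        if not np.all(np.isfinite(X)):
            raise ValueError("non-finite values in feature matrix")
        classes = np.unique(y)
        if classes.size != 2:
            raise ValueError("exactly two classes required")
        if min((y == c).sum() for c in classes) < 2:
            raise ValueError("need >= 2 examples per class")
        self.feature_names = names

        # constant features first: a t-test on them is meaningless
        sds = X.std(axis=0, ddof=0)
        nonconst = sds > 0
        a, b = X[y == classes[0]], X[y == classes[1]]
        with np.errstate(invalid="ignore", divide="ignore"):
            _, pvals = stats.ttest_ind(a, b, equal_var=False)
        pvals = np.where(np.isnan(pvals), 1.0, pvals)
        self.selected_ = nonconst & (pvals < self.t_test_p)
        if not self.selected_.any():
            raise ValueError("t-test selection removed every feature")

        Xs = X[:, self.selected_]
        self.means_ = Xs.mean(axis=0)
        self.sds_ = Xs.std(axis=0, ddof=0)
        Z = (Xs - self.means_) / self.sds_
        pca = PCA(n_components=self.retained_variance, svd_solver="full")
        pca.fit(Z)
        self.components_ = pca.components_
        self.pca_mean_ = pca.mean_
        self.explained_variance_ratio_ = pca.explained_variance_ratio_
        return self

    def transform(self, X) -> np.ndarray:
        X, names = _as_matrix(X)
        if names is not None and self.feature_names is not None \
                and names != self.feature_names:
            raise ValueError("feature names do not match the fitted preprocessor")
        Z = (X[:, self.selected_] - self.means_) / self.sds_
        return (Z - self.pca_mean_) @ self.components_.T

    @property
    def retained_variance_(self) -> float:
        return float(self.explained_variance_ratio_.sum())


def fit_preprocessor(X, y, t_test_p: float = 0.5,
                     retained_variance: float = 0.99) -> Preprocessor:
    """Fit the t-test/normalization/projection preprocessor on (X, y)."""
    return Preprocessor(t_test_p, retained_variance).fit(X, y)


def _as_matrix(X):
    if isinstance(X, pd.DataFrame):
        return X.to_numpy(dtype=float), tuple(X.columns)
    return np.asarray(X, dtype=float), None


def _sigmoid(z):
    return 0.5 * (1.0 + np.tanh(0.5 * z))


class _RpropNet:
    """Two-layer tanh/sigmoid network trained with full-batch Rprop.

    Step sizes grow by 1.2 when a gradient keeps its sign and shrink by 0.5
    when it flips (iRprop-: flipped gradients are zeroed, no weight
    backtracking).  Early stopping monitors cross-entropy on a held-out
    validation split and restores the best weights.
    """

    ETA_PLUS, ETA_MINUS = 1.2, 0.5
    DELTA0, DELTA_MIN, DELTA_MAX = 0.1, 1e-6, 50.0

    def __init__(self, n_in: int, n_hidden: int, rng: np.random.Generator):
        s = 1.0 / np.sqrt(n_in + 1)
        self.W1 = rng.uniform(-s, s, size=(n_in, n_hidden))
        self.b1 = np.zeros(n_hidden)
        s2 = 1.0 / np.sqrt(n_hidden + 1)
        self.W2 = rng.uniform(-s2, s2, size=(n_hidden, 1))
        self.b2 = np.zeros(1)

    def _params(self):
        return [self.W1, self.b1, self.W2, self.b2]

    def forward(self, X: np.ndarray) -> np.ndarray:
        H = np.tanh(X @ self.W1 + self.b1)
        return _sigmoid(H @ self.W2 + self.b2)[:, 0]

    def _grads(self, X, y):
        H = np.tanh(X @ self.W1 + self.b1)
        p = _sigmoid(H @ self.W2 + self.b2)[:, 0]
        d2 = (p - y)[:, None] / len(y)           # dL/dz2 for mean CE loss
        gW2 = H.T @ d2
        gb2 = d2.sum(axis=0)
        dH = d2 @ self.W2.T * (1.0 - H**2)
        gW1 = X.T @ dH
        gb1 = dH.sum(axis=0)
        return [gW1, gb1, gW2, gb2]

    @staticmethod
    def _loss(p, y, eps=1e-12):
        p = np.clip(p, eps, 1 - eps)
        return float(-np.mean(y * np.log(p) + (1 - y) * np.log(1 - p)))

    def train(self, X, y, X_val, y_val, max_epochs: int, patience: int):
        params = self._params()
        deltas = [np.full_like(p, self.DELTA0) for p in params]
        prev = [np.zeros_like(p) for p in params]
        best_loss = np.inf
        best = [p.copy() for p in params]
        since_best = 0
        for _ in range(max_epochs):
            grads = self._grads(X, y)
            for p, g, d, pg in zip(params, grads, deltas, prev):
                sign = np.sign(g)
                prod = pg * g
                d[prod > 0] = np.minimum(d[prod > 0] * self.ETA_PLUS,
                                         self.DELTA_MAX)
                d[prod < 0] = np.maximum(d[prod < 0] * self.ETA_MINUS,
                                         self.DELTA_MIN)
                g = np.where(prod < 0, 0.0, g)  # iRprop-
                p -= np.sign(g) * d
                pg[...] = g
            val_loss = self._loss(self.forward(X_val), y_val)
            if val_loss < best_loss - 1e-9:
                best_loss = val_loss
                best = [p.copy() for p in params]
                since_best = 0
            else:
                since_best += 1
                if since_best >= patience:
                    break
        self.W1, self.b1, self.W2, self.b2 = [b.copy() for b in best]
        return best_loss


@dataclass
class TrainedModel:
    """Fitted preprocessor + network ensemble + score thresholds."""

    preprocessor: Preprocessor
    networks: list
    bag_indices: list
    config: ClassifierConfig
    seed: int
    thresholds: dict = field(default_factory=dict)
    feature_names: Optional[tuple] = None

    def predict(self, X) -> np.ndarray:
        return predict_scores(self, X)

    def save(self, path) -> None:
        arrays = {}
        for i, net in enumerate(self.networks):
            for k in ("W1", "b1", "W2", "b2"):
                arrays[f"net{i}_{k}"] = getattr(net, k)
        pp = self.preprocessor
        arrays.update(pp_selected=pp.selected_, pp_means=pp.means_,
                      pp_sds=pp.sds_, pp_components=pp.components_,
                      pp_pca_mean=pp.pca_mean_,
                      pp_evr=pp.explained_variance_ratio_)
        meta = {
            "format_version": MODEL_FORMAT_VERSION,
            "config": asdict(self.config),
            "seed": self.seed,
            "thresholds": {str(k): v for k, v in self.thresholds.items()},
            "feature_names": list(self.feature_names or []),
            "n_networks": len(self.networks),
            "t_test_p": pp.t_test_p,
            "retained_variance": pp.retained_variance,
        }
        arrays["meta_json"] = np.frombuffer(
            json.dumps(meta).encode(), dtype=np.uint8)
        np.savez(path, **arrays)

    @classmethod
    def load(cls, path) -> "TrainedModel":
        data = np.load(path)
        meta = json.loads(bytes(data["meta_json"].tolist()).decode())
        if meta["format_version"] != MODEL_FORMAT_VERSION:
            raise ValueError("unsupported model format version")
        pp = Preprocessor(meta["t_test_p"], meta["retained_variance"])
        pp.selected_ = data["pp_selected"]
        pp.means_ = data["pp_means"]
        pp.sds_ = data["pp_sds"]
        pp.components_ = data["pp_components"]
        pp.pca_mean_ = data["pp_pca_mean"]
        pp.explained_variance_ratio_ = data["pp_evr"]
        pp.feature_names = tuple(meta["feature_names"]) or None
        nets = []
        for i in range(meta["n_networks"]):
            net = _RpropNet.__new__(_RpropNet)
            net.W1 = data[f"net{i}_W1"]
            net.b1 = data[f"net{i}_b1"]
            net.W2 = data[f"net{i}_W2"]
            net.b2 = data[f"net{i}_b2"]
            nets.append(net)
        cfg = ClassifierConfig(**meta["config"])
        return cls(preprocessor=pp, networks=nets, bag_indices=[],
                   config=cfg, seed=meta["seed"],
                   thresholds={float(k): v
                               for k, v in meta["thresholds"].items()},
                   feature_names=tuple(meta["feature_names"]) or None)


def _balanced_bag(y: np.ndarray, rng: np.random.Generator) -> np.ndarray:
    """All minority-class indices plus a uniform undersample (without
    replacement) of the majority class to the minority size."""
    idx0 = np.flatnonzero(y == 0)
    idx1 = np.flatnonzero(y == 1)
    minority, majority = (idx1, idx0) if len(idx1) <= len(idx0) else (idx0, idx1)
    sampled = rng.choice(majority, size=len(minority), replace=False)
    bag = np.concatenate([minority, sampled])
    rng.shuffle(bag)
    return bag


def train_ensemble(X, y, config: Optional[ClassifierConfig] = None,
                   preprocessor: Optional[Preprocessor] = None) -> TrainedModel:
    """Train the bagged ensemble on labeled features.

    ``y`` must be binary with 1 = pathogenic.  The preprocessor is fitted
    here unless a fitted one is supplied (cross-validation fits it on the
    training fold and passes it in).  Deterministic given (data, config).
    """
    config = config or ClassifierConfig()
    Xmat, names = _as_matrix(X)
    y = np.asarray(y, dtype=float)
    if set(np.unique(y)) - {0.0, 1.0}:
        raise ValueError("labels must be binary 0/1")
    n_minority = int(min((y == 0).sum(), (y == 1).sum()))
    if n_minority < 4:
        raise ValueError("minority class must have >= 4 examples")
    if preprocessor is None:
        preprocessor = fit_preprocessor(
            X, y, config.t_test_p, config.retained_variance)
    Z = preprocessor.transform(X)

    ss = np.random.SeedSequence(config.seed)
    nets, bags = [], []
    for child in ss.spawn(config.n_networks):
        rng = np.random.default_rng(child)
        bag = _balanced_bag(y, rng)
        n_val = max(1, int(round(config.val_fraction * len(bag))))
        val, train = bag[:n_val], bag[n_val:]
        net = _RpropNet(Z.shape[1], config.hidden_units, rng)
        net.train(Z[train], y[train], Z[val], y[val],
                  config.max_epochs, config.patience)
        nets.append(net)
        bags.append(bag)
    return TrainedModel(preprocessor=preprocessor, networks=nets,
                        bag_indices=bags, config=config, seed=config.seed,
                        feature_names=names)


def predict_scores(model: TrainedModel, X) -> np.ndarray:
    """Ensemble pathogenicity scores in [0, 1] (mean of member outputs)."""
    _, names = _as_matrix(X)
    if names is not None and model.feature_names is not None \
            and names != model.feature_names:
        raise ValueError("feature names do not match the trained model")
    Z = model.preprocessor.transform(X)
    scores = np.mean([net.forward(Z) for net in model.networks], axis=0)
    return np.clip(scores, 0.0, 1.0)


def classify_at_threshold(score, level=None, cutoff: Optional[float] = None,
                          thresholds: Optional[dict] = None):
    """Call pathogenic/neutral at an FPR level or an explicit cutoff.

    ``level`` is an FPR fraction (0.10, 0.05 or 0.01) looked up in
    ``thresholds`` (defaults to the published reference cutoffs); a score
    exactly at the cutoff is called pathogenic.
    """
    if cutoff is None:
        table = thresholds if thresholds is not None else PUBLISHED_THRESHOLDS
        if level not in table:
            raise KeyError(f"unknown FPR level {level!r}")
        cutoff = table[level]
    score = np.asarray(score, dtype=float)
    calls = np.where(score >= cutoff, "pathogenic", "neutral")
    return calls.item() if calls.ndim == 0 else calls
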