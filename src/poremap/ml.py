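"""Poration-site classification: oversampling, training, evaluation.

The porated class (~60 locations) is far smaller than the non-porated
reference set (300 locations), so the minority class is rebalanced with
SMOTE — synthetic rows interpolated between a minority row and one of its k
nearest minority neighbours — before training a random forest, an RBF-kernel
support vector machine, or a one-hidden-layer perceptron. Accuracy is the
fraction of correctly predicted (location, frame) rows, porated and
non-porated, over all rows. A location is *called* porated only when the
classifier flags it in more than 90% of trajectory frames.

The default protocol oversamples the training portion only;
``oversample_before_split`` balances the whole dataset first, reproducing
the historically used 60/40 protocol together with its acknowledged
optimistic bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.ensemble import RandomForestClassifier
from sklearn.neighbors import NearestNeighbors
from sklearn.neural_network import MLPClassifier
from sklearn.pipeline import make_pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .groups import DENSITY_GROUPS
from .surface import ALL_FEATURES
from .util import rng_for

ALGORITHMS = ("random-forest", "support-vector-machine", "multilayer-perceptron")
FOUR_FEATURES = ["PU", "GM", "CHOL", "FS"]
META_COLUMNS = ["membrane_id", "location_id", "frame", "x_rel", "y_rel", "system", "label"]


def smote_oversample(X: np.ndarray, y: np.ndarray, k_neighbors: int = 5,
                     seed: int = 0) -> tuple[np.ndarray, np.ndarray]:
    """Balance classes by synthetic minority oversampling.

    New minority rows are convex combinations ``x + u * (neighbor - x)`` with
    u ~ U(0, 1), the neighbour drawn among the k nearest minority rows.
    Majority rows pass through untouched. Deterministic given the seed.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y)
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) != 2:
        raise ValueError("SMOTE expects exactly two classes")
    minority = classes[np.argmin(counts)]
    n_min, n_maj = counts.min(), counts.max()
    if n_min == n_maj:
        return X.copy(), y.copy()
    if n_min <= k_neighbors:
        raise ValueError(
            f"minority class has {n_min} members, not enough for k_neighbors="
            f"{k_neighbors}; use a smaller k")
    Xm = X[y == minority]
    nn = NearestNeighbors(n_neighbors=k_neighbors + 1).fit(Xm)
    _, neigh = nn.kneighbors(Xm)
    neigh = neigh[:, 1:]  # drop self
    rng = rng_for(seed, "smote")
    n_new = n_maj - n_min
    base = rng.integers(0, n_min, n_new)
    pick = neigh[base, rng.integers(0, k_neighbors, n_new)]
    u = rng.random((n_new, 1))
    X_new = Xm[base] + u * (Xm[pick] - Xm[base])
    return (np.vstack([X, X_new]),
            np.concatenate([y, np.full(n_new, minority, dtype=y.dtype)]))


def train_classifier(X: np.ndarray, y: np.ndarray, algorithm: str = "random-forest",
                     hyperparams: dict | None = None, seed: int = 0):
    """Fit one of the three classifier families.

    Margin and perceptron models standardize features inside a pipeline;
    the tree ensemble consumes raw values and exposes ``feature_importances_``.
    """
    if len(np.unique(y)) < 2:
        raise ValueError("training set contains a single class")
    hp = dict(hyperparams or {})
    rs = int(seed) & 0x7FFFFFFF
    if algorithm == "random-forest":
        model = RandomForestClassifier(n_estimators=hp.pop("n_estimators", 100),
                                       random_state=rs, n_jobs=1, **hp)
    elif algorithm == "support-vector-machine":
        model = make_pipeline(StandardScaler(),
                              SVC(kernel=hp.pop("kernel", "rbf"),
                                  random_state=rs, **hp))
    elif algorithm == "multilayer-perceptron":
        model = make_pipeline(
            StandardScaler(),
            MLPClassifier(hidden_layer_sizes=hp.pop("hidden_layer_sizes", (100,)),
                          max_iter=hp.pop("max_iter", 500), random_state=rs, **hp))
    else:
        raise ValueError(f"unknown algorithm {algorithm!r}; choose from {ALGORITHMS}")
    model.fit(X, y)
    return model


def accuracy(predictions: np.ndarray, truth: np.ndarray) -> float:
    """Correctly predicted (location, frame) rows over all rows."""
    predictions = np.asarray(predictions)
    truth = np.asarray(truth)
    if len(predictions) != len(truth):
        raise ValueError("length mismatch")
    if len(truth) == 0:
        raise ValueError("empty prediction set")
    return float((predictions == truth).mean())


def per_location_call(predictions: pd.DataFrame, threshold: float = 0.9,
                      location_columns: tuple[str, ...] = ("membrane_id", "location_id"),
                      prediction_column: str = "prediction") -> pd.DataFrame:
    """Locations classified porated in strictly more than ``threshold`` of
    their frames. Returns the per-location porated-frame fraction and call."""
    frac = (predictions.groupby(list(location_columns))[prediction_column]
            .mean().rename("porated_fraction").reset_index())
    frac["called_porated"] = frac["porated_fraction"] > threshold
    return frac


@dataclass
class SplitScheme:
    """Train/test row selectors over a feature matrix.

    ``name`` picks the protocol: ``pairwise-membranes`` (train on some
    membranes, test on the rest), ``cross-composition`` / ``cross-polarity``
    (train selector by system category), ``random-60-40`` (random split by
    location), ``first-events-holdout`` (first ``train_fraction`` of porated
    and non-porated locations per membrane). ``train`` / ``test`` hold the
    membrane ids or system categories the named scheme selects on.
    """

    name: str
    train: list[str] = field(default_factory=list)
    test: list[str] = field(default_factory=list)
    train_fraction: float = 0.6
    seed: int = 0


def _split_rows(features: pd.DataFrame, scheme: SplitScheme) -> tuple[np.ndarray, np.ndarray]:
    if scheme.name == "pairwise-membranes":
        tr = features["membrane_id"].isin(scheme.train).to_numpy()
        te = features["membrane_id"].isin(scheme.test).to_numpy()
    elif scheme.name in ("cross-composition", "cross-polarity"):
        if "system" not in features.columns:
            raise ValueError(f"scheme {scheme.name} needs a 'system' column")
        tr = features["system"].isin(scheme.train).to_numpy()
        te = features["system"].isin(scheme.test).to_numpy()
    elif scheme.name == "random-60-40":
        keys = features[["membrane_id", "location_id"]].drop_duplicates()
        rng = rng_for(scheme.seed, "random-60-40")
        n_train = int(round(scheme.train_fraction * len(keys)))
        order = rng.permutation(len(keys))
        train_keys = keys.iloc[order[:n_train]]
        merged = features.merge(train_keys.assign(_tr=True), how="left",
                                on=["membrane_id", "location_id"])
        tr = merged["_tr"].eq(True).to_numpy()
        te = ~tr
    elif scheme.name == "first-events-holdout":
        tr = np.zeros(len(features), dtype=bool)
        for (_, lab), sub in features.groupby(["membrane_id", "label"]):
            locs = np.sort(sub["location_id"].unique())
            head = locs[: int(round(scheme.train_fraction * len(locs)))]
            tr |= (features["membrane_id"].isin(sub["membrane_id"].unique())
                   & (features["label"] == lab)
                   & features["location_id"].isin(head)).to_numpy()
        te = ~tr
    else:
        raise ValueError(f"unknown split scheme {scheme.name!r}")
    if not tr.any() or not te.any():
        raise ValueError(f"scheme {scheme.name} selects an empty train or test set")
    return tr, te


@dataclass
class ClassifierReport:
    algorithm: str
    scheme: str
    train_accuracy: float
    test_accuracy: float
    importances: dict[str, float] | None
    feature_subset: list[str]


def run_scheme(features: pd.DataFrame, scheme: SplitScheme,
               algorithm: str = "random-forest",
               feature_subset: list[str] | None = None,
               include_coordinates: bool = False, oversample_before_split: bool = False,
               k_neighbors: int = 5, hyperparams: dict | None = None,
               seed: int = 0) -> ClassifierReport:
    """Train one classifier under one split scheme and report both accuracies.

    By default the (x, y) coordinates are carried as row identifiers but kept
    out of the feature vector so the model cannot memorize geography;
    ``include_coordinates`` restores them. ``oversample_before_split``
    balances the whole dataset before splitting instead of the training
    rows only.
    """
    cols = list(feature_subset) if feature_subset is not None else \
        [c for c in ALL_FEATURES if c in features.columns]
    missing = [c for c in cols if c not in features.columns]
    if missing:
        raise ValueError(f"feature columns not in matrix: {missing}")
    if include_coordinates:
        cols = ["x_rel", "y_rel"] + cols
    tr, te = _split_rows(features, scheme)
    if not oversample_before_split:
        overlap = (set(map(tuple, features.loc[tr, ["membrane_id", "location_id"]].to_numpy()))
                   & set(map(tuple, features.loc[te, ["membrane_id", "location_id"]].to_numpy())))
        if overlap and scheme.name != "random-60-40":
            raise ValueError(f"train/test leakage: {len(overlap)} shared locations")

    def xy(mask: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
        sub = features.loc[mask]
        return sub[cols].to_numpy(dtype=float), sub["label"].to_numpy(dtype=int)

    X_tr, y_tr = xy(tr)
    X_te, y_te = xy(te)
    if oversample_before_split:
        X_all, y_all = smote_oversample(
            np.vstack([X_tr, X_te]), np.concatenate([y_tr, y_te]),
            k_neighbors=k_neighbors, seed=seed)
        n_orig = len(y_tr) + len(y_te)
        rng = rng_for(seed, "oversample-first-split")
        order = rng.permutation(len(y_all))
        cut = int(round(scheme.train_fraction * len(y_all)))
        tr_idx, te_idx = order[:cut], order[cut:]
        X_tr, y_tr = X_all[tr_idx], y_all[tr_idx]
        X_te, y_te = X_all[te_idx], y_all[te_idx]
        del n_orig
    else:
        X_tr, y_tr = smote_oversample(X_tr, y_tr, k_neighbors=k_neighbors, seed=seed)

    model = train_classifier(X_tr, y_tr, algorithm, hyperparams, seed=seed)
    report = ClassifierReport(
        algorithm=algorithm,
        scheme=scheme.name,
        train_accuracy=accuracy(model.predict(X_tr), y_tr),
        test_accuracy=accuracy(model.predict(X_te), y_te),
        importances=None,
        feature_subset=cols,
    )
    if hasattr(model, "feature_importances_"):
        report.importances = dict(zip(cols, model.feature_importances_.tolist()))
    return report
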