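"""Tree/mesh classification of valve morphometric feature tables.

Features are min-max normalized to [0, 1], a randomized-tree ensemble is
trained on the images with obvious class tendency, and every image is
assigned a *meshiness*: the probability weight of the mesh-like class
(the tree weight is its complement).  Condition-level meshiness is the
mean of per-image probabilities.

Three learners are supported: a single decision tree (DTC, kept for
comparison but deprecated because of its lower accuracy), a random
forest (RFC) and extremely randomized trees (ETC).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Any, Sequence

import numpy as np
import pandas as pd
from sklearn.ensemble import ExtraTreesClassifier, RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.tree import DecisionTreeClassifier

from .morphometry import FEATURE_NAMES

METHODS = ("DTC", "RFC", "ETC")
CLASSES = ("tree", "mesh")

#: hyperparameter grid searched when tuning; ties break toward the
#: simpler model (fewer trees, shallower)
DEFAULT_GRID = [
    {"n_estimators": n, "max_depth": d} for n in (100, 300) for d in (5, None)
]


@dataclass
class FeatureTable:
    """Feature matrix with one row per valve image.

    ``data`` holds exactly the morphometric feature columns; ``labels``
    (tree/mesh or NaN for unlabeled) and ``condition`` are row-aligned
    metadata.
    """

    data: pd.DataFrame
    labels: pd.Series | None = None
    condition: pd.Series | None = None

    def __post_init__(self) -> None:
        missing = [c for c in FEATURE_NAMES if c not in self.data.columns]
        if missing:
            raise ValueError(f"feature table missing columns: {missing}")
        self.data = self.data[FEATURE_NAMES].astype(float)
        if self.labels is None:
            self.labels = pd.Series(np.nan, index=self.data.index, dtype=object)
        else:
            self.labels = self.labels.reindex(self.data.index)
        if self.condition is not None:
            self.condition = self.condition.reindex(self.data.index)

    def __len__(self) -> int:
        return len(self.data)

    def labeled_mask(self) -> pd.Series:
        return self.labels.notna()


@dataclass
class NormalizationRecord:
    """Per-column min/max of the table the scaling was fitted on."""

    mins: pd.Series
    maxs: pd.Series

    def apply(self, data: pd.DataFrame) -> pd.DataFrame:
        rng = (self.maxs - self.mins).replace(0.0, 1.0)
        out = (data - self.mins) / rng
        # constant columns map to 0 by convention
        const = self.maxs == self.mins
        out.loc[:, const[const].index] = 0.0
        return out

    def invert(self, data: pd.DataFrame) -> pd.DataFrame:
        rng = (self.maxs - self.mins).replace(0.0, 1.0)
        return data * rng + self.mins


def normalize_features(t: FeatureTable) -> tuple[FeatureTable, NormalizationRecord]:
    """Min-max scale every feature column into [0, 1].

    Fitted on the full table (labeled and unlabeled rows together), so
    the training and prediction rows live on one common scale.
    Constant columns map to 0.
    """
    if len(t) < 2:
        raise ValueError("need at least 2 rows to normalize")
    rec = NormalizationRecord(t.data.min(), t.data.max())
    return FeatureTable(rec.apply(t.data), t.labels, t.condition), rec


def select_training_set(
    t: FeatureTable, labels: pd.Series | dict | None = None
) -> tuple[FeatureTable, FeatureTable]:
    """Split into (labeled training table, unlabeled table to predict).

    ``labels`` overrides/extends the table's own labels; the training
    set must contain both classes.
    """
    lab = t.labels.copy()
    if labels is not None:
        labels = pd.Series(labels)
        unknown = labels.index.difference(t.data.index)
        if len(unknown):
            raise KeyError(f"labels reference unknown rows: {list(unknown)[:5]}")
        lab.loc[labels.index] = labels.values
    mask = lab.notna()
    present = set(lab[mask].unique())
    if not mask.any():
        raise ValueError("no labeled rows")
    if len(present) < 2:
        raise ValueError(f"training set must contain both classes, got {present}")
    train = FeatureTable(t.data[mask], lab[mask], None if t.condition is None else t.condition[mask])
    rest = FeatureTable(
        t.data[~mask], None, None if t.condition is None else t.condition[~mask]
    )
    return train, rest


@dataclass
class EnsembleModel:
    """A fitted tree-ensemble classifier plus its provenance."""

    method: str
    n_estimators: int = 100
    hyperparameters: dict[str, Any] = field(default_factory=dict)
    seed: int = 0
    estimator: Any = None
    deprecated: bool = False
    feature_names: list[str] = field(default_factory=lambda: list(FEATURE_NAMES))

    def __post_init__(self) -> None:
        if self.method not in METHODS:
            raise ValueError(f"method must be one of {METHODS}")
        self.deprecated = self.method == "DTC"

    def _make(self, seed: int) -> Any:
        hp = dict(self.hyperparameters)
        if self.method == "DTC":
            warnings.warn(
                "DTC is deprecated: single decision trees are less accurate "
                "than RFC/ETC on valve feature tables",
                DeprecationWarning,
                stacklevel=3,
            )
            return DecisionTreeClassifier(random_state=seed, **hp)
        cls = RandomForestClassifier if self.method == "RFC" else ExtraTreesClassifier
        return cls(n_estimators=self.n_estimators, random_state=seed, **hp)

    def fit(self, train: FeatureTable) -> "EnsembleModel":
        y = train.labels
        if y.isna().any():
            raise ValueError("training table contains unlabeled rows")
        self.estimator = self._make(self.seed)
        self.estimator.fit(train.data.values, y.values.astype(str))
        return self

    @property
    def fitted(self) -> bool:
        return self.estimator is not None


@dataclass
class CVResult:
    method: str
    accuracies: np.ndarray  # one value per repeat

    @property
    def mean(self) -> float:
        return float(np.mean(self.accuracies))

    @property
    def sd(self) -> float:
        return float(np.std(self.accuracies, ddof=1)) if len(self.accuracies) > 1 else 0.0


def cross_validate(
    train: FeatureTable,
    method: str = "ETC",
    k: int = 5,
    repeats: int = 40,
    seed: int = 0,
    hyperparameters: dict[str, Any] | None = None,
    n_estimators: int = 100,
) -> CVResult:
    """Stratified k-fold cross-validation accuracy, repeated with
    distinct seeds.

    Each repeat reshuffles the folds and reseeds the learner; the
    returned distribution of per-repeat accuracies is the measure of the
    method's accuracy on the labeled set.
    """
    if k < 2:
        raise ValueError("k must be >= 2")
    y = train.labels.values.astype(str)
    counts = pd.Series(y).value_counts()
    if (counts < k).any():
        raise ValueError(f"class sizes {dict(counts)} do not permit {k}-fold stratification")
    X = train.data.values
    accs = np.empty(repeats)
    for r in range(repeats):
        rs = seed + r
        model = EnsembleModel(
            method, n_estimators=n_estimators, hyperparameters=hyperparameters or {}, seed=rs
        )
        skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=rs)
        fold_acc = []
        for tr, te in skf.split(X, y):
            est = model._make(rs)
            est.fit(X[tr], y[tr])
            fold_acc.append(np.mean(est.predict(X[te]) == y[te]))
        accs[r] = np.mean(fold_acc)
    return CVResult(method, accs)


def select_hyperparameters(
    train: FeatureTable,
    method: str = "ETC",
    grid: Sequence[dict[str, Any]] = tuple(DEFAULT_GRID),
    k: int = 5,
    repeats: int = 5,
    seed: int = 0,
) -> dict[str, Any]:
    """Pick the grid point maximizing mean CV accuracy.

    Ties break toward the earlier (simpler) grid entry.
    """
    best, best_acc = None, -1.0
    for hp in grid:
        hp = dict(hp)
        n_est = hp.pop("n_estimators", 100)
        res = cross_validate(
            train, method, k=k, repeats=repeats, seed=seed,
            hyperparameters=hp, n_estimators=n_est,
        )
        if res.mean > best_acc + 1e-12:
            best_acc = res.mean
            best = {"n_estimators": n_est, **hp}
    return best


@dataclass
class MeshinessResult:
    """Per-image mesh probability and its per-condition aggregation."""

    per_image: pd.DataFrame  # columns: p_mesh, p_tree, condition, call
    per_condition: pd.DataFrame  # index: condition; columns: mean, sd, n


def predict_meshiness(model: EnsembleModel, t: FeatureTable) -> MeshinessResult:
    """Assign each image its meshiness p_mesh (tree weight = 1 - p_mesh).

    p_mesh is the ensemble's mean leaf probability for the mesh class.
    Hard calls use 0.5 as the boundary; a probability of exactly 0.5 is
    called "mixed".  Condition aggregation is the mean of per-image
    probabilities with sd and n.
    """
    if not model.fitted:
        raise ValueError("model is not fitted")
    if list(t.data.columns) != model.feature_names:
        raise ValueError("feature schema mismatch with training table")
    proba = model.estimator.predict_proba(t.data.values)
    classes = list(model.estimator.classes_)
    p_mesh = proba[:, classes.index("mesh")] if "mesh" in classes else np.zeros(len(t))
    call = np.where(p_mesh > 0.5, "mesh", np.where(p_mesh < 0.5, "tree", "mixed"))
    per_image = pd.DataFrame(
        {
            "p_mesh": p_mesh,
            "p_tree": 1.0 - p_mesh,
            "condition": t.condition if t.condition is not None else "all",
            "call": call,
        },
        index=t.data.index,
    )
    grp = per_image.groupby("condition")["p_mesh"]
    per_condition = pd.DataFrame(
        {"mean": grp.mean(), "sd": grp.std(ddof=1).fillna(0.0), "n": grp.size()}
    )
    return MeshinessResult(per_image, per_condition)


def feature_importances(model: EnsembleModel) -> pd.Series:
    """Mean impurity-decrease importance per feature, summing to 1."""
    if not model.fitted:
        raise ValueError("model is not fitted")
    imp = np.asarray(model.estimator.feature_importances_, float)
    s = imp.sum()
    if s > 0:
        imp = imp / s
    return pd.Series(imp, index=model.feature_names)


def importance_report(
    train: FeatureTable,
    method: str = "ETC",
    repeats: int = 40,
    seed: int = 0,
    n_estimators: int = 100,
) -> pd.DataFrame:
    """Feature importances over repeated fits (rows = repeats)."""
    rows = []
    for r in range(repeats):
        m = EnsembleModel(method, n_estimators=n_estimators, seed=seed + r).fit(train)
        rows.append(feature_importances(m))
    return pd.DataFrame(rows).reset_index(drop=True)
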