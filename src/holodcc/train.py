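"""Class balancing, model selection and classifier training.

Three classical families are supported — k-nearest-neighbour, random forest
and RBF support-vector machine — selected by exhaustive grid search with
stratified 5-fold cross-validation on the labeled (sorted-cell) feature
table.

Class imbalance is handled by SMOTE, implemented here directly because the
balancing contract is load-bearing for the protocol: synthetic rows carry a
flag and parent indices, interpolation can be pinned (``lam_override``) for
verification, and the default protocol balances *inside* each training fold
only, so interpolated rows can never leak into a validation or test
partition.  A ``paper_protocol`` switch restores the alternative order
(balance the whole table first, then split) for faithful-reproduction runs.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from sklearn.base import BaseEstimator, ClassifierMixin
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import ParameterGrid, StratifiedKFold
from sklearn.neighbors import NearestNeighbors
from sklearn.pipeline import Pipeline
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from ._util import derive_seed
from .features import FEATURE_NAMES, feature_matrix, table_fingerprint

FAMILIES = ("knn", "rf", "svm")

#: Default hyperparameter grids (the appendix grids of the original study are
#: not public; these spans are conventional for the three families).
DEFAULT_GRIDS: dict[str, dict[str, list]] = {
    "knn": {"n_neighbors": [1, 3, 5, 11, 21]},
    "rf": {"n_estimators": [100, 300], "max_depth": [None, 10, 20]},
    "svm": {"C": [0.1, 1.0, 10.0], "gamma": ["scale", 0.01, 0.1]},
}


@dataclass(frozen=True)
class SmoteParams:
    """SMOTE settings: neighbourhood size and per-class target count.

    ``target_count=None`` balances every class up to the majority count.
    """

    k_neighbors: int = 5
    target_count: int | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.k_neighbors < 1:
            raise ValueError("k_neighbors must be >= 1")


@dataclass(frozen=True)
class SplitSpec:
    """Hold-out and cross-validation layout: 70/30 split, 5 folds."""

    test_fraction: float = 0.30
    folds: int = 5
    seed: int = 0

    def __post_init__(self) -> None:
        if not 0 < self.test_fraction < 1:
            raise ValueError("test_fraction must be in (0, 1)")
        if self.folds < 2:
            raise ValueError("folds must be >= 2")


def smote_balance(table: pd.DataFrame, params: SmoteParams,
                  lam_override: float | None = None) -> pd.DataFrame:
    """Oversample minority classes by nearest-neighbour interpolation.

    Each synthetic row is ``x_i + lam * (x_nn - x_i)`` with ``lam ~ U(0,1)``
    and ``x_nn`` one of the ``k`` nearest same-class neighbours of ``x_i``
    (Euclidean distance on z-scored features; interpolation itself is done in
    the original feature space, which is equivalent).  Original rows are
    preserved verbatim and come first; synthetic rows have ``synthetic=True``
    and their (base, neighbour) source indices are recorded in
    ``attrs['smote_parents']``.
    """
    if "label" not in table.columns:
        raise ValueError("table must be labeled")
    counts = table["label"].value_counts()
    if len(counts) < 2:
        raise ValueError("need at least two classes to balance")
    target = params.target_count if params.target_count is not None else int(counts.max())

    X = feature_matrix(table)
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    sd[sd == 0] = 1.0
    Z = (X - mu) / sd

    rng = np.random.default_rng(params.seed)
    new_rows: list[pd.DataFrame] = []
    parents: list[tuple[int, int]] = []
    for cls in sorted(counts.index):
        n = int(counts[cls])
        n_new = target - n
        if n_new <= 0:
            continue
        if n <= params.k_neighbors:
            raise ValueError(
                f"class {cls!r} has only {n} samples; needs more than "
                f"k_neighbors={params.k_neighbors} for SMOTE")
        idx = np.flatnonzero((table["label"] == cls).to_numpy())
        nn = NearestNeighbors(n_neighbors=params.k_neighbors + 1).fit(Z[idx])
        _, nbrs = nn.kneighbors(Z[idx])
        nbrs = nbrs[:, 1:]   # drop self
        base = rng.integers(0, n, size=n_new)
        pick = rng.integers(0, params.k_neighbors, size=n_new)
        lam = (np.full(n_new, float(lam_override)) if lam_override is not None
               else rng.random(n_new))
        xi = X[idx[base]]
        xn = X[idx[nbrs[base, pick]]]
        Xs = xi + lam[:, None] * (xn - xi)
        block = table.iloc[idx[base]].copy().reset_index(drop=True)
        block[FEATURE_NAMES] = Xs
        block["synthetic"] = True
        new_rows.append(block)
        parents.extend(zip(idx[base].tolist(),
                           idx[nbrs[base, pick]].tolist()))

    out = table.copy().reset_index(drop=True)
    if "synthetic" not in out.columns:
        out["synthetic"] = False
    if new_rows:
        out = pd.concat([out] + new_rows, ignore_index=True)
    out.attrs["schema_fingerprint"] = table.attrs.get("schema_fingerprint")
    out.attrs["smote_parents"] = parents
    return out


def stratified_split(table: pd.DataFrame, spec: SplitSpec
                     ) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Per-class random split into train/test at ``test_fraction``.

    Disjoint and exhaustive; each class's test share is within one sample of
    the requested fraction; reproducible from ``spec.seed``.
    """
    if "label" not in table.columns:
        raise ValueError("table must be labeled")
    rng = np.random.default_rng(spec.seed)
    test_idx: list[int] = []
    for cls in sorted(table["label"].unique()):
        idx = np.flatnonzero((table["label"] == cls).to_numpy())
        if len(idx) < 2:
            raise ValueError(f"class {cls!r} has fewer than 2 samples")
        n_test = int(round(len(idx) * spec.test_fraction))
        n_test = min(max(n_test, 1), len(idx) - 1)
        test_idx.extend(rng.permutation(idx)[:n_test].tolist())
    mask = np.zeros(len(table), dtype=bool)
    mask[test_idx] = True
    train = table.iloc[~mask].reset_index(drop=True)
    test = table.iloc[mask].reset_index(drop=True)
    for part in (train, test):
        part.attrs["schema_fingerprint"] = table.attrs.get("schema_fingerprint")
    return train, test


class TiebreakKNN(BaseEstimator, ClassifierMixin):
    """kNN majority vote with deterministic tie-breaking.

    Voting ties are resolved by the smallest mean neighbour distance among
    the tied classes, then by sorted class order.
    """

    def __init__(self, n_neighbors: int = 5):
        self.n_neighbors = n_neighbors

    def fit(self, X, y):
        X = np.asarray(X, dtype=np.float64)
        y = np.asarray(y)
        self.classes_ = np.unique(y)
        self._nn = NearestNeighbors(n_neighbors=self.n_neighbors).fit(X)
        self._y_idx = np.searchsorted(self.classes_, y)
        return self

    def predict(self, X):
        X = np.asarray(X, dtype=np.float64)
        dist, idx = self._nn.kneighbors(X)
        votes = self._y_idx[idx]                      # (n, k)
        n, C = len(X), len(self.classes_)
        counts = np.zeros((n, C), dtype=int)
        rows = np.repeat(np.arange(n), votes.shape[1])
        np.add.at(counts, (rows, votes.ravel()), 1)
        best = counts.max(axis=1)
        out = np.empty(n, dtype=int)
        for i in range(n):
            cand = np.flatnonzero(counts[i] == best[i])
            if len(cand) == 1:
                out[i] = cand[0]
            else:
                mean_d = [dist[i][votes[i] == c].mean() for c in cand]
                out[i] = cand[int(np.argmin(mean_d))]
        return self.classes_[out]


def make_estimator(family: str, hyperparameters: dict, seed: int = 0):
    """Build an unfitted sklearn estimator for one family.

    kNN and SVM are wrapped with feature standardization; forests operate on
    raw features.  Unknown hyperparameter names raise.
    """
    hp = dict(hyperparameters)
    if family == "knn":
        allowed = {"n_neighbors"}
        _check_hp(family, hp, allowed)
        return Pipeline([("scale", StandardScaler()),
                         ("clf", TiebreakKNN(**hp))])
    if family == "rf":
        allowed = {"n_estimators", "max_depth", "min_samples_leaf", "max_features"}
        _check_hp(family, hp, allowed)
        return RandomForestClassifier(random_state=seed, n_jobs=1, **hp)
    if family == "svm":
        allowed = {"C", "gamma"}
        _check_hp(family, hp, allowed)
        return Pipeline([("scale", StandardScaler()),
                         ("clf", SVC(kernel="rbf", random_state=seed, **hp))])
    raise ValueError(f"unknown family {family!r}; expected one of {FAMILIES}")


def _check_hp(family, hp, allowed):
    bad = set(hp) - allowed
    if bad:
        raise ValueError(f"invalid hyperparameters for {family}: {sorted(bad)}")


@dataclass
class TrainedModel:
    """A fitted classifier plus everything needed to apply it safely."""

    family: str
    hyperparameters: dict
    estimator: object
    schema_fingerprint: str
    classes: list[str]
    seed: int
    cv_summary: pd.DataFrame | None = None

    def predict(self, table: pd.DataFrame) -> np.ndarray:
        return predict(self, table)


def grid_search_cv(train_table: pd.DataFrame, family: str,
                   grid: dict[str, list] | None, spec: SplitSpec,
                   smote: SmoteParams | None = None,
                   balance: bool = True,
                   seed: int = 0) -> tuple[dict, pd.DataFrame]:
    """Exhaustive grid search under stratified k-fold cross-validation.

    Every grid point is scored on the same fold layout.  With ``balance``
    (default) the SMOTE step is fitted inside each training fold, so
    validation folds contain only measured rows.  The best point maximises
    mean CV accuracy; ties fall to higher mean macro sensitivity, then to
    grid order.  Returns the winning hyperparameters and a per-(point, fold)
    report.
    """
    from .evaluate import classification_metrics, confusion_matrix

    if grid is None:
        grid = DEFAULT_GRIDS[family]
    points = list(ParameterGrid(grid))
    if not points:
        raise ValueError("empty grid")
    if "label" not in train_table.columns:
        raise ValueError("training table must be labeled")
    # validate names early, against the family's signature
    make_estimator(family, points[0], seed)

    y = train_table["label"].to_numpy()
    classes = sorted(np.unique(y))
    skf = StratifiedKFold(n_splits=spec.folds, shuffle=True, random_state=spec.seed)
    folds = list(skf.split(np.zeros(len(y)), y))

    records = []
    for pi, point in enumerate(points):
        for fi, (tr_idx, va_idx) in enumerate(folds):
            tr = train_table.iloc[tr_idx].reset_index(drop=True)
            va = train_table.iloc[va_idx]
            if balance:
                sp = smote or SmoteParams()
                tr = smote_balance(
                    tr, SmoteParams(k_neighbors=sp.k_neighbors,
                                    target_count=sp.target_count,
                                    seed=derive_seed(sp.seed, f"fold{fi}")))
            est = make_estimator(family, point, derive_seed(seed, f"cv{pi}-{fi}"))
            est.fit(feature_matrix(tr), tr["label"].to_numpy())
            pred = est.predict(feature_matrix(va))
            rep = classification_metrics(
                confusion_matrix(va["label"].to_numpy(), pred, classes))
            records.append({"point": pi, "fold": fi, **point,
                            "accuracy": rep.accuracy,
                            "sensitivity": rep.macro_sensitivity,
                            "specificity": rep.macro_specificity})
    report = pd.DataFrame(records)
    agg = report.groupby("point")[["accuracy", "sensitivity"]].mean()
    order = sorted(agg.index,
                   key=lambda p: (-agg.loc[p, "accuracy"],
                                  -agg.loc[p, "sensitivity"], p))
    best = dict(points[order[0]])
    return best, report


def fit_classifier(table: pd.DataFrame, family: str, hyperparameters: dict,
                   seed: int = 0,
                   cv_summary: pd.DataFrame | None = None) -> TrainedModel:
    """Fit one classifier on the full (typically balanced) table."""
    if "label" not in table.columns:
        raise ValueError("table must be labeled")
    est = make_estimator(family, hyperparameters, seed)
    y = table["label"].to_numpy()
    est.fit(feature_matrix(table), y)
    return TrainedModel(family=family, hyperparameters=dict(hyperparameters),
                        estimator=est,
                        schema_fingerprint=table_fingerprint(table),
                        classes=sorted(np.unique(y)), seed=seed,
                        cv_summary=cv_summary)


def predict(model: TrainedModel, table: pd.DataFrame) -> np.ndarray:
    """Predict one label per row; refuses schema-mismatched tables."""
    fp = table_fingerprint(table)
    if fp != model.schema_fingerprint:
        raise ValueError(
            f"feature schema mismatch: table {fp} vs model {model.schema_fingerprint}")
    if len(table) == 0:
        return np.array([], dtype=object)
    return model.estimator.predict(feature_matrix(table))
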