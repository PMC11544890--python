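"""Scoring, subject-wise validation and composition comparison.

Covers four jobs: confusion-matrix metrics (accuracy plus one-vs-rest
sensitivity/specificity, macro-averaged without weights), leave-one-subject-
out validation (train on all animals but one, test on the held-out animal),
per-sample differential counts from predicted labels, and MAE/MRE/RMSE
comparison of a predicted composition time series against a reference-method
series.  Proportions in [0, 1] are the canonical scale throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Sequence

import numpy as np
import pandas as pd

from ._util import derive_seed


@dataclass
class ConfusionMatrix:
    classes: list
    counts: np.ndarray  # rows = true, cols = predicted

    @property
    def total(self) -> int:
        return int(self.counts.sum())


@dataclass
class MetricReport:
    accuracy: float
    sensitivity: dict
    specificity: dict
    macro_sensitivity: float
    macro_specificity: float
    support: dict

    def to_dict(self) -> dict:
        return {"accuracy": self.accuracy,
                "macro_sensitivity": self.macro_sensitivity,
                "macro_specificity": self.macro_specificity,
                "sensitivity": dict(self.sensitivity),
                "specificity": dict(self.specificity),
                "support": {k: int(v) for k, v in self.support.items()}}


def confusion_matrix(y_true: Sequence, y_pred: Sequence,
                     classes: Sequence) -> ConfusionMatrix:
    """Count matrix with rows = true class, columns = predicted class."""
    y_true = np.asarray(y_true)
    y_pred = np.asarray(y_pred)
    if y_true.shape != y_pred.shape:
        raise ValueError("label vectors must have equal length")
    classes = list(classes)
    index = {c: i for i, c in enumerate(classes)}
    counts = np.zeros((len(classes), len(classes)), dtype=np.int64)
    for t, p in zip(y_true, y_pred):
        if t not in index or p not in index:
            raise ValueError(f"label outside class set: {t!r}/{p!r}")
        counts[index[t], index[p]] += 1
    return ConfusionMatrix(classes=classes, counts=counts)


def classification_metrics(cm: ConfusionMatrix) -> MetricReport:
    """Accuracy and one-vs-rest sensitivity/specificity per class.

    Macro values are unweighted means; classes with zero support have
    undefined sensitivity and are excluded from the macro mean with a
    warning.
    """
    total = cm.total
    if total == 0:
        raise ValueError("empty confusion matrix")
    counts = cm.counts
    acc = float(np.trace(counts)) / total
    sens: dict = {}
    spec: dict = {}
    support: dict = {}
    for i, c in enumerate(cm.classes):
        tp = counts[i, i]
        fn = counts[i].sum() - tp
        fp = counts[:, i].sum() - tp
        tn = total - tp - fn - fp
        support[c] = int(tp + fn)
        if tp + fn > 0:
            sens[c] = float(tp) / (tp + fn)
        else:
            warnings.warn(f"class {c!r} has zero support; sensitivity undefined")
            sens[c] = np.nan
        spec[c] = float(tn) / (tn + fp) if (tn + fp) > 0 else np.nan
    valid = [v for v in sens.values() if not np.isnan(v)]
    macro_sens = float(np.mean(valid)) if valid else np.nan
    valid_sp = [v for v in spec.values() if not np.isnan(v)]
    macro_spec = float(np.mean(valid_sp)) if valid_sp else np.nan
    return MetricReport(accuracy=acc, sensitivity=sens, specificity=spec,
                        macro_sensitivity=macro_sens,
                        macro_specificity=macro_spec, support=support)


@dataclass
class LosoResult:
    """Per-held-out-subject metrics plus the mean (SD) summary."""

    per_subject: dict                      # subject -> MetricReport
    summary: dict                          # metric -> {"mean": .., "sd": ..}
    train_subjects: dict = field(default_factory=dict)  # fold -> training IDs

    def to_dict(self) -> dict:
        return {"per_subject": {s: r.to_dict() for s, r in self.per_subject.items()},
                "summary": self.summary,
                "train_subjects": {k: list(v)
                                   for k, v in self.train_subjects.items()}}


def leave_one_subject_out(table: pd.DataFrame, family: str,
                          hyperparameters: dict,
                          balance: bool = True,
                          smote=None,
                          seed: int = 0) -> LosoResult:
    """One fold per subject: train on the others, test on the held-out one.

    Training rows never share ``subject_id`` with test rows.  With
    ``balance`` the training portion is SMOTE-balanced per fold (synthetic
    rows stay on the training side by construction).  The summary reports
    mean and SD (sample SD for >1 fold) of accuracy and the macro metrics
    across folds — the natural reporting shape for a small animal cohort.
    """
    from .train import SmoteParams, fit_classifier, smote_balance

    subjects = sorted(table["subject_id"].unique())
    if len(subjects) < 2:
        raise ValueError("leave-one-subject-out needs at least 2 subjects")
    classes = sorted(table["label"].unique())
    per_subject: dict = {}
    train_subjects: dict = {}
    for si, subject in enumerate(subjects):
        test = table[table["subject_id"] == subject]
        train = table[table["subject_id"] != subject].reset_index(drop=True)
        train_subjects[subject] = sorted(train["subject_id"].unique())
        train.attrs["schema_fingerprint"] = table.attrs.get("schema_fingerprint")
        if balance:
            sp = smote or SmoteParams()
            train = smote_balance(
                train, SmoteParams(k_neighbors=sp.k_neighbors,
                                   target_count=sp.target_count,
                                   seed=derive_seed(seed, f"loso-{subject}")))
        model = fit_classifier(train, family, hyperparameters,
                               seed=derive_seed(seed, f"fit-{subject}"))
        pred = model.predict(test)
        per_subject[subject] = classification_metrics(
            confusion_matrix(test["label"].to_numpy(), pred, classes))
    summary = {}
    for name in ("accuracy", "macro_sensitivity", "macro_specificity"):
        vals = np.array([getattr(r, name) for r in per_subject.values()])
        sd = float(vals.std(ddof=1)) if len(vals) > 1 else 0.0
        summary[name] = {"mean": float(vals.mean()), "sd": sd}
    return LosoResult(per_subject=per_subject, summary=summary,
                      train_subjects=train_subjects)


def sample_composition(labels: Sequence, classes: Sequence | None = None
                       ) -> tuple[list, np.ndarray]:
    """Class proportions of one sample from its predicted labels."""
    labels = np.asarray(labels)
    if labels.size == 0:
        raise ValueError("cannot compute a composition from zero labels")
    if classes is None:
        classes = sorted(np.unique(labels))
    classes = list(classes)
    counts = np.array([(labels == c).sum() for c in classes], dtype=float)
    return classes, counts / labels.size


@dataclass
class CompositionSeries:
    """Per-day class proportions for one subject and matrix."""

    subject_id: str
    matrix: str
    days: list
    classes: list
    proportions: np.ndarray   # (n_days, n_classes)
    source: str = ""

    def __post_init__(self) -> None:
        self.proportions = np.asarray(self.proportions, dtype=float)
        if self.proportions.shape != (len(self.days), len(self.classes)):
            raise ValueError("proportions must be (n_days, n_classes)")
        if (self.proportions < -1e-12).any():
            raise ValueError("proportions must be non-negative")
        if np.abs(self.proportions.sum(axis=1) - 1.0).max() > 1e-9:
            raise ValueError("each day's proportions must sum to 1")

    def to_frame(self) -> pd.DataFrame:
        rows = [{"subject": self.subject_id, "day": d, "matrix": self.matrix,
                 "class": c, "proportion": self.proportions[i, j],
                 "source": self.source}
                for i, d in enumerate(self.days)
                for j, c in enumerate(self.classes)]
        return pd.DataFrame(rows)


@dataclass
class ComparisonReport:
    """MAE/MRE/RMSE between two composition series (or series sets)."""

    mae: float
    rmse: float
    mre: float
    mre_pairs_skipped: int
    per_class: dict                       # class -> {"mae","rmse","mre"}
    per_subject: dict = field(default_factory=dict)
    subject_summary: dict = field(default_factory=dict)

    def to_dict(self) -> dict:
        return {"mae": self.mae, "rmse": self.rmse, "mre": self.mre,
                "mre_pairs_skipped": self.mre_pairs_skipped,
                "per_class": self.per_class,
                "per_subject": self.per_subject,
                "subject_summary": self.subject_summary}


def _errors(t: np.ndarray, r: np.ndarray) -> tuple[float, float, float, int]:
    d = np.abs(t - r)
    mae = float(d.mean())
    rmse = float(np.sqrt((d**2).mean()))
    nz = r > 0
    skipped = int((~nz).sum())
    mre = float((d[nz] / r[nz]).mean()) if nz.any() else np.nan
    return mae, rmse, mre, skipped


def compare_series(test: CompositionSeries | Sequence[CompositionSeries],
                   reference: CompositionSeries | Sequence[CompositionSeries],
                   ) -> ComparisonReport:
    """Pool errors over aligned (day, class) pairs.

    MAE and RMSE use every pair; MRE averages ``|t - r| / r`` over pairs with
    a non-zero reference (zero-reference pairs are skipped and counted).  Per-
    class entries restrict to that class's column.  Given matching lists of
    series, per-subject errors and their across-subject mean/SD are added.
    """
    tests = [test] if isinstance(test, CompositionSeries) else list(test)
    refs = ([reference] if isinstance(reference, CompositionSeries)
            else list(reference))
    ref_by_key = {(r.subject_id, r.matrix): r for r in refs}
    pairs = []
    for t in tests:
        key = (t.subject_id, t.matrix)
        if key not in ref_by_key:
            raise ValueError(f"no reference series for {key}")
        r = ref_by_key[key]
        if list(t.days) != list(r.days) or list(t.classes) != list(r.classes):
            raise ValueError(f"misaligned days/classes for {key}")
        pairs.append((t, r))

    T = np.vstack([t.proportions for t, _ in pairs])
    R = np.vstack([r.proportions for _, r in pairs])
    mae, rmse, mre, skipped = _errors(T, R)
    classes = pairs[0][0].classes
    per_class = {}
    for j, c in enumerate(classes):
        cm, cr, cmre, _ = _errors(T[:, j], R[:, j])
        per_class[c] = {"mae": cm, "rmse": cr, "mre": cmre}

    per_subject: dict = {}
    subject_summary: dict = {}
    if len(pairs) > 1:
        for t, r in pairs:
            sm, sr, smre, _ = _errors(t.proportions, r.proportions)
            per_subject[t.subject_id] = {"mae": sm, "rmse": sr, "mre": smre}
        for name in ("mae", "rmse", "mre"):
            vals = np.array([v[name] for v in per_subject.values()])
            vals = vals[~np.isnan(vals)]
            if vals.size:
                sd = float(vals.std(ddof=1)) if vals.size > 1 else 0.0
                subject_summary[name] = {"mean": float(vals.mean()), "sd": sd}
    return ComparisonReport(mae=mae, rmse=rmse, mre=mre,
                            mre_pairs_skipped=skipped, per_class=per_class,
                            per_subject=per_subject,
                            subject_summary=subject_summary)


def feature_shift_report(table: pd.DataFrame, split_day: int) -> pd.DataFrame:
    """Descriptive before/after comparison of feature distributions.

    For each feature: mean and SD before and after ``split_day`` plus the
    standardized mean difference (Cohen's d with pooled SD).  Purely
    descriptive — mirrors a visual KDE-overlay assessment; no hypothesis test
    is attached.
    """
    from .features import FEATURE_NAMES

    before = table[table["day"] <= split_day]
    after = table[table["day"] > split_day]
    if len(before) == 0 or len(after) == 0:
        raise ValueError("both periods need rows")
    rows = []
    for name in FEATURE_NAMES:
        b = before[name].to_numpy(dtype=float)
        a = after[name].to_numpy(dtype=float)
        pooled = np.sqrt((b.var(ddof=1) + a.var(ddof=1)) / 2.0)
        d = (a.mean() - b.mean()) / pooled if pooled > 0 else 0.0
        rows.append({"feature": name, "mean_before": b.mean(), "sd_before": b.std(ddof=1),
                     "mean_after": a.mean(), "sd_after": a.std(ddof=1),
                     "cohens_d": d})
    return pd.DataFrame(rows)
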