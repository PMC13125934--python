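"""Multimodal decoding: feature assembly, LOOCV, accuracy/ROC/kappa.

Feature vectors combine rating means with LPP amplitudes (picture task) or
HRV indices (narrative task).  Features enter the classifiers on their
original scale — no standardisation — which is a deliberate, documented
caveat for the distance-based families (KNN, SVM).  Five classifier
families are supported: logistic regression (LR), k-nearest neighbours
(KNN), random forest (RF), RBF support vector machine (SVM) and Gaussian
naive Bayes (NB).  Cross-validation is leave-one-row-out by default, with a
leave-one-participant-out option guarding against within-participant row
correlation.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.special import expit, softmax
from sklearn.exceptions import ConvergenceWarning
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import roc_curve, auc as sk_auc
from sklearn.naive_bayes import GaussianNB
from sklearn.neighbors import KNeighborsClassifier
from sklearn.svm import SVC

from .errors import InsufficientDataError, ValidationError
from .hrv import HRV_FIELDS

log = logging.getLogger(__name__)

FAMILIES = ("LR", "KNN", "RF", "SVM", "NB")
STUDY2_FAMILIES = ("LR", "RF", "NB")


@dataclass
class FeatureMatrix:
    features: pd.DataFrame      # rows = samples, columns = named features
    labels: np.ndarray          # class per row
    group_ids: np.ndarray       # participant identifiers
    n_dropped: int = 0          # rows removed for missingness

    def __post_init__(self) -> None:
        self.labels = np.asarray(self.labels)
        self.group_ids = np.asarray(self.group_ids)
        if not (len(self.features) == len(self.labels) == len(self.group_ids)):
            raise ValidationError("feature/label/group lengths differ")
        if self.features.isna().any().any():
            raise ValidationError("feature matrix contains missing values")

    @property
    def n_samples(self) -> int:
        return len(self.features)

    @property
    def classes(self) -> np.ndarray:
        return np.unique(self.labels)


@dataclass
class ClassifierSpec:
    family: str = "LR"
    hyperparameters: dict = field(default_factory=dict)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.family not in FAMILIES:
            raise ValidationError(f"unknown classifier family {self.family!r}")

    def build(self, n_classes: int | None = None):
        """Instantiate the sklearn estimator.

        Class priors are balanced (``class_weight="balanced"``; uniform
        priors for NB, hence ``n_classes``): under leave-one-out the
        training fold is always short exactly one sample of the held-out
        class, and prior-sensitive classifiers would otherwise be biased
        against it — visibly below chance on informationless data.
        """
        hp = dict(self.hyperparameters)
        if self.family == "LR":
            # mild ridge penalty; iterations bounded because features enter
            # unscaled (documented caveat), which slows lbfgs convergence
            return LogisticRegression(
                C=hp.pop("C", 1.0), max_iter=hp.pop("max_iter", 300),
                class_weight=hp.pop("class_weight", "balanced"), **hp
            )
        if self.family == "KNN":
            return KNeighborsClassifier(n_neighbors=hp.pop("n_neighbors", 5), **hp)
        if self.family == "RF":
            return RandomForestClassifier(
                n_estimators=hp.pop("n_estimators", 300),
                random_state=self.seed,
                class_weight=hp.pop("class_weight", "balanced"),
                **hp,
            )
        if self.family == "SVM":
            return SVC(kernel=hp.pop("kernel", "rbf"),
                       class_weight=hp.pop("class_weight", "balanced"), **hp)
        if "priors" not in hp and n_classes is not None:
            hp["priors"] = np.full(n_classes, 1.0 / n_classes)
        return GaussianNB(**hp)


@dataclass
class DecodeReport:
    family: str
    predictions: np.ndarray      # per-fold held-out predictions
    scores: np.ndarray           # n_samples x n_classes class scores
    truth: np.ndarray
    classes: np.ndarray
    accuracy: float              # %
    kappa: float
    confusion: np.ndarray
    roc: dict                    # per-class curves + macro area
    skipped_folds: int = 0

    def summary_row(self) -> dict:
        return {
            "family": self.family,
            "accuracy_pct": self.accuracy,
            "kappa": self.kappa,
            "macro_auc": self.roc.get("macro_auc", np.nan),
        }


# ----------------------------------------------------------- feature assembly

def _rating_means(ratings: pd.DataFrame, keys: list[str]) -> pd.DataFrame:
    return (
        ratings.groupby(keys + ["scale"], sort=True)["value"]
        .mean()
        .unstack("scale")
        .add_prefix("rating_")
        .reset_index()
    )


def assemble_features_study1(
    ratings: pd.DataFrame,
    lpp: pd.DataFrame,
    tdcs_target: str | None = None,
    tdcs_type: str | None = None,
    task: str | None = None,
) -> FeatureMatrix:
    """Rows = participant x stimulation-type cells, pooled over the selected
    design cells; columns = mean self/other ratings + early/late LPP.

    Optional filters restrict to one tDCS target, tDCS type and/or task
    (the decoding analyses compare such restricted matrices).
    """
    r, l = ratings.copy(), lpp.copy()
    for col, val in (("tdcs_target", tdcs_target), ("tdcs_type", tdcs_type),
                     ("task", task)):
        if val is not None:
            r, l = r[r[col] == val], l[l[col] == val]
    keys = ["participant", "stim_type"]
    rating_feats = _rating_means(r, keys)
    if "flag" in l.columns:
        l = l[l["flag"] == "ok"]
    lpp_feats = (
        l.groupby(keys, sort=True)[["early_lpp", "late_lpp"]]
        .mean()
        .reset_index()
    )
    merged = rating_feats.merge(lpp_feats, on=keys, how="inner").dropna()
    n_dropped = max(len(rating_feats), len(lpp_feats)) - len(merged)
    if n_dropped:
        log.info("assemble_features_study1: dropped %d unmatched cells", n_dropped)
    if merged.empty:
        raise InsufficientDataError("no matched rating/LPP cells")
    feat_cols = ["rating_self", "rating_other", "early_lpp", "late_lpp"]
    return FeatureMatrix(
        features=merged[feat_cols].reset_index(drop=True),
        labels=merged["stim_type"].to_numpy(),
        group_ids=merged["participant"].to_numpy(),
        n_dropped=n_dropped,
    )


def assemble_features_study2(
    ratings: pd.DataFrame,
    hrv: pd.DataFrame,
    time: str,
    group: str | None = None,
) -> FeatureMatrix:
    """Rows = participant x valence at one time point; columns = the four
    rating means plus the HRV indices.  Rows with any missing HRV field are
    dropped and counted."""
    if time not in ("pre", "post"):
        raise ValidationError("time must be 'pre' or 'post'")
    r = ratings[ratings["time"] == time].copy()
    h = hrv[hrv["time"] == time].copy()
    if group is not None:
        r, h = r[r["group"] == group], h[h["group"] == group]
    keys = ["participant", "valence"]
    rating_feats = _rating_means(r, keys)
    hrv_cols = [c for c in HRV_FIELDS if c in h.columns]
    hrv_feats = h.groupby(keys, sort=True)[hrv_cols].mean().reset_index()
    merged = rating_feats.merge(hrv_feats, on=keys, how="inner")
    before = len(merged)
    merged = merged.dropna()
    n_dropped = before - len(merged)
    if n_dropped:
        log.info("assemble_features_study2: dropped %d rows with missingness",
                 n_dropped)
    if merged.empty:
        raise InsufficientDataError("no matched rating/HRV cells")
    feat_cols = [c for c in merged.columns if c not in keys]
    return FeatureMatrix(
        features=merged[feat_cols].reset_index(drop=True),
        labels=merged["valence"].to_numpy(),
        group_ids=merged["participant"].to_numpy(),
        n_dropped=n_dropped,
    )


# ------------------------------------------------------------------- metrics

def cohens_kappa(confusion: np.ndarray) -> float:
    """Chance-corrected agreement κ = (p_o − p_e) / (1 − p_e)."""
    c = np.asarray(confusion, dtype=float)
    if c.ndim != 2 or c.shape[0] != c.shape[1]:
        raise ValidationError("confusion matrix must be square")
    if np.any(c < 0) or c.sum() <= 0:
        raise ValidationError("confusion counts must be >= 0 with positive total")
    total = c.sum()
    p_o = np.trace(c) / total
    p_e = float(np.sum(c.sum(axis=1) * c.sum(axis=0)) / total**2)
    if np.isclose(p_e, 1.0):
        log.warning("cohens_kappa: p_e = 1 (degenerate margins); returning 0")
        return 0.0
    return float((p_o - p_e) / (1.0 - p_e))


def roc_multiclass(scores: np.ndarray, labels: np.ndarray,
                   classes: np.ndarray) -> dict:
    """One-vs-rest ROC per class plus the macro-average area.

    Classes without both a positive and a negative sample are skipped and
    noted.  In the binary case the macro average equals the standard single
    curve's area by symmetry.
    """
    scores = np.asarray(scores, dtype=float)
    out = {"per_class": {}, "skipped": []}
    areas = []
    for k, cls in enumerate(classes):
        y = (np.asarray(labels) == cls).astype(int)
        if y.min() == y.max():
            out["skipped"].append(str(cls))
            continue
        fpr, tpr, thr = roc_curve(y, scores[:, k])
        area = sk_auc(fpr, tpr)
        out["per_class"][str(cls)] = {
            "fpr": fpr.tolist(), "tpr": tpr.tolist(), "auc": float(area)
        }
        areas.append(area)
    out["macro_auc"] = float(np.mean(areas)) if areas else np.nan
    return out


# -------------------------------------------------------------------- LOOCV

def _class_scores(model, X: np.ndarray, classes: np.ndarray) -> np.ndarray:
    """Per-class scores aligned to ``classes`` (probability-like)."""
    if hasattr(model, "predict_proba"):
        proba = model.predict_proba(X)
        model_classes = model.classes_
    else:  # SVC without probability: monotone transform of decision values
        dec = model.decision_function(X)
        model_classes = model.classes_
        if dec.ndim == 1:  # binary: decision > 0 favours classes_[1]
            p1 = expit(dec)
            proba = np.column_stack([1 - p1, p1])
        else:
            proba = softmax(dec, axis=1)
    aligned = np.zeros((len(X), len(classes)))
    for j, cls in enumerate(model_classes):
        aligned[:, np.where(classes == cls)[0][0]] = proba[:, j]
    return aligned


def loocv(
    features: FeatureMatrix,
    spec: ClassifierSpec,
    by_participant: bool = False,
) -> DecodeReport:
    """Leave-one-out cross-validation: every sample is predicted exactly once
    by a model that never saw it.

    ``by_participant=True`` holds out all of a participant's rows together
    (leave-one-participant-out).  Folds whose training set lacks a class are
    flagged, excluded from the ROC, and counted.
    """
    X = features.features.to_numpy(dtype=float)
    y = features.labels
    classes = features.classes
    counts = pd.Series(y).value_counts()
    if (counts < 2).any():
        raise InsufficientDataError("need >= 2 samples per class for LOOCV")

    if by_participant:
        units = np.unique(features.group_ids)
        folds = [np.where(features.group_ids == u)[0] for u in units]
    else:
        folds = [np.array([i]) for i in range(len(y))]

    preds = np.empty(len(y), dtype=object)
    scores = np.full((len(y), len(classes)), np.nan)
    valid = np.ones(len(y), dtype=bool)
    skipped = 0
    for test_idx in folds:
        train = np.setdiff1d(np.arange(len(y)), test_idx)
        if len(np.unique(y[train])) < len(classes):
            valid[test_idx] = False
            skipped += 1
            preds[test_idx] = "__skipped__"
            continue
        model = spec.build(n_classes=len(classes))
        with warnings.catch_warnings():
            warnings.simplefilter("ignore", ConvergenceWarning)
            model.fit(X[train], y[train])
        preds[test_idx] = model.predict(X[test_idx])
        scores[test_idx] = _class_scores(model, X[test_idx], classes)

    ok = valid
    truth = y[ok]
    pred = preds[ok].astype(truth.dtype)
    confusion = np.zeros((len(classes), len(classes)), dtype=int)
    cls_index = {c: i for i, c in enumerate(classes)}
    for t, p in zip(truth, pred):
        confusion[cls_index[t], cls_index[p]] += 1
    accuracy = 100.0 * float(np.mean(pred == truth))
    kappa = cohens_kappa(confusion)
    roc = roc_multiclass(scores[ok], truth, classes)
    return DecodeReport(
        family=spec.family,
        predictions=pred,
        scores=scores[ok],
        truth=truth,
        classes=classes,
        accuracy=accuracy,
        kappa=kappa,
        confusion=confusion,
        roc=roc,
        skipped_folds=skipped,
    )


def run_families(
    features: FeatureMatrix,
    families: tuple[str, ...] = FAMILIES,
    seed: int = 0,
    hyperparameters: dict | None = None,
    by_participant: bool = False,
) -> list[DecodeReport]:
    """Run LOOCV for each named family on the same feature matrix."""
    hyperparameters = hyperparameters or {}
    return [
        loocv(
            features,
            ClassifierSpec(family=f, seed=seed,
                           hyperparameters=hyperparameters.get(f, {})),
            by_participant=by_participant,
        )
        for f in families
    ]


def ensemble_summary(reports: list[DecodeReport],
                     families: tuple[str, ...] | None = None) -> dict:
    """Mean accuracy/kappa/macro-area over an explicit family subset."""
    if families is not None and len(families) == 0:
        raise ValidationError("family subset must be non-empty")
    chosen = [r for r in reports
              if families is None or r.family in set(families)]
    if not chosen:
        raise ValidationError("no reports match the requested families")
    return {
        "families": [r.family for r in chosen],
        "mean_accuracy_pct": float(np.mean([r.accuracy for r in chosen])),
        "mean_kappa": float(np.mean([r.kappa for r in chosen])),
        "mean_macro_auc": float(
            np.nanmean([r.roc.get("macro_auc", np.nan) for r in chosen])
        ),
    }
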