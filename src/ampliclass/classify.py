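"""Random-forest sample classification with repeated cross-validated ROC/AUC.

Samples are classified from their taxa relative-abundance profiles (all ranks
simultaneously, no feature selection).  Performance is summarized by repeated
stratified k-fold cross-validation: each repeat shuffles the samples, holds
out each fold in turn, scores held-out samples with the fraction of forest
trees voting for the positive class, and computes the AUC from the pooled
out-of-fold scores; the reported AUC is the median over repeats (default 3
repeats of 10-fold).

The ROC sweep and AUC are computed by hand with the Mann-Whitney tie
convention (a tied positive/negative pair counts one half), so AUC always
equals U / (n+ * n-); tests cross-check this against brute-force pair
counting and scikit-learn.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass
from pathlib import Path
from typing import Callable, Sequence

import numpy as np
import pandas as pd
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.inspection import permutation_importance
from sklearn.model_selection import StratifiedKFold, KFold, train_test_split

from .abundance import AbundanceTable, normalize

logger = logging.getLogger(__name__)


def _make_random_forest(spec: "ClassifierSpec", seed: int):
    return RandomForestClassifier(
        n_estimators=spec.n_trees,
        max_features=spec.max_features,
        random_state=seed,
    )


#: pluggable learner registry: kind -> factory(spec, seed) -> fitted-like estimator
LEARNERS: dict[str, Callable] = {"random_forest": _make_random_forest}


@dataclass
class ClassifierSpec:
    """Learner configuration.

    Defaults: a 500-tree random forest with sqrt(#features) candidate
    features per split, no class weighting.  ``positive_class`` names the
    label whose vote fraction is the sample score.
    """

    learner: str = "random_forest"
    n_trees: int = 500
    max_features: str | int | float = "sqrt"
    positive_class: str | None = None
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_trees < 1:
            raise ValueError("n_trees must be >= 1")
        if self.learner not in LEARNERS:
            raise ValueError(f"unknown learner {self.learner!r}; "
                             f"registered: {sorted(LEARNERS)}")

    def build(self, seed: int | None = None):
        return LEARNERS[self.learner](self, self.seed if seed is None else seed)


@dataclass
class CvEvaluation:
    """Out-of-fold scores, ROC and AUC from repeated k-fold cross-validation."""

    scores: pd.DataFrame            # samples x repeats, out-of-fold scores
    folds: pd.DataFrame             # samples x repeats, test-fold index
    labels: pd.Series
    positive_class: str
    aucs: list[float]               # one per repeat
    roc: pd.DataFrame               # ROC of the median-AUC repeat

    @property
    def auc_median(self) -> float:
        return float(np.median(self.aucs))


def positive_vote_fraction(forest: RandomForestClassifier, X: np.ndarray,
                           positive) -> np.ndarray:
    """Fraction of trees whose predicted class is the positive class."""
    classes = list(forest.classes_)
    pos_code = classes.index(positive)
    votes = np.stack([est.predict(X) for est in forest.estimators_])
    return (votes == pos_code).mean(axis=0)


def _score_samples(model, X: np.ndarray, positive) -> np.ndarray:
    if isinstance(model, RandomForestClassifier):
        return positive_vote_fraction(model, X, positive)
    proba = model.predict_proba(X)
    return proba[:, list(model.classes_).index(positive)]


def _features_matrix(table: AbundanceTable) -> tuple[np.ndarray, list[str]]:
    if table.frequencies is None:
        table = normalize(table)
    F = table.frequencies
    return F.T.to_numpy(dtype=float), list(F.index)


def roc_and_auc(scores, labels, positive) -> tuple[pd.DataFrame, float]:
    """ROC points and AUC from continuous scores.

    Thresholds sweep the unique scores from high to low (predict positive
    when score >= threshold).  AUC uses the rank (Mann-Whitney) formula, so a
    tied positive/negative pair contributes one half; this equals the
    trapezoidal area under the swept ROC.
    """
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pos = y == positive
    n_pos, n_neg = int(pos.sum()), int((~pos).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("both classes must be present to compute a ROC")
    order = np.argsort(-s, kind="mergesort")
    s_sorted, pos_sorted = s[order], pos[order]
    thresholds, tps, fps = [], [], []
    tp = fp = 0
    i = 0
    while i < len(s_sorted):
        j = i
        while j < len(s_sorted) and s_sorted[j] == s_sorted[i]:
            tp += pos_sorted[j]
            fp += not pos_sorted[j]
            j += 1
        thresholds.append(s_sorted[i])
        tps.append(tp)
        fps.append(fp)
        i = j
    roc = pd.DataFrame({
        "threshold": [np.inf] + thresholds,
        "fpr": np.concatenate([[0.0], np.asarray(fps) / n_neg]),
        "tpr": np.concatenate([[0.0], np.asarray(tps) / n_pos]),
    })
    ranks = rankdata(s)                      # mid-ranks
    u = ranks[pos].sum() - n_pos * (n_pos + 1) / 2
    auc = float(u / (n_pos * n_neg))
    return roc, auc


def choose_operating_point(roc: pd.DataFrame, target_sensitivity: float
                           ) -> tuple[float, float, float]:
    """Smallest-sensitivity ROC point with sensitivity >= target.

    Ties are broken toward maximal specificity.  Returns
    ``(threshold, sensitivity, specificity)``; a target above the achievable
    maximum falls back to the all-positive endpoint with a warning.
    """
    if roc.empty:
        raise ValueError("empty ROC")
    ok = roc[roc["tpr"] >= target_sensitivity]
    if ok.empty:
        warnings.warn("target sensitivity unachievable; returning the "
                      "all-positive endpoint")
        ok = roc[roc["tpr"] == roc["tpr"].max()]
    best_tpr = ok["tpr"].min()
    cand = ok[ok["tpr"] == best_tpr]
    row = cand.loc[cand["fpr"].idxmin()]
    return float(row["threshold"]), float(row["tpr"]), float(1.0 - row["fpr"])


def confusion_at(scores, labels, threshold, positive) -> dict:
    """2x2 confusion matrix predicting positive when score >= threshold."""
    s = np.asarray(scores, dtype=float)
    y = np.asarray(labels)
    pred_pos = s >= threshold
    pos = y == positive
    tp = int((pred_pos & pos).sum())
    fp = int((pred_pos & ~pos).sum())
    fn = int((~pred_pos & pos).sum())
    tn = int((~pred_pos & ~pos).sum())
    return {
        "TP": tp, "FP": fp, "FN": fn, "TN": tn,
        "sensitivity": tp / (tp + fn) if tp + fn else float("nan"),
        "specificity": tn / (tn + fp) if tn + fp else float("nan"),
    }


def cross_validate(
    table: AbundanceTable,
    label_field: str,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    repeats: int = 3,
    stratified: bool = True,
    seed: int = 0,
) -> CvEvaluation:
    """Repeated stratified k-fold cross-validation of the sample classifier.

    Each repeat derives its own random stream from the master seed (repeat r
    is reproducible in isolation).  Folds are stratified by class unless
    ``stratified=False`` (plain random 1/k holdouts, which can lose a class
    from a training split on small cohorts).
    """
    spec = spec or ClassifierSpec()
    X, _ = _features_matrix(table)
    y = table.metadata[label_field].astype(str)
    classes = sorted(y.unique())
    if len(classes) < 2:
        raise ValueError("need at least two classes")
    positive = spec.positive_class or classes[-1]
    if positive not in classes:
        raise ValueError(f"positive class {positive!r} not among labels {classes}")
    counts = y.value_counts()
    if stratified and counts.min() < k:
        raise ValueError(
            f"stratified {k}-fold CV needs >= {k} samples per class; "
            f"smallest class {counts.idxmin()!r} has {counts.min()}. "
            f"Reduce k or use stratified=False.")

    scores = pd.DataFrame(index=table.samples,
                          columns=[f"repeat_{r}" for r in range(repeats)], dtype=float)
    folds = scores.copy()
    aucs, rocs = [], []
    yv = y.to_numpy()
    for r in range(repeats):
        rep_seed = np.random.SeedSequence(entropy=seed, spawn_key=(r,)).generate_state(1)[0] % (2**31)
        splitter = (StratifiedKFold(k, shuffle=True, random_state=rep_seed)
                    if stratified else KFold(k, shuffle=True, random_state=rep_seed))
        for fold_i, (train_idx, test_idx) in enumerate(splitter.split(X, yv)):
            if len(np.unique(yv[train_idx])) < len(classes):
                raise ValueError(
                    f"class missing from the training split of fold {fold_i} "
                    f"(repeat {r}); use stratified folds or reduce k")
            model = spec.build(seed=int(rep_seed) + fold_i)
            model.fit(X[train_idx], yv[train_idx])
            scores.iloc[test_idx, r] = _score_samples(model, X[test_idx], positive)
            folds.iloc[test_idx, r] = fold_i
        roc, auc = roc_and_auc(scores.iloc[:, r].to_numpy(), yv, positive)
        aucs.append(auc)
        rocs.append(roc)
    med_idx = int(np.argsort(aucs)[len(aucs) // 2])
    return CvEvaluation(scores=scores, folds=folds, labels=y,
                        positive_class=positive, aucs=aucs, roc=rocs[med_idx])


def feature_importance(
    table: AbundanceTable,
    label_field: str,
    spec: ClassifierSpec | None = None,
    n_repeats: int = 5,
    test_size: float = 0.3,
    seed: int = 0,
) -> pd.DataFrame:
    """Permutation feature importance: held-out accuracy drop per feature.

    A forest is trained on a stratified subset and each feature column of the
    held-out samples is permuted ``n_repeats`` times; the importance is the
    mean decrease in held-out accuracy.  Returns features with columns
    ``importance`` (mean decrease), ``importance_sd`` and ``rank`` (1 = most
    important), sorted by rank.
    """
    spec = spec or ClassifierSpec()
    X, names = _features_matrix(table)
    y = table.metadata[label_field].astype(str).to_numpy()
    X_tr, X_te, y_tr, y_te = train_test_split(
        X, y, test_size=test_size, stratify=y, random_state=seed)
    model = spec.build(seed=seed)
    model.fit(X_tr, y_tr)
    res = permutation_importance(model, X_te, y_te, scoring="accuracy",
                                 n_repeats=n_repeats, random_state=seed)
    out = pd.DataFrame({
        "feature": names,
        "importance": res.importances_mean,
        "importance_sd": res.importances_std,
    }).set_index("feature").sort_values("importance", ascending=False)
    out["rank"] = np.arange(1, len(out) + 1)
    return out


@dataclass
class TransferResult:
    """Evaluation of a model trained on one cohort and scored on another."""

    scores: pd.Series
    roc: pd.DataFrame
    auc: float
    shared_features: list[str]
    train_only: list[str]
    test_only: list[str]
    confusion: dict | None = None


def transfer_classify(
    train_table: AbundanceTable,
    train_label_field: str,
    test_table: AbundanceTable,
    test_label_field: str | None = None,
    spec: ClassifierSpec | None = None,
    threshold: float | None = None,
) -> TransferResult:
    """Train on one cohort and score another, on the shared feature set.

    Feature names are matched after rank qualification; features absent from
    the test cohort are filled with zero frequency (with a warning).  An
    empty intersection is an error listing both name sets.
    """
    spec = spec or ClassifierSpec()
    test_label_field = test_label_field or train_label_field
    if train_table.frequencies is None:
        train_table = normalize(train_table)
    if test_table.frequencies is None:
        test_table = normalize(test_table)
    train_feats = list(train_table.frequencies.index)
    test_feats = set(test_table.frequencies.index)
    shared = [f for f in train_feats if f in test_feats]
    if not shared:
        raise ValueError(
            "no shared features between cohorts.\n"
            f"  training features: {sorted(train_feats)}\n"
            f"  test features:     {sorted(test_feats)}")
    train_only = [f for f in train_feats if f not in test_feats]
    test_only = sorted(test_feats - set(train_feats))
    if train_only:
        warnings.warn(f"{len(train_only)} training features absent from the "
                      "test cohort; filled with zero frequency")

    X_train = train_table.frequencies.loc[train_feats].T.to_numpy(dtype=float)
    y_train = train_table.metadata[train_label_field].astype(str).to_numpy()
    X_test = (test_table.frequencies.reindex(train_feats, fill_value=0.0)
              .T.to_numpy(dtype=float))
    y_test = test_table.metadata[test_label_field].astype(str)

    classes = sorted(np.unique(y_train))
    positive = spec.positive_class or classes[-1]
    model = spec.build()
    model.fit(X_train, y_train)
    s = _score_samples(model, X_test, positive)
    roc, auc = roc_and_auc(s, y_test.to_numpy(), positive)
    conf = (confusion_at(s, y_test.to_numpy(), threshold, positive)
            if threshold is not None else None)
    return TransferResult(
        scores=pd.Series(s, index=test_table.samples, name="score"),
        roc=roc, auc=auc, shared_features=shared,
        train_only=train_only, test_only=test_only, confusion=conf)


def save_model(model, feature_names: Sequence[str], path: str | Path,
               positive_class: str | None = None) -> None:
    """Persist a fitted model with a feature-name manifest.

    Writes ``<path>`` (joblib archive) and ``<path>.manifest.json`` recording
    package version, feature order and the positive class.  Transfer to a new
    cohort needs the manifest to align feature columns.
    """
    import json

    import joblib

    from . import __version__

    path = Path(path)
    joblib.dump(model, path)
    manifest = {"package": "ampliclass", "version": __version__,
                "features": list(feature_names),
                "positive_class": positive_class}
    path.with_suffix(path.suffix + ".manifest.json").write_text(
        json.dumps(manifest, indent=2))


def load_model(path: str | Path):
    """Load a saved model and its manifest; returns ``(model, manifest)``."""
    import json

    import joblib

    path = Path(path)
    manifest = json.loads(
        path.with_suffix(path.suffix + ".manifest.json").read_text())
    return joblib.load(path), manifest


def one_vs_rest_rocs(
    table: AbundanceTable,
    label_field: str,
    spec: ClassifierSpec | None = None,
    k: int = 10,
    repeats: int = 3,
    seed: int = 0,
) -> dict[str, CvEvaluation]:
    """One ROC per class: each class cross-validated against all others."""
    from dataclasses import replace as dc_replace

    spec = spec or ClassifierSpec()
    y = table.metadata[label_field].astype(str)
    out = {}
    for cls in sorted(y.unique()):
        meta = table.metadata.copy()
        meta["_ovr"] = np.where(y == cls, cls, "rest")
        tab = dc_replace(table, metadata=meta)
        ovr_spec = dc_replace(spec, positive_class=cls)
        out[cls] = cross_validate(tab, "_ovr", ovr_spec, k=k, repeats=repeats, seed=seed)
    return out
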