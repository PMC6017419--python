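"""Classification and evaluation of RPI feature matrices.

Two classifiers are supported with fixed reference hyperparameters:
an RBF-kernel SVM (C = 2^5, gamma = 2^-7 for string-model features;
C = 2^7, gamma = 2^-11 for the 124-dim feature-based descriptors) and a
random forest of 200 trees.  Evaluation is stratified k-fold
cross-validation (10 folds by default) with confusion counts pooled over
folds and the rank-based (Mann-Whitney) AUC computed on the pooled
continuous scores; per-fold reports and the fold-mean AUC are returned
alongside since pooling conventions differ between studies.

Metric definitions (zero denominators reported as 0 with a flag):

    PRE = TP/(TP+FP)   REC = TP/(TP+FN)
    ACC = (TP+TN)/(TP+TN+FP+FN)   FSC = 2*PRE*REC/(PRE+REC)
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.stats import rankdata
from sklearn.ensemble import RandomForestClassifier
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

from .errors import ConfigError, LabelError

#: reference SVM hyperparameters per feature family
SVM_PARAMS_STRING = {"C": 2.0 ** 5, "gamma": 2.0 ** -7}
SVM_PARAMS_FEATURE = {"C": 2.0 ** 7, "gamma": 2.0 ** -11}
RF_N_TREES = 200


@dataclass(frozen=True)
class ModelConfig:
    classifier: str = "svm_rbf"  # or "random_forest"
    C: float = SVM_PARAMS_STRING["C"]
    gamma_svm: float = SVM_PARAMS_STRING["gamma"]  # kernel width, not a k-mer count
    rf_n_trees: int = RF_N_TREES
    cv_folds: int = 10
    random_seed: int = 0

    def __post_init__(self):
        if self.classifier not in ("svm_rbf", "random_forest"):
            raise ConfigError(f"unknown classifier {self.classifier!r}")
        if self.C <= 0 or self.gamma_svm <= 0:
            raise ConfigError("C and gamma_svm must be positive")
        if self.rf_n_trees < 1:
            raise ConfigError("rf_n_trees must be >= 1")
        if self.cv_folds < 2:
            raise ConfigError("cv_folds must be >= 2")

    @classmethod
    def for_string_model(cls, classifier: str = "svm_rbf", **kw) -> "ModelConfig":
        return cls(classifier=classifier, **{**SVM_PARAMS_STRING_KW, **kw})

    @classmethod
    def for_feature_model(cls, classifier: str = "svm_rbf", **kw) -> "ModelConfig":
        return cls(classifier=classifier,
                   C=SVM_PARAMS_FEATURE["C"],
                   gamma_svm=SVM_PARAMS_FEATURE["gamma"], **kw)


SVM_PARAMS_STRING_KW = {"C": SVM_PARAMS_STRING["C"],
                        "gamma_svm": SVM_PARAMS_STRING["gamma"]}


@dataclass(frozen=True)
class MetricsReport:
    TP: int
    FP: int
    TN: int
    FN: int
    PRE: float
    REC: float
    ACC: float
    FSC: float
    AUC: float
    flags: tuple[str, ...] = ()

    def to_dict(self) -> dict:
        return {k: getattr(self, k)
                for k in ("TP", "FP", "TN", "FN", "PRE", "REC", "ACC", "FSC", "AUC")}


def auc_mann_whitney(labels, scores) -> float:
    """Rank-based AUC: P(score_pos > score_neg) + 0.5 P(tie).

    Equivalent to the area under the ROC curve; 0.5 for constant scores.
    """
    labels = np.asarray(labels)
    scores = np.asarray(scores, dtype=float)
    n_pos = int(np.sum(labels == 1))
    n_neg = int(np.sum(labels == 0))
    if n_pos == 0 or n_neg == 0:
        return 0.5
    ranks = rankdata(scores)  # average ranks for ties
    r_pos = float(np.sum(ranks[labels == 1]))
    return (r_pos - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg)


def compute_metrics(TP: int, FP: int, TN: int, FN: int,
                    scores=None, labels=None) -> MetricsReport:
    """Build a MetricsReport from confusion counts (+ optional scores for AUC)."""
    for name, v in (("TP", TP), ("FP", FP), ("TN", TN), ("FN", FN)):
        if v < 0:
            raise ConfigError(f"{name} must be non-negative")
    flags = []

    def ratio(num, den, name):
        if den == 0:
            flags.append(f"{name}_undefined")
            return 0.0
        return num / den

    pre = ratio(TP, TP + FP, "PRE")
    rec = ratio(TP, TP + FN, "REC")
    acc = ratio(TP + TN, TP + TN + FP + FN, "ACC")
    fsc = ratio(2 * pre * rec, pre + rec, "FSC")
    if scores is not None and labels is not None:
        auc = auc_mann_whitney(labels, scores)
    else:
        auc = 0.0
        flags.append("AUC_unavailable")
    return MetricsReport(TP=TP, FP=FP, TN=TN, FN=FN, PRE=pre, REC=rec,
                         ACC=acc, FSC=fsc, AUC=auc, flags=tuple(flags))


def metrics_from_predictions(labels, predictions, scores=None) -> MetricsReport:
    labels = np.asarray(labels)
    predictions = np.asarray(predictions)
    tp = int(np.sum((labels == 1) & (predictions == 1)))
    fp = int(np.sum((labels == 0) & (predictions == 1)))
    tn = int(np.sum((labels == 0) & (predictions == 0)))
    fn = int(np.sum((labels == 1) & (predictions == 0)))
    return compute_metrics(tp, fp, tn, fn, scores=scores, labels=labels)


@dataclass
class FittedModel:
    """Handle over a fitted sklearn estimator with a uniform score surface."""

    estimator: object
    config: ModelConfig

    def predict(self, X) -> np.ndarray:
        return np.asarray(self.estimator.predict(X)).astype(int)

    def scores(self, X) -> np.ndarray:
        """Continuous score, larger = more positive-like.

        SVM: signed decision-function margin; RF: fraction of trees voting
        positive.
        """
        if self.config.classifier == "svm_rbf":
            return np.asarray(self.estimator.decision_function(X), dtype=float)
        proba = self.estimator.predict_proba(X)
        pos_col = list(self.estimator.classes_).index(1)
        return np.asarray(proba[:, pos_col], dtype=float)


def _make_estimator(config: ModelConfig):
    if config.classifier == "svm_rbf":
        return SVC(C=config.C, gamma=config.gamma_svm, kernel="rbf",
                   random_state=config.random_seed)
    return RandomForestClassifier(n_estimators=config.rf_n_trees,
                                  random_state=config.random_seed)


def train(X, y, config: ModelConfig) -> FittedModel:
    """Fit a classifier; deterministic given ``config.random_seed``."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    if np.isnan(X).any():
        raise ConfigError("feature matrix contains missing values")
    classes = np.unique(y)
    if len(classes) < 2:
        raise LabelError(f"training requires both classes, got labels {classes}")
    est = _make_estimator(config)
    est.fit(X, y)
    return FittedModel(estimator=est, config=config)


@dataclass(frozen=True)
class CvResult:
    pooled: MetricsReport
    per_fold: tuple[MetricsReport, ...]
    auc_fold_mean: float
    #: per-example records in original order: (label, prediction, score, fold)
    predictions: tuple[tuple[int, int, float, int], ...]


def cross_validate(X, y, config: ModelConfig) -> CvResult:
    """Stratified k-fold CV with pooled confusion counts and pooled-score AUC."""
    X = np.asarray(X, dtype=float)
    y = np.asarray(y).astype(int)
    counts = np.bincount(y, minlength=2)
    if counts.min() < config.cv_folds:
        raise LabelError(
            f"cannot make {config.cv_folds} stratified folds with class "
            f"counts {counts.tolist()}")
    skf = StratifiedKFold(n_splits=config.cv_folds, shuffle=True,
                          random_state=config.random_seed)
    preds = np.empty(len(y), dtype=int)
    scores = np.empty(len(y), dtype=float)
    fold_of = np.empty(len(y), dtype=int)
    per_fold = []
    fold_aucs = []
    for fold, (tr, te) in enumerate(skf.split(X, y)):
        model = train(X[tr], y[tr], config)
        p = model.predict(X[te])
        s = model.scores(X[te])
        preds[te], scores[te], fold_of[te] = p, s, fold
        rep = metrics_from_predictions(y[te], p, scores=s)
        per_fold.append(rep)
        fold_aucs.append(rep.AUC)
    pooled = metrics_from_predictions(y, preds, scores=scores)
    records = tuple((int(l), int(p), float(s), int(f))
                    for l, p, s, f in zip(y, preds, scores, fold_of))
    return CvResult(pooled=pooled, per_fold=tuple(per_fold),
                    auc_fold_mean=float(np.mean(fold_aucs)),
                    predictions=records)
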