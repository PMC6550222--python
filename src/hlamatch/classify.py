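"""Leave-one-out cross-validated linear-margin classification.

Each couple is scored by a linear-kernel support vector machine (margin
constant C, default 1) trained on all other couples.  Standardization and
probability calibration are fitted inside each training fold only, so the
held-out couple never influences its own model.  The out-of-fold scores
feed the ROC curve, AUC, accuracy and threshold-dependent sensitivity /
specificity, the feature-addition curve, and candidate ranking.

RM (recurrent miscarriage) is the positive class throughout.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Dict, List, Mapping, Sequence, Tuple

import numpy as np
from sklearn.linear_model import LogisticRegression
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _sk_roc_curve
from sklearn.svm import SVC

from .features import FeatureMatrix, FunctionTable, couple_feature
from .hla_model import LABEL_UNKNOWN, CoupleGenotype, HLAAllele

PairMap = Mapping[str, Tuple[HLAAllele, HLAAllele]]


class ClassificationError(ValueError):
    """Raised for degenerate classification inputs."""


@dataclass(frozen=True)
class ClassifierConfig:
    """Linear-margin classifier settings.

    calibration maps the SVM decision value to a [0, 1] score.  "rank" (the
    default) uses the empirical CDF of the training fold's decision values;
    it is free of the training fold's class prior, so scores pooled across
    LOOCV folds are comparable and the null AUC is unbiased.  "platt" fits
    a sigmoid (logistic regression) on the training decision values and
    returns a genuine class probability, at the cost of a small
    prior-driven pessimistic bias when pooled across folds.
    """

    C: float = 1.0
    standardize: bool = True
    calibration: str = "rank"
    seed: int = 0

    def __post_init__(self) -> None:
        if self.C <= 0:
            raise ClassificationError("margin constant C must be positive")
        if self.calibration not in ("platt", "rank"):
            raise ClassificationError(f"unknown calibration {self.calibration!r}")


@dataclass
class CVResult:
    """Out-of-fold scores and the derived performance summaries."""

    scores: np.ndarray
    labels: np.ndarray  # binary, 1 = RM
    auc: float
    accuracy_at_half: float
    roc: np.ndarray  # (n_points, 2): false positive rate, true positive rate
    threshold_table: Dict[float, Tuple[float, float]]
    config: ClassifierConfig


def _check_two_classes(y: np.ndarray, context: str) -> None:
    if len(np.unique(y)) < 2:
        raise ClassificationError(f"{context}: both classes must be present")


def _fit_scaler(X: np.ndarray, standardize: bool) -> Tuple[np.ndarray, np.ndarray]:
    if not standardize:
        return np.zeros(X.shape[1]), np.ones(X.shape[1])
    mu = X.mean(axis=0)
    sd = X.std(axis=0)
    if np.any(sd == 0):
        warnings.warn("zero-variance feature in training fold; scale set to 1")
        sd = np.where(sd == 0, 1.0, sd)
    return mu, sd


def _calibrate(d_train: np.ndarray, y_train: np.ndarray, d_new: np.ndarray, cfg: ClassifierConfig) -> np.ndarray:
    if cfg.calibration == "platt":
        lr = LogisticRegression(C=1e6, solver="lbfgs", max_iter=1000)
        lr.fit(d_train.reshape(-1, 1), y_train)
        return lr.predict_proba(d_new.reshape(-1, 1))[:, 1]
    # empirical-CDF rank score: monotone in the decision value
    d_new = np.atleast_1d(d_new)
    below = (d_train[None, :] < d_new[:, None]).sum(axis=1)
    tied = (d_train[None, :] == d_new[:, None]).sum(axis=1)
    return (below + 0.5 * tied) / len(d_train)


def loocv_scores(X: np.ndarray, y: np.ndarray, cfg: ClassifierConfig | None = None) -> np.ndarray:
    """Held-out probability scores for every row under leave-one-out CV.

    For each row i: drop it, fit standardization and the linear SVM on the
    rest, calibrate, score row i.  Deterministic given the config.
    """
    cfg = cfg or ClassifierConfig()
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 4 or min((y == 1).sum(), (y == 0).sum()) < 2:
        raise ClassificationError("need at least 2 couples per class for LOOCV")
    scores = np.empty(n)
    mask = np.ones(n, dtype=bool)
    svm = SVC(kernel="linear", C=cfg.C, random_state=cfg.seed)
    for i in range(n):
        mask[i] = False
        X_tr, y_tr = X[mask], y[mask]
        if len(np.unique(y_tr)) < 2:
            raise ClassificationError(f"fold {i}: training labels are single-class")
        mu, sd = _fit_scaler(X_tr, cfg.standardize)
        Z_tr = (X_tr - mu) / sd
        svm.fit(Z_tr, y_tr)
        # linear kernel: decision values directly from the primal coefficients
        w, b = svm.coef_[0], svm.intercept_[0]
        d_tr = Z_tr @ w + b
        d_te = np.array([((X[i] - mu) / sd) @ w + b])
        scores[i] = _calibrate(d_tr, y_tr, d_te, cfg)[0]
        mask[i] = True
    return scores


def roc_auc(scores: np.ndarray, labels: np.ndarray) -> Tuple[np.ndarray, float]:
    """ROC points (FPR, TPR) from a threshold sweep, and the trapezoidal AUC.

    Tied scores are grouped (diagonal segments), so the AUC equals the
    Mann–Whitney pairwise statistic (#concordant + 0.5 #tied) / (#pos #neg).
    """
    labels = np.asarray(labels, dtype=int)
    _check_two_classes(labels, "roc_auc")
    fpr, tpr, _ = _sk_roc_curve(labels, np.asarray(scores, dtype=float),
                                drop_intermediate=False)
    return np.column_stack([fpr, tpr]), float(_trapezoid_auc(fpr, tpr))


def accuracy_at(scores: np.ndarray, labels: np.ndarray, threshold: float = 0.5) -> float:
    """Fraction of couples with (score >= threshold) matching (label == RM)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if len(scores) == 0:
        raise ClassificationError("empty input")
    return float(((scores >= threshold).astype(int) == labels).mean())


def sensitivity_specificity(
    scores: np.ndarray, labels: np.ndarray, threshold: float
) -> Tuple[float, float]:
    """Sensitivity and specificity at a threshold (ties classed positive)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    pos, neg = labels == 1, labels == 0
    if not pos.any():
        raise ClassificationError("no positive examples; sensitivity undefined")
    if not neg.any():
        raise ClassificationError("no negative examples; specificity undefined")
    pred = scores >= threshold
    sens = float(pred[pos].mean())
    spec = float((~pred[neg]).mean())
    return sens, spec


def run_loocv(features: FeatureMatrix, cfg: ClassifierConfig | None = None) -> CVResult:
    """Full LOOCV evaluation of a feature matrix: scores, ROC, AUC, accuracy."""
    cfg = cfg or ClassifierConfig()
    y = features.y
    scores = loocv_scores(features.values, y, cfg)
    roc, auc_value = roc_auc(scores, y)
    table = {
        float(t): sensitivity_specificity(scores, y, float(t))
        for t in np.unique(scores)
    }
    return CVResult(
        scores=scores,
        labels=y,
        auc=auc_value,
        accuracy_at_half=accuracy_at(scores, y, 0.5),
        roc=roc,
        threshold_table=table,
        config=cfg,
    )


def feature_addition_curve(
    features: FeatureMatrix, cfg: ClassifierConfig | None = None
) -> List[Tuple[int, float]]:
    """AUC as features are added in order of single-feature performance.

    Columns are ranked by their single-feature LOOCV AUC (descending, ties
    by column order); for each k the full LOOCV runs on the top-k set.
    """
    cfg = cfg or ClassifierConfig()
    y = features.y
    n_cols = features.values.shape[1]
    single = np.array([
        roc_auc(loocv_scores(features.values[:, [j]], y, cfg), y)[1]
        for j in range(n_cols)
    ])
    order = np.argsort(-single, kind="stable")
    curve = []
    for k in range(1, n_cols + 1):
        sub = features.select(sorted(order[:k]))
        curve.append((k, roc_auc(loocv_scores(sub.values, y, cfg), y)[1]))
    return curve


@dataclass
class TrainedModel:
    """A linear-margin model fitted on a full labelled cohort."""

    svm: SVC
    mu: np.ndarray
    sd: np.ndarray
    d_train: np.ndarray = field(repr=False)
    y_train: np.ndarray = field(repr=False)
    columns: Tuple[Tuple[str, str], ...]
    config: ClassifierConfig

    def predict_proba(self, X: np.ndarray) -> np.ndarray:
        """RM probability for each feature row."""
        Z = (np.asarray(X, dtype=float) - self.mu) / self.sd
        d = self.svm.decision_function(Z)
        return _calibrate(self.d_train, self.y_train, d, self.config)


def fit_model(features: FeatureMatrix, cfg: ClassifierConfig | None = None) -> TrainedModel:
    """Fit the linear SVM (plus scaler and calibrator) on the whole cohort."""
    cfg = cfg or ClassifierConfig()
    y = features.y
    _check_two_classes(y, "fit_model")
    mu, sd = _fit_scaler(features.values, cfg.standardize)
    Z = (features.values - mu) / sd
    svm = SVC(kernel="linear", C=cfg.C, random_state=cfg.seed)
    svm.fit(Z, y)
    return TrainedModel(
        svm=svm,
        mu=mu,
        sd=sd,
        d_train=svm.decision_function(Z),
        y_train=y,
        columns=features.columns,
        config=cfg,
    )


def rank_candidates(
    recipient: PairMap,
    candidates: Sequence[Tuple[str, PairMap]],
    model: TrainedModel,
    functions: FunctionTable,
) -> List[Tuple[str, float]]:
    """Rank donor candidates for one recipient by predicted RM probability.

    Each candidate forms a virtual couple with the recipient; its features
    are computed with the pipeline similarity functions and scored by the
    trained model.  Best candidates (lowest RM probability) come first;
    ties are broken by candidate id, then original order (stable sort).
    """
    rows = []
    for cand_id, cand in candidates:
        couple = CoupleGenotype(
            couple_id=f"virtual:{cand_id}",
            maternal=dict(recipient),
            paternal=dict(cand),
            label=LABEL_UNKNOWN,
        )
        rows.append([
            couple_feature(couple, locus, functions[(locus, kind)])
            for locus, kind in model.columns
        ])
    probs = model.predict_proba(np.asarray(rows, dtype=float))
    ranked = sorted(
        zip((cid for cid, _ in candidates), probs.tolist()),
        key=lambda item: (item[1], item[0]),
    )
    return [(cid, float(p)) for cid, p in ranked]
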