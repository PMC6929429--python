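"""Cross-validated subtype prediction from editing-level features.

Predicts IDH mutation status (over the whole cohort) and 1p/19q codeletion
(by default over IDH-mutant samples only, where the codel/non-codel
distinction is clinically posed) with three supervised learners — a
linear-kernel SVM, a random forest, and AdaBoost on decision stumps — under
stratified 10-fold cross-validation.  Feature selection, when enabled, is
refit inside each training fold so test samples never influence the chosen
sites.  Pooled test-fold scores yield ACC/SEN/SPE, the ROC curve and its
AUC; correlated AUCs of two learners on the same samples are compared with
the DeLong test.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterable, Literal, Sequence

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.ensemble import AdaBoostClassifier, RandomForestClassifier
from sklearn.metrics import auc as _trapezoid_auc
from sklearn.metrics import roc_curve as _roc_curve
from sklearn.model_selection import KFold, StratifiedKFold
from sklearn.svm import SVC

from .quant import GlioeditError

LearnerName = Literal["svm", "random_forest", "adaboost"]
LEARNERS: tuple[str, ...] = ("svm", "random_forest", "adaboost")


@dataclass
class TaskSpec:
    """Which clinical status is predicted, and over which samples."""

    task: Literal["idh", "codel", "three_class"] = "idh"
    cohort_restriction: Literal["all", "idh_mutant_only"] = "all"

    def __post_init__(self) -> None:
        if self.task not in ("idh", "codel", "three_class"):
            raise GlioeditError(f"unknown task {self.task!r}")


@dataclass
class CVConfig:
    """Cross-validation settings.  ``seed`` drives fold assignment and any
    learner randomness; stratified folds are the default (plain random folds
    can starve a training fold of a class)."""

    n_folds: int = 10
    seed: int = 0
    learner: str = "svm"
    feature_selection: Literal["none", "in_fold"] = "none"
    stratified: bool = True
    top_k: int | None = None

    def __post_init__(self) -> None:
        if self.n_folds < 2:
            raise GlioeditError("n_folds must be >= 2")
        if self.learner not in LEARNERS:
            raise GlioeditError(f"unknown learner {self.learner!r}; choose from {LEARNERS}")


@dataclass
class FoldResult:
    fold_index: int
    train_ids: list[str]
    test_ids: list[str]
    selected_site_ids: list[str]
    scores: pd.Series = field(repr=False)
    predicted: pd.Series = field(repr=False)


@dataclass
class PerformanceSummary:
    acc: float
    sen: float
    spe: float
    auc: float
    roc: np.ndarray = field(repr=False)  # columns: (1-SPE, SEN)
    confusion: dict[str, int] = field(default_factory=dict)


@dataclass
class AUCComparison:
    auc_a: float
    auc_b: float
    variance: float
    z: float
    p_value: float


def make_task_labels(cohort: pd.DataFrame, spec: TaskSpec) -> pd.Series | pd.DataFrame:
    """Binary label vector for a prediction task (1 = positive class).

    IDH task: positive = IDH mutant, over all samples.  Codel task:
    positive = 1p/19q codeleted, over the restricted cohort (default
    restriction for codel is IDH-mutant-only).  ``three_class`` returns a
    DataFrame of three one-vs-rest label vectors, one per subtype.
    """
    if spec.task == "three_class":
        sub = cohort["subtype"]
        out = pd.DataFrame(
            {s: (sub == s).astype(int) for s in ("wt", "mut-codel", "mut-non-codel")}
        )
        for col in out:
            if out[col].nunique() < 2:
                raise GlioeditError(f"class {col!r} is empty or exhaustive")
        return out
    if spec.task == "idh":
        labels = (cohort["idh_status"] == "mutant").astype(int)
    else:  # codel
        sub = cohort
        if spec.cohort_restriction == "idh_mutant_only":
            sub = cohort[cohort["idh_status"] == "mutant"]
        labels = (sub["codel_status"] == "codel").astype(int)
    for cls, name in ((1, "positive"), (0, "negative")):
        if (labels == cls).sum() == 0:
            raise GlioeditError(f"{name} class is empty for task {spec.task!r}")
    labels.name = spec.task
    return labels


def build_feature_matrix(
    levels: pd.DataFrame,
    sites: Iterable[str],
    samples: Iterable[str] | None = None,
    impute: Literal["zero", "mean"] = "zero",
) -> pd.DataFrame:
    """Sample x site feature matrix of editing levels with imputation.

    Missing levels (uncovered cells) default to 0 — biologically "unedited";
    ``impute="mean"`` substitutes the site's cohort mean instead (all-missing
    sites fall back to 0).
    """
    ids = pd.Index(sites)
    missing = ids.difference(levels.index)
    if len(missing):
        raise GlioeditError(f"sites absent from level matrix: {list(missing)[:5]}")
    mat = levels.loc[ids].T  # samples x sites
    if samples is not None:
        mat = mat.loc[pd.Index(samples)]
    if impute == "zero":
        mat = mat.fillna(0.0)
    elif impute == "mean":
        mat = mat.fillna(mat.mean(axis=0)).fillna(0.0)
    else:
        raise GlioeditError(f"unknown imputation {impute!r}")
    return mat


def _make_learner(name: str, seed: int):
    if name == "svm":
        return SVC(kernel="linear", random_state=seed)
    if name == "random_forest":
        return RandomForestClassifier(random_state=seed)
    if name == "adaboost":
        return AdaBoostClassifier(random_state=seed)
    raise GlioeditError(f"unknown learner {name!r}")


def _score(estimator, X: np.ndarray) -> np.ndarray:
    if hasattr(estimator, "decision_function"):
        return np.asarray(estimator.decision_function(X), dtype=float)
    return np.asarray(estimator.predict_proba(X)[:, 1], dtype=float)


def _importances(name: str, estimator) -> np.ndarray:
    if name == "svm":
        return np.abs(np.asarray(estimator.coef_).ravel())
    return np.asarray(estimator.feature_importances_, dtype=float)


def select_features_fold(
    learner: str,
    features: pd.DataFrame,
    labels: pd.Series,
    rule: Literal["default", "top_k"] = "default",
    top_k: int | None = None,
    seed: int = 0,
) -> list[str]:
    """Importance-based feature selection fit on training data only.

    Importance is the absolute linear weight for the SVM and impurity-based
    importance for the tree ensembles.  The default rule keeps features with
    importance at or above the mean importance for SVM and random forest and
    features with any nonzero importance for AdaBoost (each stump uses one
    feature, so at most ``n_estimators`` sites can score).  ``rule="top_k"``
    keeps the ``top_k`` highest-importance features (ties broken by column
    order).
    """
    est = _make_learner(learner, seed)
    est.fit(features.to_numpy(), labels.to_numpy())
    imp = _importances(learner, est)
    if not np.any(imp > 0):
        raise GlioeditError("all feature importances are zero")
    cols = np.asarray(features.columns)
    if rule == "top_k" or top_k is not None:
        if not top_k or top_k < 1:
            raise GlioeditError("top_k rule needs a positive top_k")
        order = np.lexsort((np.arange(len(imp)), -imp))
        return list(cols[order[:top_k]])
    if learner == "adaboost":
        keep = imp > 0
    else:
        keep = imp >= imp.mean()
    return list(cols[keep])


def run_cv(
    features: pd.DataFrame,
    labels: pd.Series,
    config: CVConfig,
) -> tuple[list[FoldResult], PerformanceSummary]:
    """Stratified k-fold cross-validation with optional in-fold selection.

    Every sample is scored exactly once as a test case; the pooled test-set
    scores and predictions yield the performance summary.
    """
    features, labels = features.align(labels, join="inner", axis=0)
    if features.empty:
        raise GlioeditError("no overlapping samples between features and labels")
    if config.n_folds > len(labels):
        raise GlioeditError("more folds than samples")
    y = labels.to_numpy()
    if config.stratified:
        splitter = StratifiedKFold(
            n_splits=config.n_folds, shuffle=True, random_state=config.seed)
    else:
        splitter = KFold(n_splits=config.n_folds, shuffle=True, random_state=config.seed)

    folds: list[FoldResult] = []
    for fold_index, (tr, te) in enumerate(splitter.split(features, y)):
        y_tr = y[tr]
        if len(np.unique(y_tr)) < 2:
            raise GlioeditError(
                f"training fold {fold_index} lacks a class; use stratified folds")
        X_tr = features.iloc[tr]
        X_te = features.iloc[te]
        if config.feature_selection == "in_fold":
            sel = select_features_fold(
                config.learner, X_tr, labels.iloc[tr],
                top_k=config.top_k, seed=config.seed)
            X_tr, X_te = X_tr[sel], X_te[sel]
        else:
            sel = list(features.columns)
        est = _make_learner(config.learner, config.seed)
        est.fit(X_tr.to_numpy(), y_tr)
        scores = pd.Series(_score(est, X_te.to_numpy()), index=X_te.index)
        predicted = pd.Series(est.predict(X_te.to_numpy()), index=X_te.index)
        folds.append(
            FoldResult(
                fold_index=fold_index,
                train_ids=list(features.index[tr]),
                test_ids=list(features.index[te]),
                selected_site_ids=sel,
                scores=scores,
                predicted=predicted,
            )
        )
    summary = summarize_folds(folds, labels)
    return folds, summary


def summarize_folds(folds: Sequence[FoldResult], labels: pd.Series) -> PerformanceSummary:
    """Pool per-fold test scores/predictions into one performance summary."""
    scores = pd.concat([f.scores for f in folds]).reindex(labels.index)
    predicted = pd.concat([f.predicted for f in folds]).reindex(labels.index)
    acc, sen, spe, confusion = compute_metrics(predicted, labels)
    roc, auc_value = compute_roc_auc(scores, labels)
    return PerformanceSummary(
        acc=acc, sen=sen, spe=spe, auc=auc_value, roc=roc, confusion=confusion)


def compute_metrics(
    predicted: pd.Series | np.ndarray, true: pd.Series | np.ndarray
) -> tuple[float, float, float, dict[str, int]]:
    """ACC, SEN, SPE and confusion counts for binary predictions.

    ACC = (TP+TN)/(TP+FP+TN+FN), SEN = TP/(TP+FN), SPE = TN/(TN+FP); SEN
    (resp. SPE) is NaN when there are no true positives (negatives).
    """
    yp = np.asarray(predicted)
    yt = np.asarray(true)
    if yp.shape != yt.shape:
        raise GlioeditError("predicted/true length mismatch")
    tp = int(np.sum((yp == 1) & (yt == 1)))
    tn = int(np.sum((yp == 0) & (yt == 0)))
    fp = int(np.sum((yp == 1) & (yt == 0)))
    fn = int(np.sum((yp == 0) & (yt == 1)))
    total = tp + tn + fp + fn
    acc = (tp + tn) / total if total else float("nan")
    sen = tp / (tp + fn) if tp + fn else float("nan")
    spe = tn / (tn + fp) if tn + fp else float("nan")
    return acc, sen, spe, {"TP": tp, "FP": fp, "TN": tn, "FN": fn}


def compute_roc_auc(
    scores: pd.Series | np.ndarray, labels: pd.Series | np.ndarray
) -> tuple[np.ndarray, float]:
    """ROC curve (all distinct score thresholds) and trapezoidal AUC.

    Returns an array of (1-SPE, SEN) points from (0,0) to (1,1) and the
    area under it, which equals the Mann-Whitney concordance probability.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    if len(np.unique(y)) < 2:
        raise GlioeditError("ROC needs both classes present")
    fpr, tpr, _ = _roc_curve(y, s, drop_intermediate=False)
    roc = np.column_stack([fpr, tpr])
    return roc, float(_trapezoid_auc(fpr, tpr))


def _placements(scores: np.ndarray, labels: np.ndarray) -> tuple[float, np.ndarray, np.ndarray]:
    """AUC and DeLong placement values for one score vector."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    all_ranks = stats.rankdata(np.concatenate([pos, neg]))
    pos_ranks = stats.rankdata(pos)
    neg_ranks = stats.rankdata(neg)
    auc_value = (all_ranks[:m].sum() - m * (m + 1) / 2) / (m * n)
    v_pos = (all_ranks[:m] - pos_ranks) / n          # per-positive placements
    v_neg = 1.0 - (all_ranks[m:] - neg_ranks) / m    # per-negative placements
    return float(auc_value), v_pos, v_neg


def delong_test(
    scores_a: pd.Series | np.ndarray,
    scores_b: pd.Series | np.ndarray,
    labels: pd.Series | np.ndarray,
) -> AUCComparison:
    """DeLong paired comparison of two correlated AUCs on the same samples.

    Uses placement values to estimate the covariance of the two empirical
    AUCs; the difference divided by its standard error is referred to a
    standard normal (two-sided).  Two identical score vectors (zero variance
    of the difference, zero AUC difference) give p = 1.
    """
    sa = np.asarray(scores_a, dtype=float)
    sb = np.asarray(scores_b, dtype=float)
    y = np.asarray(labels)
    if sa.shape != sb.shape or sa.shape != y.shape:
        raise GlioeditError("DeLong test needs paired scores on identical samples")
    if len(np.unique(y)) < 2:
        raise GlioeditError("DeLong test needs both classes present")
    auc_a, va_pos, va_neg = _placements(sa, y)
    auc_b, vb_pos, vb_neg = _placements(sb, y)
    m, n = len(va_pos), len(va_neg)
    s_pos = np.cov(np.vstack([va_pos, vb_pos]), ddof=1)
    s_neg = np.cov(np.vstack([va_neg, vb_neg]), ddof=1)
    cov = s_pos / m + s_neg / n
    var_diff = float(cov[0, 0] + cov[1, 1] - 2 * cov[0, 1])
    diff = auc_a - auc_b
    if var_diff <= 0:
        if abs(diff) < 1e-12:
            return AUCComparison(auc_a, auc_b, 0.0, 0.0, 1.0)
        warnings.warn("zero DeLong variance with nonzero AUC difference")
        return AUCComparison(auc_a, auc_b, 0.0, float(np.sign(diff) * np.inf), 0.0)
    z = diff / np.sqrt(var_diff)
    p = 2.0 * stats.norm.sf(abs(z))
    return AUCComparison(auc_a, auc_b, var_diff, float(z), float(min(p, 1.0)))


def identify_misclassified(
    runs: Sequence[Sequence[FoldResult]], labels: pd.Series
) -> set[str]:
    """Samples predicted wrongly in *every* supplied cross-validation run."""
    if not runs:
        raise GlioeditError("need at least one run")
    common: set[str] | None = None
    for folds in runs:
        predicted = pd.concat([f.predicted for f in folds])
        missing = labels.index.difference(predicted.index)
        if len(missing):
            raise GlioeditError("run does not cover the full cohort")
        wrong = set(labels.index[predicted.reindex(labels.index) != labels])
        common = wrong if common is None else common & wrong
    return common or set()


def repeated_selected_sites(
    folds: Sequence[FoldResult], min_count: int = 5
) -> set[str]:
    """Sites selected in at least ``min_count`` cross-validation folds."""
    if min_count > len(folds):
        warnings.warn(
            f"min_count={min_count} exceeds the {len(folds)} folds; returning empty set")
        return set()
    tally: dict[str, int] = {}
    for f in folds:
        for site in f.selected_site_ids:
            tally[site] = tally.get(site, 0) + 1
    return {site for site, c in tally.items() if c >= min_count}
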