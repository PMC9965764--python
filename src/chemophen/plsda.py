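"""PLS-DA marker selection and model evaluation.

The classifier is a PLS2 regression (NIPALS) of one-hot class membership on
column-centered, unit-scaled variables.  Variable importance is the VIP score

    VIP_j = sqrt( p * sum_a SSY_a (w_ja / ||w_a||)^2 / sum_a SSY_a )

with p variables, component weights w_a, and SSY_a the response variance
explained by component a; the per-class variant weighs components by the
class's own explained variance.  VIP obeys sum_j VIP_j^2 = p, which serves as
the module's built-in sanity identity.  Markers are the variables whose
importance strictly exceeds the empirical 0.995 quantile of their class
column.  Model quality is reported as stratified cross-validated accuracy,
the R-squared of the full model's one-hot fit, and one-vs-rest ROC / PR areas
pooled over the CV folds.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from sklearn.cross_decomposition import PLSRegression
from sklearn.metrics import (
    average_precision_score,
    precision_recall_curve,
    roc_auc_score,
    roc_curve,
)
logger = logging.getLogger(__name__)

__all__ = [
    "PlsdaModel",
    "fit_plsda",
    "variable_importance",
    "MarkerSelection",
    "select_markers",
    "EvaluationResult",
    "evaluate",
    "heatmap_matrix",
]


def _as_frame(X) -> pd.DataFrame:
    if isinstance(X, pd.DataFrame):
        return X
    X = np.asarray(X, dtype=float)
    return pd.DataFrame(X, columns=[f"V{j + 1}" for j in range(X.shape[1])])


def _one_hot(y: np.ndarray, classes: np.ndarray) -> np.ndarray:
    return (y[:, None] == classes[None, :]).astype(float)


def _fit_pls(X: np.ndarray, Y: np.ndarray, n_components: int) -> PLSRegression:
    pls = PLSRegression(n_components=n_components, scale=True)
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")  # y residual / constant-column chatter
        pls.fit(X, Y)
    return pls


@dataclass
class PlsdaModel:
    """A fitted PLS-DA model (weights, scores, loadings, class labels)."""

    n_components: int
    classes: np.ndarray
    variables: list[str]
    pls: PLSRegression
    seed: int
    cv_accuracy_by_components: dict[int, float] = field(default_factory=dict)

    @property
    def x_weights(self) -> np.ndarray:
        return self.pls.x_weights_

    @property
    def x_scores(self) -> np.ndarray:
        return self.pls.x_scores_

    @property
    def y_loadings(self) -> np.ndarray:
        return self.pls.y_loadings_

    def decision_scores(self, X) -> np.ndarray:
        """Continuous per-class scores (predicted one-hot values)."""
        return self.pls.predict(np.asarray(_as_frame(X), dtype=float))

    def predict(self, X) -> np.ndarray:
        scores = self.decision_scores(X)
        return self.classes[np.argmax(scores, axis=1)]


def _class_counts(y: np.ndarray) -> tuple[np.ndarray, np.ndarray]:
    classes, counts = np.unique(y, return_counts=True)
    return classes, counts


def _stratified_folds(y: np.ndarray, k: int, rng: np.random.Generator) -> list[np.ndarray]:
    """Deal each class's shuffled members round-robin over k folds.

    Unlike a strict stratified split this tolerates k larger than the
    smallest class (folds then simply lack that class), which small balanced
    designs with, say, 3 replicates per taxon require.
    """
    folds: list[list[int]] = [[] for _ in range(k)]
    pointer = 0
    for cls in np.unique(y):
        idx = np.flatnonzero(y == cls)
        rng.shuffle(idx)
        for i in idx:
            folds[pointer % k].append(int(i))
            pointer += 1
    return [np.array(sorted(f), dtype=int) for f in folds if f]


def fit_plsda(X, y, max_components: int = 5, seed: int = 0) -> PlsdaModel:
    """Fit a PLS-DA model, choosing the component count by stratified CV accuracy.

    Every class needs at least 2 samples (stratification is impossible
    otherwise).  Constant columns receive zero weight rather than being
    dropped, so variable indices are stable.  Ties in CV accuracy resolve to
    the smaller component count; the fit itself (NIPALS) is deterministic,
    and the CV shuffling is governed by ``seed``.
    """
    Xf = _as_frame(X)
    Xv = Xf.to_numpy(dtype=float)
    y = np.asarray(y)
    if not np.isfinite(Xv).all():
        raise ValueError("X must be finite")
    classes, counts = _class_counts(y)
    if len(classes) < 2:
        raise ValueError("PLS-DA needs at least 2 classes")
    if counts.min() < 2:
        small = classes[np.argmin(counts)]
        raise ValueError(f"class {small!r} has a single sample; cannot stratify")
    n, p = Xv.shape
    Y = _one_hot(y, classes)
    Xc = Xv - Xv.mean(axis=0)
    rank = int(np.linalg.matrix_rank(Xc)) if Xc.any() else 0
    if rank == 0:
        raise ValueError("X has no variance; nothing to fit")
    a_max = int(min(max_components, n - 1, p, rank))

    # same clamped fold count the evaluation uses, so the selected component
    # count is the one that actually cross-validates best under that scheme
    k_sel = int(min(10, counts.min() * len(classes), n))
    accs: dict[int, float] = {}
    if a_max == 1:
        best_a = 1
    else:
        rng = np.random.default_rng(seed)
        test_folds = _stratified_folds(y, k_sel, rng)
        all_idx = np.arange(n)
        for a in range(1, a_max + 1):
            hits = 0
            try:
                for test in test_folds:
                    train = np.setdiff1d(all_idx, test)
                    pls = _fit_pls(Xv[train], Y[train], min(a, len(train) - 1))
                    pred = pls.predict(Xv[test])
                    if not np.isfinite(pred).all():
                        raise ValueError("degenerate fit")
                    hits += int((classes[np.argmax(pred, axis=1)] == y[test]).sum())
            except (ValueError, np.linalg.LinAlgError):
                # a exceeds the rank a training fold supports
                continue
            accs[a] = hits / n
        if not accs:
            accs[1] = float("nan")
        finite = {a: v for a, v in accs.items() if np.isfinite(v)}
        if finite:
            best = max(finite.values())
            best_a = min(a for a, v in finite.items() if v == best)
        else:
            best_a = 1

    pls = _fit_pls(Xv, Y, best_a)
    return PlsdaModel(
        n_components=best_a,
        classes=classes,
        variables=list(Xf.columns),
        pls=pls,
        seed=seed,
        cv_accuracy_by_components=accs,
    )


def variable_importance(model: PlsdaModel) -> pd.DataFrame:
    """Variables x classes matrix of per-class VIP scores.

    Component a explains SSY_{k,a} = q_{k,a}^2 * t_a't_a of class k's one-hot
    response; the class column weighs the squared normalized weights by these
    explained-variance shares.  Each column satisfies sum_j VIP^2 = p.
    """
    W = model.x_weights  # p x A, NIPALS weights
    T = model.x_scores   # n x A
    Q = model.y_loadings  # k x A
    p, A = W.shape
    w_norm2 = (W ** 2).sum(axis=0)
    w_norm2[w_norm2 == 0] = 1.0
    W2 = (W ** 2) / w_norm2  # squared normalized weights
    t2 = (T ** 2).sum(axis=0)  # t_a' t_a
    ssy = (Q ** 2) * t2[None, :]  # classes x components

    cols = {}
    for k, cls in enumerate(model.classes):
        weights = ssy[k]
        total = weights.sum()
        if total <= 0:
            logger.warning("class %r: no explained response variance; VIP set to 0", cls)
            cols[str(cls)] = np.zeros(p)
            continue
        cols[str(cls)] = np.sqrt(p * (W2 @ (weights / total)))
    return pd.DataFrame(cols, index=model.variables)


@dataclass
class MarkerSelection:
    selected: set[str]
    per_class: dict[str, list[str]]
    thresholds: dict[str, float]
    quantile_threshold: float


def select_markers(
    importance: pd.DataFrame, quantile_threshold: float = 0.995, pooled: bool = False
) -> MarkerSelection:
    """Variables strictly above the empirical quantile of their importance column.

    The quantile uses linear interpolation.  By default the rule is applied
    per class column and the union returned with per-class provenance;
    ``pooled=True`` applies it to the row-wise maximum importance instead.
    """
    if pooled:
        importance = importance.max(axis=1).to_frame("pooled")
    per_class: dict[str, list[str]] = {}
    thresholds: dict[str, float] = {}
    for cls in importance.columns:
        col = importance[cls].to_numpy(dtype=float)
        thr = float(np.quantile(col, quantile_threshold, method="linear"))
        thresholds[str(cls)] = thr
        per_class[str(cls)] = list(importance.index[col > thr])
    selected = set().union(*per_class.values()) if per_class else set()
    return MarkerSelection(
        selected=selected,
        per_class=per_class,
        thresholds=thresholds,
        quantile_threshold=quantile_threshold,
    )


@dataclass
class EvaluationResult:
    accuracy: float
    r2: float
    auc: dict[str, float]
    auc_pr: dict[str, float]
    macro_auc: float
    macro_auc_pr: float
    k_folds: int
    roc_curves: dict[str, pd.DataFrame]
    pr_curves: dict[str, pd.DataFrame]


def evaluate(model: PlsdaModel, X, y, k_folds: int = 10, seed: int = 0) -> EvaluationResult:
    """Stratified k-fold CV metrics plus the full model's one-hot R-squared.

    k clamps to min(k_folds, smallest class size x number of classes, number
    of samples); small designs cannot support a literal 10-fold split.  AUC
    and PR areas are one-vs-rest on the CV-pooled decision scores, with
    macro averages.
    """
    Xf = _as_frame(X)
    Xv = Xf.to_numpy(dtype=float)
    y = np.asarray(y)
    classes, counts = _class_counts(y)
    n = len(y)
    k = int(min(k_folds, counts.min() * len(classes), n))
    if k < 2:
        raise ValueError(f"cannot cross-validate with k={k}")
    logger.info("evaluating with %d-fold stratified CV", k)

    Y = _one_hot(y, classes)
    rng = np.random.default_rng(seed)
    pooled_scores = np.zeros_like(Y)
    all_idx = np.arange(n)
    for test in _stratified_folds(y, k, rng):
        train = np.setdiff1d(all_idx, test)
        pls = _fit_pls(Xv[train], Y[train], min(model.n_components, len(train) - 1))
        pooled_scores[test] = pls.predict(Xv[test])

    pred = classes[np.argmax(pooled_scores, axis=1)]
    accuracy = float((pred == y).mean())

    fitted = model.decision_scores(Xf)
    sse = float(((Y - fitted) ** 2).sum())
    sst = float(((Y - Y.mean(axis=0)) ** 2).sum())
    r2 = 1.0 - sse / sst

    auc, auc_pr, roc_curves, pr_curves = {}, {}, {}, {}
    for kdx, cls in enumerate(classes):
        truth = Y[:, kdx]
        score = pooled_scores[:, kdx]
        auc[str(cls)] = float(roc_auc_score(truth, score))
        auc_pr[str(cls)] = float(average_precision_score(truth, score))
        fpr, tpr, _ = roc_curve(truth, score)
        roc_curves[str(cls)] = pd.DataFrame({"fpr": fpr, "tpr": tpr})
        prec, rec, _ = precision_recall_curve(truth, score)
        pr_curves[str(cls)] = pd.DataFrame({"recall": rec, "precision": prec})

    return EvaluationResult(
        accuracy=accuracy,
        r2=r2,
        auc=auc,
        auc_pr=auc_pr,
        macro_auc=float(np.mean(list(auc.values()))),
        macro_auc_pr=float(np.mean(list(auc_pr.values()))),
        k_folds=k,
        roc_curves=roc_curves,
        pr_curves=pr_curves,
    )


def heatmap_matrix(
    X, selected, y, importance: pd.DataFrame | None = None, replicates=None
) -> pd.DataFrame:
    """Z-scored matrix of the selected variables, ordered for heatmap display.

    Columns are the selected variables z-scored across samples (population
    sd); constant variables are excluded with a log note.  Rows group by
    class label (then input order); columns order by descending maximum
    importance when an importance matrix is given, else by name.
    """
    Xf = _as_frame(X)
    selected = list(selected)
    if not selected:
        raise ValueError("empty selection: lower the quantile threshold to select markers")
    sub = Xf[selected].astype(float)
    sd = sub.std(axis=0, ddof=0)
    constant = list(sd.index[sd == 0])
    if constant:
        logger.info("excluding %d constant variable(s) from heatmap: %s",
                    len(constant), constant[:5])
        sub = sub.drop(columns=constant)
        sd = sd.drop(index=constant)
    if sub.shape[1] == 0:
        raise ValueError("all selected variables are constant")
    z = (sub - sub.mean(axis=0)) / sd

    y = np.asarray(y)
    order = np.argsort(y, kind="mergesort")  # stable: class, then input order
    z = z.iloc[order]

    if importance is not None:
        imp = importance.reindex(z.columns).max(axis=1)
        z = z[imp.sort_values(ascending=False, kind="mergesort").index]
    else:
        z = z[sorted(z.columns)]
    return z
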