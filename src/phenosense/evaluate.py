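"""Nested leave-one-cohort-out classification protocol.

Each enrollment cohort is held out in turn; on the remaining cohorts a
univariate t-test keeps the 100 smallest-p features, sequential forward
selection (greedy, scored by inner stratified 10-fold CV accuracy of an
RBF-kernel SVM jointly grid-searched over C and gamma) picks up to five
of them, and the chosen model is refit and applied to the held-out
cohort.  L1-regularized logistic regression ("LASSO") instead selects its
penalty by inner 10-fold CV.  Out-of-fold predictions are concatenated
across cohorts before computing accuracy (with an adjusted-Wald /
Agresti-Coull 95% CI) and the F1 score.

Missing feature values are imputed by the training-fold median and
features are standardized with training-fold statistics; the held-out
cohort never influences imputation, scaling, filtering or selection.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.svm import SVC

try:  # low-level binding: same solver as SVC without per-call estimator overhead
    from sklearn.svm import _libsvm as _lsvm

    _lsvm.set_verbosity_wrap(0)
    _HAVE_LIBSVM = True
except Exception:  # pragma: no cover - exercised only on incompatible sklearn
    _HAVE_LIBSVM = False

logger = logging.getLogger(__name__)


class ProtocolError(ValueError):
    """The evaluation protocol cannot be applied to the given data."""


@dataclass
class ModelSpec:
    """Classifier family and tuning configuration.

    ``family`` is one of ``svm_rbf``, ``svm_linear``, ``lasso``.  Feature
    selection (prefilter + SFS) applies to the SVM families; the lasso
    relies on its L1 penalty, tuned over ``n_lasso_penalties`` log-spaced
    values by inner CV.
    """

    family: str = "svm_rbf"
    c_grid: tuple = (0.1, 1.0, 10.0, 100.0)
    gamma_grid: tuple = (1e-3, 1e-2, 1e-1, 1.0, 10.0)
    n_lasso_penalties: int = 50
    prefilter_k: int = 100
    max_features: int = 5
    inner_folds: int = 10
    seed: int = 0

    def validate(self):
        if self.family not in ("svm_rbf", "svm_linear", "lasso"):
            raise ProtocolError(f"unknown model family '{self.family}'")
        if not self.c_grid or not self.gamma_grid:
            raise ProtocolError("hyperparameter grids must be nonempty")
        if self.prefilter_k < 1 or self.max_features < 1 or self.inner_folds < 2:
            raise ProtocolError("prefilter_k, max_features >= 1 and inner_folds >= 2 required")

    def lasso_cs(self) -> np.ndarray:
        return np.logspace(-3, 3, self.n_lasso_penalties)


@dataclass
class FoldResult:
    cohort: str
    train_ids: list[str]
    test_ids: list[str]
    selected_features: list[str]
    hyperparameters: dict
    predictions: np.ndarray
    truths: np.ndarray

    @property
    def accuracy(self) -> float:
        return float(np.mean(self.predictions == self.truths))


@dataclass
class EvaluationResult:
    """Concatenated out-of-fold predictions and summary metrics."""

    outcome: str
    family: str
    ids: list[str]
    predictions: np.ndarray
    truths: np.ndarray
    accuracy: float
    accuracy_ci: tuple[float, float]
    f1: float
    folds: list[FoldResult]
    selection_frequency: pd.Series = field(default=None)

    @property
    def n(self) -> int:
        return len(self.ids)

    def to_dict(self) -> dict:
        return {
            "outcome": self.outcome,
            "family": self.family,
            "n": self.n,
            "accuracy": self.accuracy,
            "accuracy_ci": list(self.accuracy_ci),
            "f1": self.f1,
            "folds": [
                {
                    "cohort": f.cohort,
                    "n_train": len(f.train_ids),
                    "n_test": len(f.test_ids),
                    "selected_features": f.selected_features,
                    "hyperparameters": f.hyperparameters,
                    "accuracy": f.accuracy,
                }
                for f in self.folds
            ],
            "selection_frequency": (
                self.selection_frequency.to_dict() if self.selection_frequency is not None else {}
            ),
        }


# ---------------------------------------------------------------------------
# metrics


def f1_score(predictions: np.ndarray, truths: np.ndarray, positive: int = 1) -> float:
    """F1 = 2 * precision * recall / (precision + recall); positive = high group.

    Returns 0 when precision + recall is 0 (no true or predicted
    positives overlap).
    """
    predictions = np.asarray(predictions)
    truths = np.asarray(truths)
    tp = float(np.sum((predictions == positive) & (truths == positive)))
    fp = float(np.sum((predictions == positive) & (truths != positive)))
    fn = float(np.sum((predictions != positive) & (truths == positive)))
    if tp + fp == 0 or tp + fn == 0:
        return 0.0
    precision = tp / (tp + fp)
    recall = tp / (tp + fn)
    if precision + recall == 0:
        return 0.0
    return 2.0 * precision * recall / (precision + recall)


def adjusted_wald_ci(successes: int, n: int, level: float = 0.95) -> tuple[float, float]:
    """Adjusted-Wald (Agresti-Coull) binomial confidence interval, clipped to [0, 1].

    With z the normal quantile, p~ = (x + z^2/2) / (n + z^2) and the
    half-width is z * sqrt(p~ (1 - p~) / (n + z^2)).
    """
    if n < 1 or not 0 <= successes <= n:
        raise ValueError("need 0 <= successes <= n and n >= 1")
    z = stats.norm.ppf(0.5 + level / 2.0)
    n_t = n + z**2
    p_t = (successes + z**2 / 2.0) / n_t
    half = z * np.sqrt(p_t * (1.0 - p_t) / n_t)
    return (max(p_t - half, 0.0), min(p_t + half, 1.0))


def selection_frequency(per_fold_selected: list[list[str]]) -> pd.Series:
    """Percent of models selecting each feature, over the completed folds."""
    if not per_fold_selected:
        raise ProtocolError("no completed folds")
    n_models = len(per_fold_selected)
    counts: dict[str, int] = {}
    for sel in per_fold_selected:
        for feat in set(sel):
            counts[feat] = counts.get(feat, 0) + 1
    freq = pd.Series({k: 100.0 * v / n_models for k, v in counts.items()},
                     name="selected_pct").sort_values(ascending=False)
    freq.attrs["n_models"] = n_models
    return freq


# ---------------------------------------------------------------------------
# feature filtering and selection


def ttest_prefilter(X: pd.DataFrame, y: np.ndarray, k: int = 100) -> list[str]:
    """Keep the k features with the smallest two-sample t-test p-values.

    Welch's t-test is computed per feature on the training data only,
    with missing values dropped pairwise; returned names are in ascending
    p-value order (NaN p-values rank last).
    """
    y = np.asarray(y)
    if len(np.unique(y)) < 2:
        raise ProtocolError("both classes must be present in the training data")
    a = X.loc[y == 1]
    b = X.loc[y == 0]
    if min(a.shape[0], b.shape[0]) < 2:
        raise ProtocolError("need >= 2 training samples per class")
    with warnings.catch_warnings():
        warnings.simplefilter("ignore")
        res = stats.ttest_ind(a.to_numpy(dtype=float), b.to_numpy(dtype=float),
                              axis=0, equal_var=False, nan_policy="omit")
    p = np.asarray(res.pvalue, dtype=float)
    p = np.where(np.isnan(p), np.inf, p)
    order = np.argsort(p, kind="stable")[: min(k, X.shape[1])]
    return [X.columns[i] for i in order]


def _inner_folds(y: np.ndarray, n_folds: int, seed: int) -> list[tuple[np.ndarray, np.ndarray]]:
    classes, counts = np.unique(y, return_counts=True)
    if len(classes) < 2:
        raise ProtocolError("inner CV requires both classes")
    k = min(n_folds, int(counts.min()))
    if k < 2:
        raise ProtocolError("a class is too small for stratified inner CV")
    skf = StratifiedKFold(n_splits=k, shuffle=True, random_state=seed)
    return list(skf.split(np.zeros_like(y), y))


def _svm_fit_predict(Xtr: np.ndarray, ytr: np.ndarray, Xte: np.ndarray,
                     c: float, gamma: float, kernel: str = "rbf") -> np.ndarray:
    """Fit an SVM and predict the test rows; identical output to ``SVC``.

    Uses the low-level libsvm binding when available: at the tiny fold
    sizes of the inner CV, estimator construction and input validation
    dominate ``SVC.fit``, and the direct call is several times faster.
    """
    if _HAVE_LIBSVM:
        model = _lsvm.fit(Xtr, ytr, svm_type=0, kernel=kernel, C=c, gamma=gamma)
        return _lsvm.predict(Xte, *model[:7], svm_type=0, kernel=kernel, gamma=gamma)
    clf = SVC(C=c, gamma=gamma, kernel=kernel).fit(Xtr, ytr)
    return clf.predict(Xte)


def _cv_accuracy_grid(X: np.ndarray, y: np.ndarray, folds, c_grid, gamma_grid):
    """Pooled inner-CV accuracy for every (C, gamma); returns (best_acc, best_params)."""
    n = y.shape[0]
    yf = np.asarray(y, dtype=np.float64)
    correct = np.zeros((len(c_grid), len(gamma_grid)), dtype=np.int64)
    for tr, te in folds:
        Xtr = np.ascontiguousarray(X[tr], dtype=np.float64)
        Xte = np.ascontiguousarray(X[te], dtype=np.float64)
        ytr, yte = yf[tr], yf[te]
        for i, c in enumerate(c_grid):
            for j, g in enumerate(gamma_grid):
                preds = _svm_fit_predict(Xtr, ytr, Xte, c=float(c), gamma=float(g))
                correct[i, j] += int(np.sum(preds == yte))
    best_acc, best_params = -1.0, None
    for i, c in enumerate(c_grid):
        for j, g in enumerate(gamma_grid):
            acc = correct[i, j] / n
            if acc > best_acc:
                best_acc, best_params = acc, {"C": float(c), "gamma": float(g)}
    return best_acc, best_params


def sfs_select(X: pd.DataFrame, y: np.ndarray, spec: ModelSpec,
               feature_order: list[str] | None = None):
    """Sequential forward selection of up to ``max_features`` features.

    At each step the feature whose addition maximizes inner stratified
    CV accuracy of an RBF SVM (grid-searched jointly over C and gamma) is
    added; ties prefer the lower-prefilter-rank feature.  The returned
    subset is the prefix with the best inner-CV accuracy (ties prefer
    fewer features), together with its tuned hyperparameters.

    The input is assumed already imputed and standardized.
    """
    spec.validate()
    candidates = list(feature_order) if feature_order is not None else list(X.columns)
    y = np.asarray(y)
    folds = _inner_folds(y, spec.inner_folds, spec.seed)
    Xv = X[candidates].to_numpy(dtype=float)
    col_of = {f: i for i, f in enumerate(candidates)}

    selected: list[str] = []
    history: list[tuple[float, list[str], dict]] = []
    for _step in range(min(spec.max_features, len(candidates))):
        best = None  # (acc, cand_rank, name, params)
        sel_idx = [col_of[f] for f in selected]
        for rank, name in enumerate(candidates):
            if name in selected:
                continue
            cols = sel_idx + [col_of[name]]
            acc, params = _cv_accuracy_grid(Xv[:, cols], y, folds,
                                            spec.c_grid, spec.gamma_grid)
            if best is None or acc > best[0] or (acc == best[0] and rank < best[1]):
                best = (acc, rank, name, params)
        acc, _rank, name, params = best
        selected.append(name)
        history.append((acc, list(selected), params))

    best_acc = max(h[0] for h in history)
    for acc, sel, params in history:  # first hit = fewest features
        if acc == best_acc:
            return sel, params, acc
    raise AssertionError("unreachable")


def _tune_family(X: np.ndarray, y: np.ndarray, spec: ModelSpec, folds) -> tuple[object, dict]:
    """Fit the final model for the spec's family, tuning by pooled inner-CV accuracy."""
    n = y.shape[0]
    if spec.family == "svm_rbf":
        _, params = _cv_accuracy_grid(X, y, folds, spec.c_grid, spec.gamma_grid)
        model = SVC(kernel="rbf", **params)
    elif spec.family == "svm_linear":
        best_acc, best_c = -1.0, None
        yf = np.asarray(y, dtype=np.float64)
        for c in spec.c_grid:
            correct = 0
            for tr, te in folds:
                Xtr = np.ascontiguousarray(X[tr], dtype=np.float64)
                Xte = np.ascontiguousarray(X[te], dtype=np.float64)
                preds = _svm_fit_predict(Xtr, yf[tr], Xte, c=float(c), gamma=1.0,
                                         kernel="linear")
                correct += int(np.sum(preds == yf[te]))
            acc = correct / n
            if acc > best_acc:
                best_acc, best_c = acc, float(c)
        params = {"C": best_c}
        model = SVC(kernel="linear", C=best_c)
    else:  # lasso: L1-regularized logistic regression
        best_acc, best_c = -1.0, None
        for c in spec.lasso_cs():
            correct = 0
            for tr, te in folds:
                clf = LogisticRegression(penalty="l1", C=c, solver="liblinear", max_iter=500)
                clf.fit(X[tr], y[tr])
                correct += int(np.sum(clf.predict(X[te]) == y[te]))
            acc = correct / n
            if acc > best_acc:
                best_acc, best_c = acc, float(c)
        params = {"C": best_c}
        model = LogisticRegression(penalty="l1", C=best_c, solver="liblinear", max_iter=500)
    model.fit(X, y)
    return model, params


@dataclass
class _FoldPrep:
    """Training-fold preprocessing state (median imputer + standardizer)."""

    medians: pd.Series
    means: pd.Series
    sds: pd.Series
    columns: list[str]

    @classmethod
    def fit(cls, X: pd.DataFrame) -> "_FoldPrep":
        keep = [c for c in X.columns if X[c].notna().any()]
        Xk = X[keep]
        med = Xk.median()
        filled = Xk.fillna(med)
        means = filled.mean()
        sds = filled.std(ddof=0).replace(0.0, 1.0)
        return cls(medians=med, means=means, sds=sds, columns=keep)

    def transform(self, X: pd.DataFrame) -> pd.DataFrame:
        return (X[self.columns].fillna(self.medians) - self.means) / self.sds


def loco_cv(X: pd.DataFrame, labels, cohorts: pd.Series,
            spec: ModelSpec | None = None, outcome: str = "") -> EvaluationResult:
    """Leave-one-cohort-out evaluation of the full nested protocol.

    Parameters
    ----------
    X : DataFrame indexed by participant id (features may contain NaN).
    labels : LabelSet or Series mapping participant id -> {0, 1}.
    cohorts : Series mapping participant id -> cohort label.
    spec : ModelSpec.

    A fold is skipped (with a warning) when its training or test side
    lacks one of the classes.  Every labeled participant appearing in a
    completed fold is predicted exactly once.
    """
    spec = spec or ModelSpec()
    spec.validate()
    y_all = labels.series() if hasattr(labels, "series") else pd.Series(labels)
    ids = [i for i in y_all.index if i in X.index]
    missing_cohort = [i for i in ids if i not in cohorts.index or pd.isna(cohorts.loc[i])]
    if missing_cohort:
        raise ProtocolError(f"cohort label missing for participants: {missing_cohort[:5]}")
    y_all = y_all.loc[ids]
    coh = cohorts.loc[ids]
    fold_labels = sorted(coh.unique())
    if len(fold_labels) < 2:
        raise ProtocolError("need at least 2 cohorts for leave-one-cohort-out")

    folds: list[FoldResult] = []
    for fold_i, cohort in enumerate(fold_labels):
        test_ids = [i for i in ids if coh.loc[i] == cohort]
        train_ids = [i for i in ids if coh.loc[i] != cohort]
        y_tr = y_all.loc[train_ids].to_numpy()
        y_te = y_all.loc[test_ids].to_numpy()
        if len(np.unique(y_tr)) < 2 or len(np.unique(y_te)) < 2:
            logger.warning("fold %s skipped: a class is absent", cohort)
            continue

        fold_seed = (spec.seed * 1000 + fold_i) % (2**31)
        fold_spec = ModelSpec(**{**spec.__dict__, "seed": fold_seed})
        prep = _FoldPrep.fit(X.loc[train_ids])
        Xtr = prep.transform(X.loc[train_ids])
        Xte = prep.transform(X.loc[test_ids])
        inner = _inner_folds(y_tr, spec.inner_folds, fold_seed)

        if spec.family in ("svm_rbf", "svm_linear"):
            ranked = ttest_prefilter(Xtr, y_tr, k=spec.prefilter_k)
            selected, rbf_params, _acc = sfs_select(Xtr[ranked], y_tr, fold_spec,
                                                    feature_order=ranked)
            Xs, Xs_te = Xtr[selected].to_numpy(), Xte[selected].to_numpy()
            if spec.family == "svm_rbf":
                model = SVC(kernel="rbf", **rbf_params).fit(Xs, y_tr)
                params = rbf_params
            else:
                model, params = _tune_family(Xs, y_tr, fold_spec, inner)
            preds = model.predict(Xs_te)
        else:  # lasso: all features, penalty by inner CV
            selected_cols = list(Xtr.columns)
            model, params = _tune_family(Xtr.to_numpy(), y_tr, fold_spec, inner)
            preds = model.predict(Xte.to_numpy())
            coefs = model.coef_.ravel()
            selected = [c for c, w in zip(selected_cols, coefs) if w != 0.0]

        folds.append(FoldResult(cohort=cohort, train_ids=train_ids, test_ids=test_ids,
                                selected_features=selected, hyperparameters=params,
                                predictions=np.asarray(preds), truths=y_te))

    if not folds:
        raise ProtocolError("no fold could be evaluated")
    all_ids = [i for f in folds for i in f.test_ids]
    preds = np.concatenate([f.predictions for f in folds])
    truths = np.concatenate([f.truths for f in folds])
    correct = int(np.sum(preds == truths))
    acc = correct / len(all_ids)
    ci = adjusted_wald_ci(correct, len(all_ids))
    freq = selection_frequency([f.selected_features for f in folds])
    return EvaluationResult(
        outcome=outcome or getattr(labels, "outcome", ""),
        family=spec.family,
        ids=all_ids,
        predictions=preds,
        truths=truths,
        accuracy=acc,
        accuracy_ci=ci,
        f1=f1_score(preds, truths),
        folds=folds,
        selection_frequency=freq,
    )
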