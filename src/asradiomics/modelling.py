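"""LOOCV predictive modelling: classifier grid, AUC with DeLong CI,
sensitivity/specificity trade-off table.

Every (feature set, selector, classifier) cell is evaluated by leave-one-out
cross-validation.  Inside each fold the training lesions are z-scored, the
filter selector is re-run on the training fold only (no selection leakage;
``selection_scope='global'`` reproduces the alternative reading where
selection is done once on the full cohort), tunable hyperparameters (KNN's
k, the elastic net's regularisation strength, the SVM's C) are chosen by
inner stratified 3-fold CV, and the held-out lesion is scored with the
progressor class probability (decision value for the SVM, which is
rank-equivalent).

AUC is the Mann-Whitney pair statistic with ties counted 1/2; its 95% CI is
DeLong's.  An elastic net whose coefficients shrink to zero in every fold is
reported as ``intercept_only`` and carries no AUC, mirroring how
regularised cells are blanked in the heatmap.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.discriminant_analysis import LinearDiscriminantAnalysis
from sklearn.ensemble import RandomForestClassifier
from sklearn.linear_model import LogisticRegression
from sklearn.model_selection import StratifiedKFold
from sklearn.neighbors import KNeighborsClassifier
from sklearn.preprocessing import StandardScaler
from sklearn.svm import SVC

from .selection import TOP_K, score_features

CLASSIFIERS = ("KNN", "LG", "LDA", "GLMnet", "SVM", "RF")
SELECTORS = ("FSCR", "TSCR", "WLCX", "GINI", "MIM", "MRMR")

#: the seven feature-set panels of the evaluation grid
FEATURE_SETS = (
    "clinical",
    "t2w",
    "adc",
    "clinical+t2w+adc",
    "clinical+t2w",
    "clinical+adc",
    "t2w+adc",
)

SPEC_TARGETS = (0.70, 0.75, 0.80, 0.85, 0.90)


@dataclass
class CVResult:
    feature_set: str
    selector: str
    classifier: str
    scores: np.ndarray | None
    auc: float | None
    ci95: tuple[float, float] | None
    status: str = "ok"  # ok | intercept_only
    selected_features: list = field(default_factory=list)


def _kgrid(n_train: int):
    # inner 3-fold CV fits on ~2/3 of the training fold; k must not exceed that
    inner_fit = n_train - int(np.ceil(n_train / 3))
    return [k for k in (1, 3, 5, 7, 9) if k <= inner_fit] or [1]


def _inner_cv_score(model_factory, grid, Xtr, ytr, seed) -> object:
    """Pick the grid value with the best inner 3-fold CV AUC; return a fitted model."""
    if len(grid) == 1:
        best = grid[0]
    else:
        n_splits = min(3, int(np.bincount(ytr).min()))
        best, best_auc = grid[0], -np.inf
        if n_splits >= 2:
            skf = StratifiedKFold(n_splits=n_splits, shuffle=True, random_state=seed)
            for g in grid:
                scores, truth = [], []
                for tr, va in skf.split(Xtr, ytr):
                    m = model_factory(g)
                    m.fit(Xtr[tr], ytr[tr])
                    scores.append(_score_samples(m, Xtr[va]))
                    truth.append(ytr[va])
                a = auc(np.concatenate(scores), np.concatenate(truth))
                if a > best_auc:
                    best, best_auc = g, a
    model = model_factory(best)
    model.fit(Xtr, ytr)
    return model


def _score_samples(model, X) -> np.ndarray:
    if hasattr(model, "predict_proba"):
        return model.predict_proba(X)[:, 1]
    return model.decision_function(X)


def _fit_classifier(name: str, Xtr: np.ndarray, ytr: np.ndarray, seed: int):
    if name == "KNN":
        return _inner_cv_score(
            lambda k: KNeighborsClassifier(n_neighbors=k), _kgrid(len(ytr)), Xtr, ytr, seed
        )
    if name == "LG":
        m = LogisticRegression(max_iter=2000)
        m.fit(Xtr, ytr)
        return m
    if name == "LDA":
        m = LinearDiscriminantAnalysis()
        m.fit(Xtr, ytr)
        return m
    if name == "GLMnet":
        return _inner_cv_score(
            lambda c: LogisticRegression(
                l1_ratio=0.5, C=c, solver="saga", max_iter=5000
            ),
            [0.01, 0.1, 1.0, 10.0],
            Xtr,
            ytr,
            seed,
        )
    if name == "SVM":
        return _inner_cv_score(
            lambda c: SVC(kernel="rbf", C=c, gamma="scale"), [0.1, 1.0, 10.0], Xtr, ytr, seed
        )
    if name == "RF":
        m = RandomForestClassifier(n_estimators=100, random_state=seed)
        m.fit(Xtr, ytr)
        return m
    raise ValueError(f"unknown classifier {name!r}")


def loocv_scores(
    X: pd.DataFrame,
    y,
    selector: str,
    classifier: str,
    k: int,
    seed: int = 0,
    selection_scope: str = "fold",
) -> tuple[np.ndarray, str]:
    """Out-of-fold progressor scores for every lesion, plus a status flag."""
    y = np.asarray(y).astype(int)
    n = len(y)
    if n < 6:
        raise ValueError("LOOCV needs at least 6 lesions")
    if np.unique(y).size != 2:
        raise ValueError("both classes must be present")
    if selection_scope not in ("fold", "global"):
        raise ValueError("selection_scope must be 'fold' or 'global'")

    global_subset = None
    if selection_scope == "global":
        ranking = score_features(X, y, selector)
        global_subset = list(ranking.index[: min(k, X.shape[1])])

    scores = np.empty(n)
    intercept_only_folds = 0
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        ytr = y[tr]
        if np.unique(ytr).size != 2:
            raise ValueError("a training fold lost one class")
        if global_subset is None:
            ranking = score_features(X.loc[tr], ytr, selector)
            subset = list(ranking.index[: min(k, X.shape[1])])
        else:
            subset = global_subset
        scaler = StandardScaler().fit(X.loc[tr, subset])
        Xtr = scaler.transform(X.loc[tr, subset])
        Xte = scaler.transform(X.loc[~tr, subset])
        model = _fit_classifier(classifier, Xtr, ytr, seed)
        if classifier == "GLMnet" and np.all(np.abs(model.coef_) < 1e-10):
            intercept_only_folds += 1
        scores[i] = _score_samples(model, Xte)[0]
    status = "intercept_only" if (classifier == "GLMnet" and intercept_only_folds == n) else "ok"
    return scores, status


# ---------------------------------------------------------------------------
# AUC, DeLong CI, sensitivity/specificity
# ---------------------------------------------------------------------------

def auc(scores, y) -> float:
    """Mann-Whitney AUC with ties counted 1/2."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    if pos.size == 0 or neg.size == 0:
        raise ValueError("both classes must be present")
    if np.ptp(scores) == 0:
        return 0.5
    diff = pos[:, None] - neg[None, :]
    return float((np.sum(diff > 0) + 0.5 * np.sum(diff == 0)) / (pos.size * neg.size))


def _midranks(x: np.ndarray) -> np.ndarray:
    return stats.rankdata(x, method="average")


def auc_ci(scores, y, level: float = 0.95) -> tuple[float, float]:
    """DeLong 95% CI for the AUC of one score vector, clipped to [0, 1]."""
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos = scores[y == 1]
    neg = scores[y == 0]
    m, n = pos.size, neg.size
    if m == 0 or n == 0:
        raise ValueError("both classes must be present")
    tx = _midranks(pos)
    ty = _midranks(neg)
    tz = _midranks(np.concatenate([pos, neg]))
    a = auc(scores, y)
    v01 = (tz[:m] - tx) / n  # per-positive placement values
    v10 = 1.0 - (tz[m:] - ty) / m  # per-negative
    s01 = v01.var(ddof=1) if m > 1 else 0.0
    s10 = v10.var(ddof=1) if n > 1 else 0.0
    se = np.sqrt(s01 / m + s10 / n)
    z = stats.norm.ppf(0.5 + level / 2)
    return (float(max(0.0, a - z * se)), float(min(1.0, a + z * se)))


def sens_spec_table(scores, y, targets=SPEC_TARGETS) -> pd.DataFrame:
    """Best achievable partner value on the empirical ROC per target.

    For each target specificity, the largest sensitivity over thresholds with
    specificity >= target; symmetrically for target sensitivity.  No
    interpolation — thresholds are the observed score values (plus one above
    the maximum).
    """
    scores = np.asarray(scores, dtype=float)
    y = np.asarray(y).astype(int)
    pos, neg = scores[y == 1], scores[y == 0]
    thresholds = np.concatenate([np.unique(scores), [np.inf]])
    sens = np.array([(pos >= t).mean() for t in thresholds])
    spec = np.array([(neg < t).mean() for t in thresholds])
    rows = []
    for t in targets:
        ok_spec = spec >= t - 1e-12
        best_sens = float(sens[ok_spec].max()) if ok_spec.any() else 0.0
        ok_sens = sens >= t - 1e-12
        best_spec = float(spec[ok_sens].max()) if ok_sens.any() else 0.0
        rows.append((t, best_sens, best_spec))
    return pd.DataFrame(rows, columns=["target", "sensitivity_at_specificity", "specificity_at_sensitivity"])


# ---------------------------------------------------------------------------
# The evaluation grid
# ---------------------------------------------------------------------------

def _set_type(feature_set: str) -> str:
    if feature_set == "clinical":
        return "clinical"
    if "+" in feature_set:
        return "combined"
    return "radiomic"


def assemble_feature_set(tables: dict[str, pd.DataFrame], feature_set: str) -> pd.DataFrame:
    parts = []
    for part in feature_set.split("+"):
        if part not in tables:
            raise ValueError(f"missing feature table {part!r}")
        t = tables[part]
        parts.append(t.add_prefix(f"{part}_") if part != "clinical" else t)
    return pd.concat(parts, axis=1)


def run_grid(
    tables: dict[str, pd.DataFrame],
    y,
    seed: int = 0,
    feature_sets=FEATURE_SETS,
    selectors=SELECTORS,
    classifiers=CLASSIFIERS,
    selection_scope: str = "fold",
) -> list[CVResult]:
    """Evaluate every (feature set, selector, classifier) cell by LOOCV."""
    y = np.asarray(y).astype(int)
    results = []
    for fs, sel, clf in itertools.product(feature_sets, selectors, classifiers):
        X = assemble_feature_set(tables, fs)
        k = TOP_K[_set_type(fs)]
        scores, status = loocv_scores(
            X, y, sel, clf, k, seed=seed, selection_scope=selection_scope
        )
        if status == "intercept_only":
            results.append(CVResult(fs, sel, clf, None, None, None, status))
        else:
            a = auc(scores, y)
            results.append(CVResult(fs, sel, clf, scores, a, auc_ci(scores, y), status))
    return results


def grid_table(results: list[CVResult]) -> pd.DataFrame:
    """Flatten grid results into the heatmap CSV layout."""
    rows = [
        (
            r.feature_set,
            r.selector,
            r.classifier,
            r.auc,
            r.ci95[0] if r.ci95 else None,
            r.ci95[1] if r.ci95 else None,
            r.status,
        )
        for r in results
    ]
    return pd.DataFrame(
        rows, columns=["feature_set", "selector", "classifier", "auc", "ci_lo", "ci_hi", "status"]
    )
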