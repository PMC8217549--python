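"""Filter feature selection: FSCR, TSCR, WLCX, GINI, MIM, MRMR.

Six filter methods rank candidate features against the binary progression
label; the top k are kept, with k fixed by feature-set type: 5 for the
clinical table, 10 for a single-sequence radiomic table, 15 for any
combination.  Higher score = better for every method; ties break by feature
name so rankings are deterministic.

Standard definitions (the methods are named, not specified, in the source
literature of this pipeline, so the conventional formulas are frozen here):

* FSCR  — Fisher score: between-class scatter over within-class scatter,
          (n1 (mu1-mu)^2 + n2 (mu2-mu)^2) / (n1 s1^2 + n2 s2^2).
* TSCR  — Welch t magnitude |mu1 - mu2| / sqrt(s1^2/n1 + s2^2/n2).
* WLCX  — two-sided rank-sum distance from its null mean, |U - n1 n2 / 2|
          (invariant under strictly monotone feature transforms).
* GINI  — impurity decrease of the best single threshold split.
* MIM   — mutual information with the label after equal-frequency
          discretisation into ceil(sqrt(n)) bins.
* MRMR  — greedy forward selection maximising MI(f; y) minus the mean MI
          of f with the already-selected set.

Class variances use ddof=0; a zero-variance (constant) feature scores 0 for
every method.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

METHODS = ("FSCR", "TSCR", "WLCX", "GINI", "MIM", "MRMR")

#: top-k per feature-set type
TOP_K = {"clinical": 5, "radiomic": 10, "combined": 15}


@dataclass
class SelectionResult:
    method: str
    ranking: pd.Series  # scores indexed by feature, descending
    k: int
    selected: list[str]


def _check_xy(X: pd.DataFrame, y: np.ndarray) -> np.ndarray:
    y = np.asarray(y).astype(int)
    classes = np.unique(y)
    if classes.size != 2:
        raise ValueError("labels must contain exactly two classes")
    if min(np.sum(y == c) for c in classes) < 2:
        raise ValueError("need >= 2 lesions per class")
    return y


def _fisher(x, y):
    mu = x.mean()
    out = 0.0
    num = den = 0.0
    for c in np.unique(y):
        xc = x[y == c]
        num += xc.size * (xc.mean() - mu) ** 2
        den += xc.size * xc.var(ddof=0)
    return num / den if den > 0 else 0.0


def _tscore(x, y):
    c0, c1 = np.unique(y)
    a, b = x[y == c0], x[y == c1]
    se2 = a.var(ddof=0) / a.size + b.var(ddof=0) / b.size
    return abs(a.mean() - b.mean()) / np.sqrt(se2) if se2 > 0 else 0.0


def _wilcoxon(x, y):
    c0, c1 = np.unique(y)
    n1 = int((y == c1).sum())
    n2 = int((y == c0).sum())
    from scipy.stats import rankdata

    ranks = rankdata(x, method="average")
    u = ranks[y == c1].sum() - n1 * (n1 + 1) / 2
    return abs(u - n1 * n2 / 2)


def _gini(x, y):
    n = y.size
    p1 = y.mean()
    parent = 2 * p1 * (1 - p1)
    order = np.argsort(x, kind="stable")
    xs, ys = x[order], y[order]
    cum1 = np.cumsum(ys)
    idx = np.arange(1, n)
    valid = xs[1:] != xs[:-1]
    if not valid.any():
        return 0.0
    nl = idx[valid].astype(float)
    nr = n - nl
    p1l = cum1[:-1][valid] / nl
    p1r = (cum1[-1] - cum1[:-1][valid]) / nr
    child = (nl / n) * 2 * p1l * (1 - p1l) + (nr / n) * 2 * p1r * (1 - p1r)
    return float(parent - child.min())


def equal_frequency_bins(x: np.ndarray, n_bins: int | None = None) -> np.ndarray:
    """Equal-frequency discretisation into ceil(sqrt(n)) bins by default."""
    n = x.size
    if n_bins is None:
        n_bins = int(np.ceil(np.sqrt(n)))
    qs = np.quantile(x, np.linspace(0, 1, n_bins + 1)[1:-1])
    return np.searchsorted(qs, x, side="left")


def mutual_information(a: np.ndarray, b: np.ndarray) -> float:
    """MI (nats) of two discrete label vectors from their contingency table."""
    ua, ia = np.unique(a, return_inverse=True)
    ub, ib = np.unique(b, return_inverse=True)
    cont = np.zeros((ua.size, ub.size))
    np.add.at(cont, (ia, ib), 1.0)
    p = cont / cont.sum()
    px = p.sum(axis=1, keepdims=True)
    py = p.sum(axis=0, keepdims=True)
    nz = p > 0
    return float(np.sum(p[nz] * np.log(p[nz] / (px @ py)[nz])))


def _mim(x, y):
    if np.ptp(x) == 0:
        return 0.0
    return mutual_information(equal_frequency_bins(x), y)


_SCORERS = {
    "FSCR": _fisher,
    "TSCR": _tscore,
    "WLCX": _wilcoxon,
    "GINI": _gini,
    "MIM": _mim,
}


def score_features(X: pd.DataFrame, y, method: str) -> pd.Series:
    """Score every feature; return scores sorted descending (ties by name)."""
    if method not in METHODS:
        raise ValueError(f"unknown method {method!r}")
    y = _check_xy(X, y)
    if method == "MRMR":
        order = mrmr_select(X, y, k=X.shape[1])
        # ranks as pseudo-scores so the interface is uniform
        scores = pd.Series(
            {f: float(len(order) - i) for i, f in enumerate(order)}, name="MRMR"
        )
        return scores.loc[order]
    scorer = _SCORERS[method]
    scores = pd.Series(
        {c: float(scorer(X[c].to_numpy(dtype=float), y)) for c in X.columns},
        name=method,
    )
    order = sorted(scores.index, key=lambda f: (-scores[f], f))
    return scores.loc[order]


def mrmr_select(X: pd.DataFrame, y, k: int) -> list[str]:
    """Greedy mRMR: maximise MI(f;y) - mean MI(f; selected)."""
    y = _check_xy(X, y)
    feats = list(X.columns)
    if k > len(feats):
        import warnings

        warnings.warn("k exceeds candidate count; truncating")
        k = len(feats)
    disc = {c: equal_frequency_bins(X[c].to_numpy(dtype=float)) for c in feats}
    relevance = {c: (_mim(X[c].to_numpy(dtype=float), y)) for c in feats}
    selected: list[str] = []
    red_cache: dict[tuple[str, str], float] = {}
    while len(selected) < k:
        best, best_score = None, -np.inf
        for f in feats:
            if f in selected:
                continue
            if selected:
                reds = []
                for s in selected:
                    key = (f, s)
                    if key not in red_cache:
                        red_cache[key] = mutual_information(disc[f], disc[s])
                    reds.append(red_cache[key])
                score = relevance[f] - float(np.mean(reds))
            else:
                score = relevance[f]
            if score > best_score or (score == best_score and best is not None and f < best):
                best, best_score = f, score
        selected.append(best)
    return selected


def top_k(result_or_ranking, feature_set_type: str) -> list[str]:
    """First k of a ranking, with k fixed by feature-set type."""
    if feature_set_type not in TOP_K:
        raise ValueError(
            f"unknown feature-set type {feature_set_type!r}; expected one of {sorted(TOP_K)}"
        )
    k = TOP_K[feature_set_type]
    if isinstance(result_or_ranking, SelectionResult):
        names = list(result_or_ranking.ranking.index)
    elif isinstance(result_or_ranking, pd.Series):
        names = list(result_or_ranking.index)
    else:
        names = list(result_or_ranking)
    return names[:k]


def select(X: pd.DataFrame, y, method: str, feature_set_type: str) -> SelectionResult:
    """Rank with one method and keep the top k for the feature-set type."""
    ranking = score_features(X, y, method)
    k = TOP_K[feature_set_type]
    chosen = list(ranking.index[: min(k, len(ranking))])
    return SelectionResult(method, ranking, k, chosen)
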