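"""Acquisition-parameter decoupling via Spearman correlation.

Robust features may still track scanner settings rather than biology.  Each
robust feature is tested against the six MRI acquisition parameters (TE, TR,
flip angle, slice thickness, spacing between slices, pixel spacing) with
Spearman's rank correlation; a feature is flagged dependent — and removed —
iff p < alpha for any parameter.  No multiple-testing correction is applied
(single-threshold rule); alpha is configurable, defaulting to 0.001.

A parameter that is constant across the cohort (common for single-scanner
metadata) has no defined rank correlation; it is reported with rho = 0,
p = 1 and flagged "degenerate parameter".
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

from .core import ACQUISITION_PARAMS

DEFAULT_ALPHA = 0.001


@dataclass
class DecouplingResult:
    table: pd.DataFrame  # columns: feature, parameter, rho, p
    retained: list[str] = field(default_factory=list)
    flagged: list[str] = field(default_factory=list)
    degenerate_params: list[str] = field(default_factory=list)
    alpha: float = DEFAULT_ALPHA


def spearman_test(x, y) -> tuple[float, float]:
    """Spearman rho and two-sided p (t-approximation, n-2 df), midrank ties.

    Constant input (zero rank variance) returns (0.0, 1.0).
    """
    x = np.asarray(x, dtype=float)
    y = np.asarray(y, dtype=float)
    if x.size != y.size:
        raise ValueError("x and y must have equal length")
    if x.size < 4:
        raise ValueError("Spearman test needs n >= 4")
    if not (np.isfinite(x).all() and np.isfinite(y).all()):
        raise ValueError("Spearman test requires finite values")
    if np.ptp(x) == 0 or np.ptp(y) == 0:
        return 0.0, 1.0
    rho, p = stats.spearmanr(x, y)
    if np.isnan(rho):
        return 0.0, 1.0
    return float(rho), float(p)


def decouple_features(
    features,
    acquisition,
    alpha: float = DEFAULT_ALPHA,
    params=ACQUISITION_PARAMS,
) -> DecouplingResult:
    """Flag features correlated with any acquisition parameter.

    ``features``: lesions x features DataFrame (the robust set);
    ``acquisition``: lesions x parameters DataFrame, aligned by position.
    """
    missing = [p for p in params if p not in acquisition.columns]
    if missing:
        raise ValueError(f"missing acquisition column(s): {missing}")
    if len(features) != len(acquisition):
        raise ValueError("features and acquisition tables differ in length")

    rows = []
    degenerate = [p for p in params if np.ptp(acquisition[p].to_numpy(dtype=float)) == 0]
    for feat in features.columns:
        fv = features[feat].to_numpy(dtype=float)
        for p in params:
            rho, pv = spearman_test(fv, acquisition[p].to_numpy(dtype=float))
            rows.append((feat, p, rho, pv))
    table = pd.DataFrame(rows, columns=["feature", "parameter", "rho", "p"])
    flagged = sorted(table.loc[table.p < alpha, "feature"].unique())
    retained = [f for f in features.columns if f not in flagged]
    return DecouplingResult(table, retained, flagged, degenerate, alpha)
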