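"""ICC(3,1) robustness screening across mask perturbations and bin counts.

For each (sequence, bin count) configuration, every feature's stability
across the three mask versions (original, opening, closing) is quantified
by the intraclass correlation coefficient ICC(3,1) — two-way mixed-effects
model, consistency, single measurement:

    ICC(3,1) = (MS_R - MS_E) / (MS_R + (k - 1) MS_E)

with MS_R, MS_C, MS_E the two-way-ANOVA mean squares for rows (lesions),
columns (mask versions) and error.  A feature is "highly robust" iff
ICC > 0.8 (strict).  The operating bin count is the one maximising the
combined (T2WI + ADC) robust-feature count, ties broken toward the smaller
bin count.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .core import BIN_COUNTS, MASK_VERSIONS, SEQUENCES

logger = logging.getLogger(__name__)

ICC_THRESHOLD = 0.8


@dataclass
class ICCComponents:
    ms_r: float
    ms_c: float
    ms_e: float
    n: int
    k: int


@dataclass
class RobustnessReport:
    """Per-(sequence, bin count) ICC values and robust-feature counts."""

    icc: pd.DataFrame  # columns: sequence, n_bins, feature, icc
    counts: pd.DataFrame  # index n_bins, columns per sequence + 'combined'
    threshold: float
    selected_n_bins: int | None = None
    non_evaluable: list = field(default_factory=list)  # (sequence, n_bins, feature)

    def robust_features(self, sequence: str, n_bins: int | None = None) -> list[str]:
        nb = self.selected_n_bins if n_bins is None else n_bins
        sub = self.icc[(self.icc.sequence == sequence) & (self.icc.n_bins == nb)]
        return sorted(sub.loc[sub.icc > self.threshold, "feature"])


def icc31(values: np.ndarray) -> tuple[float, ICCComponents]:
    """ICC(3,1) of a subjects x raters matrix via two-way ANOVA mean squares.

    NaN entries make the result NaN (the feature is non-evaluable and is
    treated as non-robust by the screen).  The degenerate case
    MS_R = MS_E = 0 returns 0.
    """
    y = np.asarray(values, dtype=float)
    if y.ndim != 2:
        raise ValueError("values must be a 2D subjects x raters matrix")
    n, k = y.shape
    if n < 2 or k < 2:
        raise ValueError("ICC needs >= 2 subjects and >= 2 raters")
    if (n - 1) * (k - 1) == 0:
        raise ValueError("zero error degrees of freedom")
    if np.isnan(y).any():
        return float("nan"), ICCComponents(np.nan, np.nan, np.nan, n, k)
    grand = y.mean()
    ss_rows = k * np.sum((y.mean(axis=1) - grand) ** 2)
    ss_cols = n * np.sum((y.mean(axis=0) - grand) ** 2)
    ss_tot = np.sum((y - grand) ** 2)
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = max(ss_err, 0.0) / ((n - 1) * (k - 1))
    comp = ICCComponents(ms_r, ms_c, ms_e, n, k)
    num = ms_r - ms_e
    den = ms_r + (k - 1) * ms_e
    if den == 0:
        return (0.0 if num == 0 else float("nan")), comp
    return float(num / den), comp


def robustness_screen(
    features: pd.DataFrame,
    threshold: float = ICC_THRESHOLD,
    bin_counts=BIN_COUNTS,
    sequences=SEQUENCES,
) -> RobustnessReport:
    """Screen a long-format feature table for robustness across mask versions.

    ``features`` columns: lesion_id, sequence, mask_version, n_bins, feature,
    value — one row per (lesion, configuration, feature).  For every
    (sequence, n_bins) each feature needs all three mask versions for every
    lesion; missing versions raise with the offending lesions named.
    """
    required = {"lesion_id", "sequence", "mask_version", "n_bins", "feature", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table missing columns: {sorted(missing)}")

    icc_rows = []
    non_evaluable = []
    for seq in sequences:
        for nb in bin_counts:
            sub = features[(features.sequence == seq) & (features.n_bins == nb)]
            if sub.empty:
                raise ValueError(f"no features for sequence={seq}, n_bins={nb}")
            wide = sub.pivot_table(
                index=["feature", "lesion_id"],
                columns="mask_version",
                values="value",
                aggfunc="first",
            )
            wide = wide.reindex(columns=list(MASK_VERSIONS))
            # NaN here means a (lesion, version) cell absent from the input;
            # a NaN feature *value* is legal and handled by icc31
            provided = sub.groupby(["feature", "lesion_id"]).mask_version.nunique()
            incomplete = provided[provided < len(MASK_VERSIONS)]
            if not incomplete.empty:
                bad = sorted(incomplete.index.get_level_values("lesion_id").unique())
                raise ValueError(
                    f"missing mask version(s) for sequence={seq}, n_bins={nb}: "
                    f"lesions {bad}"
                )
            for feat, block in wide.groupby(level="feature", sort=True):
                mat = block.to_numpy()
                val, _ = icc31(mat) if not np.isnan(mat).any() else (float("nan"), None)
                if np.isnan(val):
                    non_evaluable.append((seq, nb, feat))
                icc_rows.append((seq, nb, feat, val))

    icc = pd.DataFrame(icc_rows, columns=["sequence", "n_bins", "feature", "icc"])
    counts = (
        icc.assign(robust=icc.icc > threshold)
        .pivot_table(index="n_bins", columns="sequence", values="robust", aggfunc="sum")
        .reindex(list(bin_counts))
        .astype(int)
    )
    counts["combined"] = counts[list(sequences)].sum(axis=1)
    report = RobustnessReport(icc, counts, threshold, non_evaluable=non_evaluable)
    report.selected_n_bins = select_bin_count(report)
    return report


def select_bin_count(report: RobustnessReport) -> int:
    """Bin count with the highest combined robust count (ties -> smaller)."""
    counts = report.counts["combined"]
    if counts.empty:
        raise ValueError("empty robustness report")
    best = int(counts.index[np.argmax(counts.to_numpy())])  # argmax -> first = smallest
    logger.info("selected n_bins=%d (combined robust counts: %s)", best, counts.to_dict())
    return best
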