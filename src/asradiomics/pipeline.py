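"""End-to-end orchestration: simulate -> perturb -> extract -> calibrate ->
decouple -> grid, with a content-hashed run manifest.

Stage order is fixed (calibration and pre-processing before modelling; no
stage reads a later stage's output).  When a work directory is given, each
stage's artifact is written as CSV/JSON keyed by a content hash of the
configuration, so re-running with the same config reuses cached artifacts
and re-running with the same seed reproduces byte-identical manifests.
"""

from __future__ import annotations

import dataclasses
import hashlib
import json
import logging
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .calibration import RobustnessReport, robustness_screen
from .core import BIN_COUNTS, SEQUENCES
from .decoupling import DEFAULT_ALPHA, decouple_features
from .features import QuantisationConfig, extract_feature_vector
from .modelling import CLASSIFIERS, FEATURE_SETS, SELECTORS, grid_table, run_grid
from .perturb import mask_versions
from .synthetic import PhantomConfig, clinical_feature_table, generate_cohort

logger = logging.getLogger(__name__)


def _hash_obj(obj) -> str:
    return hashlib.sha256(
        json.dumps(obj, sort_keys=True, default=str).encode()
    ).hexdigest()[:16]


def _hash_df(df: pd.DataFrame) -> str:
    return hashlib.sha256(df.to_csv(index=False).encode()).hexdigest()[:16]


def extract_cohort_features(
    lesions,
    bin_counts=BIN_COUNTS,
    sequences=SEQUENCES,
    versions=("original", "opening", "closing"),
) -> pd.DataFrame:
    """Long-format feature table over lesions x sequences x masks x bins.

    Columns: lesion_id, sequence, mask_version, n_bins, feature, value.
    """
    rows = []
    for lesion in lesions:
        masks = mask_versions(lesion.mask)
        for seq in sequences:
            vol = lesion.volumes[seq]
            for ver in versions:
                for nb in bin_counts:
                    vec = extract_feature_vector(vol, masks[ver], QuantisationConfig(nb))
                    for name, val in vec.items():
                        if name in ("sequence", "mask_version", "n_bins"):
                            continue
                        rows.append((lesion.lesion_id, seq, ver, nb, name, val))
    return pd.DataFrame(
        rows, columns=["lesion_id", "sequence", "mask_version", "n_bins", "feature", "value"]
    )


def radiomic_tables(
    long_features: pd.DataFrame,
    report: RobustnessReport,
    cohort: pd.DataFrame,
    alpha: float = DEFAULT_ALPHA,
):
    """Wide per-sequence tables of robust, acquisition-decoupled features.

    Returns ({'t2w': df, 'adc': df}, {'t2w': DecouplingResult, ...}).
    Values come from the *original* mask at the selected bin count.
    """
    nb = report.selected_n_bins
    acq = cohort.set_index("lesion_id")
    tables, decs = {}, {}
    for seq, key in (("T2W", "t2w"), ("ADC", "adc")):
        robust = report.robust_features(seq, nb)
        sub = long_features[
            (long_features.sequence == seq)
            & (long_features.n_bins == nb)
            & (long_features.mask_version == "original")
            & (long_features.feature.isin(robust))
        ]
        wide = sub.pivot_table(index="lesion_id", columns="feature", values="value")
        wide = wide.reindex(acq.index)
        dec = decouple_features(wide, acq, alpha=alpha)
        decs[key] = dec
        tables[key] = wide[dec.retained].reset_index(drop=True)
    return tables, decs


def run_experiment(
    config: PhantomConfig,
    bin_counts=BIN_COUNTS,
    selectors=SELECTORS,
    classifiers=CLASSIFIERS,
    feature_sets=FEATURE_SETS,
    alpha: float = DEFAULT_ALPHA,
    selection_scope: str = "fold",
    workdir: str | Path | None = None,
) -> dict:
    """Run the full pipeline; return the manifest with all stage artifacts.

    The manifest contains the config hash, seed, Table-2-shaped robust
    counts, selected bin count, retained-after-decoupling counts, the grid
    summary table and content hashes of every stage output.
    """
    cfg_key = _hash_obj(
        dict(
            config=dataclasses.asdict(config),
            bin_counts=list(bin_counts),
            selectors=list(selectors),
            classifiers=list(classifiers),
            feature_sets=list(feature_sets),
            alpha=alpha,
            selection_scope=selection_scope,
        )
    )
    wd = Path(workdir) if workdir is not None else None
    if wd is not None:
        wd.mkdir(parents=True, exist_ok=True)

    logger.info("stage 1/5: simulate cohort (%d lesions)", config.n_progressors + config.n_stable)
    lesions, cohort = generate_cohort(config)
    y = (cohort.label == "progressor").astype(int).to_numpy()

    logger.info("stage 2/5: perturb + extract (%d bin settings)", len(bin_counts))
    cache = wd / f"features_{cfg_key}.csv" if wd is not None else None
    if cache is not None and cache.exists():
        # round_trip parser: cached doubles must hash identically to fresh ones
        long_features = pd.read_csv(cache, float_precision="round_trip")
    else:
        long_features = extract_cohort_features(lesions, bin_counts=bin_counts)
        if cache is not None:
            long_features.to_csv(cache, index=False)

    logger.info("stage 3/5: ICC(3,1) robustness calibration")
    report = robustness_screen(long_features, bin_counts=bin_counts)

    logger.info("stage 4/5: acquisition decoupling (alpha=%g)", alpha)
    tables, decs = radiomic_tables(long_features, report, cohort, alpha=alpha)
    tables["clinical"] = clinical_feature_table(cohort)

    logger.info("stage 5/5: LOOCV grid (%d x %d x %d)", len(feature_sets), len(selectors), len(classifiers))
    results = run_grid(
        tables,
        y,
        seed=config.seed,
        feature_sets=feature_sets,
        selectors=selectors,
        classifiers=classifiers,
        selection_scope=selection_scope,
    )
    grid = grid_table(results)

    manifest = {
        "software_version": __version__,
        "config_hash": cfg_key,
        "seed": config.seed,
        "n_lesions": len(cohort),
        "selected_n_bins": int(report.selected_n_bins),
        "robust_counts": {
            str(nb): {c: int(report.counts.loc[nb, c]) for c in report.counts.columns}
            for nb in report.counts.index
        },
        "retained_after_decoupling": {k: len(t.columns) for k, t in tables.items() if k != "clinical"},
        "non_evaluable_features": len(report.non_evaluable),
        "grid_summary": {
            "n_cells": len(grid),
            "n_intercept_only": int((grid.status == "intercept_only").sum()),
            "best": (
                grid.loc[grid.auc.idxmax(), ["feature_set", "selector", "classifier", "auc"]].to_dict()
                if grid.auc.notna().any()
                else None
            ),
        },
        "hashes": {
            "cohort": _hash_df(cohort),
            "features": _hash_df(long_features),
            "grid": _hash_df(grid),
        },
    }
    artifacts = {
        "cohort": cohort,
        "features": long_features,
        "report": report,
        "decoupling": decs,
        "tables": tables,
        "grid": grid,
        "results": results,
    }
    if wd is not None:
        cohort.to_csv(wd / "cohort.csv", index=False)
        report.counts.to_csv(wd / "robust_counts.csv")
        grid.to_csv(wd / "grid.csv", index=False)
        (wd / "manifest.json").write_text(json.dumps(manifest, indent=2, default=str))
    manifest["artifacts"] = artifacts
    return manifest
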