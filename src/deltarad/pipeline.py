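"""End-to-end pipeline: simulate -> extract -> robustness -> delta ->
fit -> evaluate.

A :class:`RunConfig` describes a full run; :func:`run_pipeline`
executes the requested stages, persists every stage's outputs together
with the effective configuration (seeds included) under the run
directory, and is deterministic given an identical configuration.

In feature mode the cohort already consists of baseline/final feature
vectors, so the extraction stage is replaced by simulated
ROI-perturbation replicates; in image mode features are extracted from
the generated volumes over the bin-count grid with original, opened
and closed masks.
"""

from __future__ import annotations

import dataclasses
import json
import logging
import time
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd

from . import __version__
from .evaluation import (
    dichotomise_precise,
    evaluate_predictions,
    loocv,
    report_table,
)
from .features import FEATURE_CLASSES, MaskEmptiedError, extract_features, perturb_mask
from .io import save_long_features, write_json
from .modeling import MODEL_NAMES, delta_matrix, get_model
from .robustness import acquisition_screen, compute_robustness, select_bins
from .synthetic import (
    CohortConfig,
    MODALITIES,
    SyntheticCohort,
    assign_precise_scores,
    generate_cohort,
    perturbation_replicate_tables,
)

__all__ = ["RunConfig", "run_pipeline", "extract_cohort_features"]

log = logging.getLogger(__name__)

DEFAULT_BINS_GRID = (8, 16, 32, 64, 128, 256)


@dataclass
class RunConfig:
    """Serialisable configuration of a full pipeline run."""

    cohort: CohortConfig = field(default_factory=CohortConfig)
    models: tuple[str, ...] = MODEL_NAMES
    bins_grid: tuple[int, ...] = DEFAULT_BINS_GRID
    feature_classes: tuple[str, ...] = FEATURE_CLASSES
    icc_threshold: float = 0.8
    icc_variant: str = "consistency"
    tie_policy: str = "largest-of-tied"
    bootstrap_replicates: int = 2000
    probability_threshold: float = 0.5
    reader_error_rate: float = 0.2
    fragile_fraction: float = 0.3
    seed: int = 42

    def __post_init__(self) -> None:
        unknown = set(self.models) - set(MODEL_NAMES)
        if unknown:
            raise ValueError(f"unknown models: {sorted(unknown)}")

    def to_json(self) -> str:
        d = dataclasses.asdict(self)
        return json.dumps(d, indent=2, sort_keys=True)

    @classmethod
    def from_json(cls, text: str) -> "RunConfig":
        d = json.loads(text)
        d["cohort"] = CohortConfig(**{
            k: tuple(v) if isinstance(v, list) else v
            for k, v in d["cohort"].items()
        })
        for k in ("models", "bins_grid", "feature_classes"):
            d[k] = tuple(d[k])
        return cls(**d)


def extract_cohort_features(
    cohort: SyntheticCohort,
    bins_grid=DEFAULT_BINS_GRID,
    classes=FEATURE_CLASSES,
) -> pd.DataFrame:
    """Long-format feature table over mask variants and bin counts.

    For every sample, modality and time point, features are extracted
    with the original, opened and closed masks at each bin count.
    Perturbations that empty a mask are skipped with a log entry; the
    affected sample simply lacks that replicate downstream.
    """
    if cohort.volumes is None:
        raise ValueError("cohort is not in image mode")
    rows = []
    for sid in cohort.sample_ids:
        for mod in MODALITIES:
            mask = cohort.masks[sid][mod]
            variants = {"original": mask}
            for mode, name in (("opening", "opened"), ("closing", "closed")):
                try:
                    variants[name] = perturb_mask(mask, mode)
                except MaskEmptiedError:
                    log.warning("%s of %s/%s emptied the mask; skipped",
                                mode, sid, mod)
            for tp, vol in cohort.volumes[sid][mod].items():
                for nb in bins_grid:
                    for vname, vmask in variants.items():
                        fv = extract_features(vol, vmask, nb, classes)
                        for fname, value in fv.values.items():
                            rows.append(
                                dict(sample_id=sid, modality=mod,
                                     time_point=tp, n_bins=nb, variant=vname,
                                     feature=fname, value=value)
                            )
    return pd.DataFrame(rows)


def _feature_mode_long_table(cohort, config: RunConfig):
    """Replicate tables for a feature-mode cohort, in long format."""
    rng = np.random.default_rng(config.seed + 17)
    p = cohort.config.n_features
    n_fragile = int(round(config.fragile_fraction * p))
    informative = set(cohort.ground_truth.tolist())
    candidates = [i for i in range(p) if i not in informative]
    fragile = rng.choice(candidates, size=min(n_fragile, len(candidates)),
                         replace=False)
    tables = perturbation_replicate_tables(cohort, fragile=fragile)
    rows = []
    for variant, tps in tables.items():
        for tp, tab in tps.items():
            stacked = tab.stack()
            for (sid, feat), value in stacked.items():
                rows.append(
                    dict(sample_id=sid, modality="SIM", time_point=tp,
                         n_bins=0, variant=variant, feature=feat, value=value)
                )
    return pd.DataFrame(rows), fragile


def _wide_tables(long_table: pd.DataFrame, n_bins: int, robust: dict):
    """Original-mask base/final wide tables over the robust feature set.

    Columns are prefixed with the modality so T2WI- and ADC-derived
    deltas can be concatenated into one matrix.
    """
    sel = long_table[
        (long_table.n_bins == n_bins) & (long_table.variant == "original")
    ]
    out = {}
    for tp in ("base", "final"):
        parts = []
        for mod, feats in robust.items():
            sub = sel[(sel.time_point == tp) & (sel.modality == mod)]
            wide = sub.pivot_table(index="sample_id", columns="feature",
                                   values="value")[feats]
            wide.columns = [f"{mod}:{c}" for c in wide.columns]
            parts.append(wide)
        out[tp] = pd.concat(parts, axis=1).sort_index()
    return out["base"], out["final"]


def run_pipeline(config: RunConfig, out_dir: str | Path) -> dict:
    """Execute the full pipeline and persist all stage outputs.

    Returns a dictionary with the cohort, robustness report, delta
    matrix, LOOCV predictions and evaluation report. Every output file
    (config echo, feature CSVs, robustness summary, predictions,
    metric JSON) lands under ``out_dir``.
    """
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    (out / "config.json").write_text(config.to_json())
    t0 = time.time()

    # --- simulate -----------------------------------------------------
    cohort = generate_cohort(config.cohort)
    cohort = assign_precise_scores(cohort, config.reader_error_rate,
                                   seed=config.seed + 23)
    log.info("simulated %d-sample cohort (mode=%s, seed=%d)",
             config.cohort.n_samples, config.cohort.mode, config.cohort.seed)

    # --- extract / replicate ------------------------------------------
    if config.cohort.mode == "images":
        long_table = extract_cohort_features(
            cohort, bins_grid=config.bins_grid, classes=config.feature_classes
        )
    else:
        long_table, fragile = _feature_mode_long_table(cohort, config)
        log.info("fragile feature indices: %s", sorted(fragile.tolist()))
    save_long_features(long_table, out / "features.csv")

    # --- robustness ---------------------------------------------------
    report = compute_robustness(long_table, threshold=config.icc_threshold,
                                icc_variant=config.icc_variant)
    report.selected_bins = select_bins(report, policy=config.tie_policy)
    report.counts.to_csv(out / "robustness_counts.csv")
    report.icc_table.to_csv(out / "robustness_icc.csv", index=False)
    robust = report.robust_set()
    write_json(
        {"selected_bins": report.selected_bins, "robust_set": robust},
        out / "robustness_summary.json",
    )
    n_robust = sum(len(v) for v in robust.values())
    log.info("selected %d bins; %d robust features",
             report.selected_bins, n_robust)
    if n_robust < 2:
        raise RuntimeError("fewer than 2 robust features; cannot model")

    # --- delta --------------------------------------------------------
    base, final = _wide_tables(long_table, report.selected_bins, robust)
    order = pd.Index(cohort.sample_ids)
    base, final = base.loc[order], final.loc[order]
    dm = delta_matrix(base, final, cohort.outcome)
    dm.X.assign(outcome=dm.y).to_csv(out / "delta.csv")

    # --- fit (LOOCV) --------------------------------------------------
    predictions: dict[str, np.ndarray] = {}
    for name in config.models:
        model = get_model(name, seed=config.seed)
        predictions[name] = loocv(dm.X.to_numpy(), dm.y, model)
        log.info("LOOCV finished for %s (%.1f s elapsed)",
                 name, time.time() - t0)
    precise_binary = dichotomise_precise(cohort.precise_scores)
    predictions["precise"] = precise_binary.astype(float)
    pred_df = pd.DataFrame(predictions, index=cohort.sample_ids)
    pred_df.assign(outcome=cohort.outcome).to_csv(out / "predictions.csv")

    # --- evaluate -----------------------------------------------------
    evaluation = evaluate_predictions(
        predictions,
        cohort.outcome,
        threshold=config.probability_threshold,
        n_boot=config.bootstrap_replicates,
        seed=config.seed + 31,
    )
    evaluation["provenance"] = {
        "package_version": __version__,
        "config": json.loads(config.to_json()),
    }
    write_json(evaluation, out / "evaluation.json")
    table = report_table(evaluation)
    table.to_csv(out / "performance_table.csv")
    log.info("pipeline complete in %.1f s", time.time() - t0)

    return {
        "cohort": cohort,
        "features": long_table,
        "robustness": report,
        "delta": dm,
        "predictions": predictions,
        "evaluation": evaluation,
        "table": table,
        "out_dir": out,
    }
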