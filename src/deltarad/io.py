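"""File-format plumbing: NIfTI volumes/masks, CSV feature tables.

Volumes and masks are written one NIfTI file per
sample/modality/time-point on an identical grid (masks as 0/1 uint8);
feature tables travel as long-format CSV with columns (sample_id,
modality, time_point, n_bins, variant, feature, value).
"""

from __future__ import annotations

import json
from pathlib import Path

import nibabel as nib
import numpy as np
import pandas as pd

from .synthetic import MODALITIES, TIME_POINTS, SyntheticCohort

__all__ = [
    "save_image_cohort",
    "load_volume",
    "save_long_features",
    "load_long_features",
]

FEATURE_COLUMNS = [
    "sample_id", "modality", "time_point", "n_bins", "variant", "feature",
    "value",
]


def _affine(spacing) -> np.ndarray:
    aff = np.eye(4)
    aff[0, 0], aff[1, 1], aff[2, 2] = spacing
    return aff


def save_image_cohort(cohort: SyntheticCohort, out_dir: str | Path) -> Path:
    """Write an image-mode cohort as NIfTI files plus an outcomes CSV."""
    if cohort.volumes is None:
        raise ValueError("cohort has no image volumes")
    out = Path(out_dir)
    out.mkdir(parents=True, exist_ok=True)
    aff = _affine(cohort.spacing)
    for sid in cohort.sample_ids:
        for mod in MODALITIES:
            mask = cohort.masks[sid][mod].astype(np.uint8)
            nib.save(
                nib.Nifti1Image(mask, aff),
                out / f"{sid}_{mod}_mask.nii.gz",
            )
            for tp in TIME_POINTS:
                vol = cohort.volumes[sid][mod][tp].astype(np.float32)
                nib.save(
                    nib.Nifti1Image(vol, aff),
                    out / f"{sid}_{mod}_{tp}.nii.gz",
                )
    meta = pd.DataFrame(
        {"sample_id": cohort.sample_ids, "outcome": cohort.outcome}
    )
    if cohort.precise_scores is not None:
        meta["precise_score"] = cohort.precise_scores
    meta.to_csv(out / "outcomes.csv", index=False)
    if cohort.acquisition_params is not None:
        cohort.acquisition_params.rename_axis("sample_id").to_csv(
            out / "acquisition_params.csv"
        )
    return out


def load_volume(path: str | Path) -> tuple[np.ndarray, tuple[float, float, float]]:
    """Load a NIfTI volume, returning (array, voxel spacing in mm)."""
    img = nib.load(str(path))
    return np.asarray(img.dataobj, dtype=float), tuple(
        float(z) for z in img.header.get_zooms()[:3]
    )


def save_long_features(table: pd.DataFrame, path: str | Path) -> None:
    missing = set(FEATURE_COLUMNS) - set(table.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")
    table[FEATURE_COLUMNS].to_csv(path, index=False)


def load_long_features(path: str | Path) -> pd.DataFrame:
    return pd.read_csv(path)


def write_json(obj, path: str | Path) -> None:
    Path(path).write_text(json.dumps(obj, indent=2, sort_keys=True,
                                     default=_jsonable))


def _jsonable(x):
    if isinstance(x, (np.integer,)):
        return int(x)
    if isinstance(x, (np.floating,)):
        return float(x)
    if isinstance(x, np.ndarray):
        return x.tolist()
    if isinstance(x, (set, tuple)):
        return list(x)
    raise TypeError(f"not JSON-serialisable: {type(x)}")
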