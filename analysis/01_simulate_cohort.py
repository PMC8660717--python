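"""Generate the synthetic study cohorts every later stage consumes.

Writes a feature-mode cohort shaped like the target study population
(27 progressors / 38 non-progressor lesions, paired baseline and final
feature vectors) plus a small image-mode cohort (paired T2WI-like and
ADC-like volumes with lesion masks) under results/cohort/.
"""

import pathlib
import sys

import pandas as pd

import deltarad as dr
from deltarad.io import save_image_cohort, write_json

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42


def main() -> None:
    out = RESULTS / "cohort"
    out.mkdir(parents=True, exist_ok=True)

    feat_cfg = dr.CohortConfig(seed=SEED)  # 27/38, feature mode
    cohort = dr.generate_feature_cohort(feat_cfg)
    cohort = dr.assign_precise_scores(cohort)
    cohort.base.rename_axis("sample_id").to_csv(out / "base.csv")
    cohort.final.rename_axis("sample_id").to_csv(out / "final.csv")
    pd.DataFrame({
        "sample_id": cohort.sample_ids,
        "outcome": cohort.outcome,
        "precise_score": cohort.precise_scores,
    }).to_csv(out / "outcomes.csv", index=False)
    write_json({"informative_features": cohort.ground_truth, "seed": SEED},
               out / "ground_truth.json")
    print(f"feature cohort: {feat_cfg.n_samples} samples "
          f"({int(cohort.outcome.sum())} progressors), "
          f"{feat_cfg.n_features} features, informative = "
          f"{cohort.ground_truth.tolist()}")

    img_cfg = dr.CohortConfig(mode="images", n_progressors=5,
                              n_nonprogressors=5, seed=SEED)
    img = dr.generate_image_cohort(img_cfg)
    save_image_cohort(img, out / "images")
    n_vox = sum(img.masks[s]["T2WI"].sum() for s in img.sample_ids)
    print(f"image cohort: {img_cfg.n_samples} samples written as NIfTI, "
          f"mean lesion size {n_vox / img_cfg.n_samples:.0f} voxels")


if __name__ == "__main__":
    main()
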