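"""Discrimination report and published-table consistency check.

Loads the LOOCV predictions written by 04_fit_models.py and produces
the summary performance table (sensitivity/specificity with stratified
percentile-bootstrap CIs, PPV/NPV with Wald CIs, AUC with DeLong CIs)
and all pairwise DeLong AUC comparisons. Separately, it reconstructs
the integer confusion matrices implied by the published
sensitivity/specificity percentages (27 positives / 38 negatives) and
verifies that the published PPV/NPV cells follow arithmetically.
"""

import pathlib
import sys

import pandas as pd

import deltarad as dr
from deltarad.evaluation import report_table
from deltarad.io import write_json

RESULTS = pathlib.Path(__file__).resolve().parent.parent / "results"
SEED = int(sys.argv[1]) if len(sys.argv) > 1 else 42

#: published summary rows: sensitivity, specificity, PPV, NPV (percent)
PUBLISHED = {
    "PRECISE": (74.1, 94.7, 90.9, 83.7),
    "Parenclitic networks": (85.2, 73.7, 69.7, 87.5),
    "LASSO regression": (70.4, 84.2, 76.0, 80.0),
    "Random forests": (92.6, 65.8, 65.8, 92.6),
}


def main() -> None:
    pred_path = RESULTS / "run" / "predictions.csv"
    if not pred_path.exists():
        sys.exit("run 04_fit_models.py first (predictions.csv missing)")
    df = pd.read_csv(pred_path, index_col=0)
    y = df.pop("outcome").to_numpy(int)
    preds = {c: df[c].to_numpy(float) for c in df.columns}
    report = dr.evaluate_predictions(preds, y, n_boot=2000, seed=SEED)
    out = RESULTS / "evaluation"
    out.mkdir(parents=True, exist_ok=True)
    write_json(report, out / "evaluation.json")
    tab = report_table(report)
    tab.to_csv(out / "performance_table.csv")
    print("synthetic-cohort performance (percent):")
    print(tab.round(1).to_string())
    print("\npairwise DeLong comparisons:")
    for c in report["delong_comparisons"]:
        print(f"  {c['method_a']:12s} vs {c['method_b']:12s}: "
              f"z = {c['z']:+.2f}, p = {c['p']:.3f}")

    print("\npublished-table consistency (PPV/NPV from printed "
          "sensitivity/specificity, 27 positives / 38 negatives):")
    rows = []
    for method, (sens, spec, ppv, npv) in PUBLISHED.items():
        cm = dr.reconstruct_confusion(sens, spec, 27, 38)
        pv = dr.predictive_values(cm)
        rows.append({
            "method": method, "TP": cm.tp, "FP": cm.fp, "FN": cm.fn,
            "TN": cm.tn, "ppv_recomputed": round(100 * pv["ppv"], 1),
            "ppv_printed": ppv,
            "npv_recomputed": round(100 * pv["npv"], 1),
            "npv_printed": npv,
        })
    recon = pd.DataFrame(rows).set_index("method")
    recon.to_csv(out / "published_reconstruction.csv")
    print(recon.to_string())


if __name__ == "__main__":
    main()
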