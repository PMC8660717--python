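"""LOOCV orchestration and discrimination statistics.

Covers the evaluation conventions of the pipeline: leave-one-out
cross-validated probabilities; ROC AUC as the tie-corrected rank
statistic with DeLong (structural-components) confidence intervals and
paired tests; sensitivity/specificity with stratified percentile
bootstrap intervals (2,000 replicates); PPV/NPV with Wald intervals;
dichotomisation of 5-point serial-MRI change scores at >= 4; and
reconstruction of integer confusion matrices from printed
sensitivity/specificity percentages.
"""

from __future__ import annotations

from dataclasses import dataclass
from decimal import ROUND_HALF_UP, Decimal
from itertools import combinations

import numpy as np
import pandas as pd
from scipy import stats
from sklearn.base import clone

__all__ = [
    "loocv",
    "dichotomise_precise",
    "roc_auc",
    "delong_ci",
    "delong_test",
    "bootstrap_sens_spec",
    "predictive_values",
    "ConfusionMatrix",
    "confusion_from_predictions",
    "reconstruct_confusion",
    "evaluate_predictions",
]

Z975 = 1.959963984540054  # two-sided 95% normal quantile


def loocv(X, y, model, progress: bool = False) -> np.ndarray:
    """Leave-one-out cross-validated positive-class probabilities.

    Each sample's probability comes from a fresh clone of ``model``
    fitted on the other n - 1 samples; nothing derived from the
    held-out sample (label, scaling statistics, penalty choice) enters
    its own prediction. Raises if any training fold loses a class.
    """
    X = np.asarray(X, dtype=float)
    y = np.asarray(y, dtype=int)
    n = len(y)
    if n < 3:
        raise ValueError("LOOCV needs at least 3 samples")
    probs = np.empty(n)
    for i in range(n):
        tr = np.ones(n, dtype=bool)
        tr[i] = False
        if len(np.unique(y[tr])) < 2:
            raise ValueError(
                f"training fold without sample {i} contains a single class"
            )
        est = clone(model)
        est.fit(X[tr], y[tr])
        probs[i] = est.predict_proba(X[i : i + 1])[0, 1]
    return probs


def dichotomise_precise(score) -> np.ndarray | int:
    """Binary radiological progression: 1 iff the 5-point score >= 4."""
    arr = np.asarray(score)
    if np.any((arr < 1) | (arr > 5)) or not np.issubdtype(arr.dtype, np.integer):
        raise ValueError("scores must be integers in 1..5")
    out = (arr >= 4).astype(int)
    return int(out) if np.isscalar(score) or arr.ndim == 0 else out


def _check_labels(labels: np.ndarray) -> None:
    if labels.min() == labels.max():
        raise ValueError("both classes must be present")


def roc_auc(scores, labels) -> float:
    """Tie-corrected rank AUC: (concordant + half-tied) / (n1 * n0)."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    ranks = stats.rankdata(scores)
    n1 = int(labels.sum())
    n0 = len(labels) - n1
    return float((ranks[labels == 1].sum() - n1 * (n1 + 1) / 2) / (n1 * n0))


# ---------------------------------------------------------------------------
# DeLong


def _structural_components(scores: np.ndarray, labels: np.ndarray):
    """Per-sample placement values (V10, V01) of the Mann-Whitney AUC."""
    pos = scores[labels == 1]
    neg = scores[labels == 0]
    m, n = len(pos), len(neg)
    # midrank-based placements
    v10 = np.empty(m)
    v01 = np.empty(n)
    for idx, x in enumerate(pos):
        v10[idx] = ((x > neg).sum() + 0.5 * (x == neg).sum()) / n
    for idx, x in enumerate(neg):
        v01[idx] = ((pos > x).sum() + 0.5 * (pos == x).sum()) / m
    return v10, v01


def delong_ci(scores, labels, level: float = 0.95) -> tuple[float, tuple]:
    """AUC with its DeLong (asymptotically exact) confidence interval."""
    scores = np.asarray(scores, dtype=float)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    v10, v01 = _structural_components(scores, labels)
    auc = float(v10.mean())
    var = v10.var(ddof=1) / len(v10) + v01.var(ddof=1) / len(v01)
    z = stats.norm.ppf(0.5 + level / 2)
    half = z * np.sqrt(var)
    return auc, (float(auc - half), float(auc + half))


def delong_test(scores_a, scores_b, labels) -> dict:
    """Paired DeLong comparison of two AUCs measured on the same samples.

    Returns auc_a, auc_b, their 95% CIs, the z statistic of the AUC
    difference and the two-sided normal p-value. Identical score
    vectors (zero-variance difference) give z = 0, p = 1 by convention.
    """
    a = np.asarray(scores_a, dtype=float)
    b = np.asarray(scores_b, dtype=float)
    labels = np.asarray(labels, dtype=int)
    if a.shape != b.shape or a.shape[0] != labels.shape[0]:
        raise ValueError("score vectors must cover the same samples")
    _check_labels(labels)
    v10a, v01a = _structural_components(a, labels)
    v10b, v01b = _structural_components(b, labels)
    auc_a, auc_b = float(v10a.mean()), float(v10b.mean())
    m, n = len(v10a), len(v01a)
    s10 = np.cov(np.vstack([v10a, v10b]))  # 2x2, ddof=1
    s01 = np.cov(np.vstack([v01a, v01b]))
    cov = s10 / m + s01 / n
    var_diff = cov[0, 0] + cov[1, 1] - 2 * cov[0, 1]
    if var_diff <= 0:
        z, p = 0.0, 1.0
    else:
        z = (auc_a - auc_b) / np.sqrt(var_diff)
        p = float(2 * stats.norm.sf(abs(z)))
    za = Z975 * np.sqrt(cov[0, 0])
    zb = Z975 * np.sqrt(cov[1, 1])
    return {
        "auc_a": auc_a,
        "auc_b": auc_b,
        "ci_a": (auc_a - za, auc_a + za),
        "ci_b": (auc_b - zb, auc_b + zb),
        "z": float(z),
        "p": float(p),
    }


# ---------------------------------------------------------------------------
# binary-prediction metrics


@dataclass
class ConfusionMatrix:
    tp: int
    fp: int
    fn: int
    tn: int

    def __post_init__(self) -> None:
        if min(self.tp, self.fp, self.fn, self.tn) < 0:
            raise ValueError("confusion-matrix cells must be non-negative")

    @property
    def sensitivity(self) -> float:
        return self.tp / (self.tp + self.fn)

    @property
    def specificity(self) -> float:
        return self.tn / (self.tn + self.fp)


def confusion_from_predictions(pred, labels) -> ConfusionMatrix:
    pred = np.asarray(pred, dtype=int)
    labels = np.asarray(labels, dtype=int)
    return ConfusionMatrix(
        tp=int(((pred == 1) & (labels == 1)).sum()),
        fp=int(((pred == 1) & (labels == 0)).sum()),
        fn=int(((pred == 0) & (labels == 1)).sum()),
        tn=int(((pred == 0) & (labels == 0)).sum()),
    )


def bootstrap_sens_spec(
    pred, labels, n_boot: int = 2000, seed: int = 0, level: float = 0.95
) -> dict:
    """Sensitivity/specificity with stratified percentile bootstrap CIs.

    Resampling is stratified by outcome (positives resampled among
    positives, negatives among negatives); intervals are the 2.5/97.5
    percentiles of the replicate metrics and the point estimates come
    from the original data.
    """
    pred = np.asarray(pred, dtype=int)
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    rng = np.random.default_rng(seed)
    pos = pred[labels == 1]
    neg = pred[labels == 0]
    sens_reps = rng.choice(pos, size=(n_boot, len(pos))).mean(axis=1)
    spec_reps = 1 - rng.choice(neg, size=(n_boot, len(neg))).mean(axis=1)
    lo, hi = 100 * (1 - level) / 2, 100 * (1 + level) / 2
    return {
        "sensitivity": float(pos.mean()),
        "sensitivity_ci": tuple(np.percentile(sens_reps, [lo, hi])),
        "specificity": float(1 - neg.mean()),
        "specificity_ci": tuple(np.percentile(spec_reps, [lo, hi])),
    }


def predictive_values(cm: ConfusionMatrix, level: float = 0.95) -> dict:
    """PPV/NPV with Wald intervals on the proportion scale, clipped to [0,1]."""
    z = stats.norm.ppf(0.5 + level / 2)
    out = {}
    for name, num, den in (
        ("ppv", cm.tp, cm.tp + cm.fp),
        ("npv", cm.tn, cm.tn + cm.fn),
    ):
        if den == 0:
            out[name], out[f"{name}_ci"] = float("nan"), (float("nan"),) * 2
            continue
        p = num / den
        half = z * np.sqrt(p * (1 - p) / den)
        out[name] = float(p)
        out[f"{name}_ci"] = (max(0.0, p - half), min(1.0, p + half))
    return out


def _rounds_to(value: float, printed: float, decimals: int = 1) -> bool:
    """Does 100*value round (half-up, ``decimals`` places) to ``printed``?"""
    q = Decimal(10) ** -decimals
    r = Decimal(100 * value).quantize(q, rounding=ROUND_HALF_UP)
    return r == Decimal(str(printed)).quantize(q, rounding=ROUND_HALF_UP)


def reconstruct_confusion(
    sens_printed: float, spec_printed: float, n_pos: int, n_neg: int
) -> ConfusionMatrix:
    """Recover the integer confusion matrix behind printed percentages.

    Searches TP in 0..n_pos for the unique integer whose sensitivity
    rounds (half-up, one decimal) to ``sens_printed``, likewise TN from
    ``spec_printed``. Raises if no integer — or more than one — is
    consistent, which signals a transcription or denominator mismatch.
    """
    if not (0 <= sens_printed <= 100 and 0 <= spec_printed <= 100):
        raise ValueError("printed percentages must lie in [0, 100]")
    if n_pos < 1 or n_neg < 1:
        raise ValueError("n_pos and n_neg must be >= 1")
    tp = [t for t in range(n_pos + 1) if _rounds_to(t / n_pos, sens_printed)]
    tn = [t for t in range(n_neg + 1) if _rounds_to(t / n_neg, spec_printed)]
    if len(tp) != 1 or len(tn) != 1:
        raise ValueError(
            f"printed values are consistent with {len(tp)} TP and "
            f"{len(tn)} TN candidates"
        )
    return ConfusionMatrix(
        tp=tp[0], fp=n_neg - tn[0], fn=n_pos - tp[0], tn=tn[0]
    )


# ---------------------------------------------------------------------------
# report


def evaluate_predictions(
    predictions: dict[str, np.ndarray],
    labels: np.ndarray,
    threshold: float = 0.5,
    n_boot: int = 2000,
    seed: int = 0,
) -> dict:
    """Full discrimination report for a set of per-method predictions.

    ``predictions`` maps method name to per-sample scores: continuous
    probabilities are binarised at ``threshold`` for the
    sensitivity/specificity/PPV/NPV block, while AUC/DeLong use the
    scores as given. Returns per-method metrics (95% CIs throughout)
    and all pairwise DeLong comparisons.
    """
    labels = np.asarray(labels, dtype=int)
    _check_labels(labels)
    methods = {}
    for name, scores in predictions.items():
        scores = np.asarray(scores, dtype=float)
        binary = (scores >= threshold).astype(int)
        cm = confusion_from_predictions(binary, labels)
        auc, auc_ci = delong_ci(scores, labels)
        entry = {
            "auc": auc,
            "auc_ci": auc_ci,
            "confusion": dict(tp=cm.tp, fp=cm.fp, fn=cm.fn, tn=cm.tn),
        }
        entry.update(bootstrap_sens_spec(binary, labels, n_boot=n_boot,
                                         seed=seed))
        entry.update(predictive_values(cm))
        methods[name] = entry
    comparisons = []
    for a, b in combinations(predictions, 2):
        res = delong_test(predictions[a], predictions[b], labels)
        comparisons.append(
            {"method_a": a, "method_b": b, "z": res["z"], "p": res["p"]}
        )
    return {"methods": methods, "delong_comparisons": comparisons}


def report_table(report: dict) -> pd.DataFrame:
    """Summary-performance table (percent scale, CI bounds as columns)."""
    rows = []
    for name, m in report["methods"].items():
        rows.append(
            {
                "method": name,
                "sensitivity": 100 * m["sensitivity"],
                "sensitivity_lo": 100 * m["sensitivity_ci"][0],
                "sensitivity_hi": 100 * m["sensitivity_ci"][1],
                "specificity": 100 * m["specificity"],
                "specificity_lo": 100 * m["specificity_ci"][0],
                "specificity_hi": 100 * m["specificity_ci"][1],
                "ppv": 100 * m["ppv"],
                "npv": 100 * m["npv"],
                "auc": 100 * m["auc"],
                "auc_lo": 100 * m["auc_ci"][0],
                "auc_hi": 100 * m["auc_ci"][1],
            }
        )
    return pd.DataFrame(rows).set_index("method")
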