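"""Feature-robustness screening under ROI perturbation.

Calibration stage of the delta-radiomics pipeline: each feature is
re-measured after morphological perturbation of the tumour ROI
(original / opened / closed masks as k = 3 "raters"), and its
intraclass correlation coefficient across samples is computed per
modality, time point and bin count. Features with ICC > 0.8 at BOTH
time points are retained; the working bin count is the one maximising
the total robust-feature count. A Spearman screen flags features
associated with MRI acquisition parameters.
"""

from __future__ import annotations

import logging
import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy import stats

__all__ = [
    "icc",
    "compute_robustness",
    "select_bins",
    "acquisition_screen",
    "RobustnessReport",
]

log = logging.getLogger(__name__)

#: replicate mask variants treated as fixed "raters"
VARIANTS = ("original", "opened", "closed")


def icc(measurements: np.ndarray, variant: str = "consistency") -> float:
    """Intraclass correlation of a subjects x replicates table.

    ``variant``:

    * ``"consistency"`` (default) — two-way mixed effects, single
      rater, consistency: ICC(3,1) = (MS_R - MS_E) / (MS_R + (k-1) MS_E).
      Systematic offsets between replicates do not count against
      agreement; appropriate when the replicate set (mask perturbation
      modes) is fixed rather than sampled.
    * ``"agreement"`` — two-way mixed, single rater, absolute agreement
      (ICC(2,1)-style formula with fixed raters).
    * ``"one_way"`` — one-way random effects ICC(1,1).

    All values are <= 1 and may be negative. If every cell is identical
    the function returns 1.0 by convention (perfect agreement with zero
    variance) and logs the fact.
    """
    x = np.asarray(measurements, dtype=float)
    if x.ndim != 2 or x.shape[0] < 2 or x.shape[1] < 2:
        raise ValueError("need >= 2 subjects and >= 2 replicates")
    if not np.isfinite(x).all():
        raise ValueError("missing or non-finite cells")
    n, k = x.shape
    grand = x.mean()
    row_mean = x.mean(axis=1)
    col_mean = x.mean(axis=0)
    ss_rows = k * ((row_mean - grand) ** 2).sum()
    ss_cols = n * ((col_mean - grand) ** 2).sum()
    ss_tot = ((x - grand) ** 2).sum()
    ss_err = ss_tot - ss_rows - ss_cols
    ms_r = ss_rows / (n - 1)
    ms_c = ss_cols / (k - 1)
    ms_e = ss_err / ((n - 1) * (k - 1))

    if ss_tot == 0:
        log.info("all measurements identical; ICC = 1 by convention")
        return 1.0

    if variant == "consistency":
        denom = ms_r + (k - 1) * ms_e
        return float((ms_r - ms_e) / denom) if denom > 0 else 1.0
    if variant == "agreement":
        denom = ms_r + (k - 1) * ms_e + k / n * (ms_c - ms_e)
        return float((ms_r - ms_e) / denom) if denom > 0 else 1.0
    if variant == "one_way":
        ms_w = (ss_tot - ss_rows) / (n * (k - 1))
        denom = ms_r + (k - 1) * ms_w
        return float((ms_r - ms_w) / denom) if denom > 0 else 1.0
    raise ValueError(f"unknown ICC variant {variant!r}")


@dataclass
class RobustnessReport:
    """Per-feature ICCs and the retained robust feature set.

    ``icc_table`` has one row per (feature, modality, time_point,
    n_bins) with columns ``icc`` and ``robust`` (strictly icc > threshold).
    ``counts`` mirrors the robust-feature-count summary table: one row
    per bin count with columns base_<modality>, final_<modality> and
    ``total``. ``robust_sets[(n_bins, modality)]`` is the set of
    features robust at both time points.
    """

    icc_table: pd.DataFrame
    counts: pd.DataFrame
    robust_sets: dict[tuple[int, str], list[str]]
    threshold: float = 0.8
    selected_bins: int | None = None
    skipped: list = field(default_factory=list)

    def robust_set(self, n_bins: int | None = None) -> dict[str, list[str]]:
        """Robust (dual-time-point) features per modality at a bin count."""
        nb = self.selected_bins if n_bins is None else n_bins
        if nb is None:
            raise ValueError("no bin count selected")
        return {
            mod: feats
            for (b, mod), feats in self.robust_sets.items()
            if b == nb
        }


def compute_robustness(
    features: pd.DataFrame,
    threshold: float = 0.8,
    icc_variant: str = "consistency",
) -> RobustnessReport:
    """ICC-based robustness screen over a long-format feature table.

    ``features`` columns: sample_id, modality, time_point, n_bins,
    variant (original/opened/closed), feature, value. Samples missing
    any replicate variant (e.g. perturbation emptied the mask) are
    excluded from that feature's ICC with a log entry.
    """
    required = {"sample_id", "modality", "time_point", "n_bins", "variant",
                "feature", "value"}
    missing = required - set(features.columns)
    if missing:
        raise ValueError(f"feature table lacks columns {sorted(missing)}")

    rows = []
    skipped: list = []
    group_cols = ["modality", "time_point", "n_bins", "feature"]
    for key, grp in features.groupby(group_cols, sort=True):
        wide = grp.pivot_table(
            index="sample_id", columns="variant", values="value"
        )
        have = [v for v in VARIANTS if v in wide.columns]
        wide = wide[have].dropna()
        if len(wide) < 2 or wide.shape[1] < 2:
            skipped.append(key)
            log.warning("skipping %s: insufficient replicate data", key)
            continue
        val = icc(wide.to_numpy(), variant=icc_variant)
        rows.append(dict(zip(group_cols, key), icc=val,
                         robust=bool(val > threshold)))
    icc_table = pd.DataFrame(rows)
    if icc_table.empty:
        raise ValueError("no complete replicate groups in the feature table")

    modalities = sorted(icc_table["modality"].unique())
    counts_rows = {}
    robust_sets: dict[tuple[int, str], list[str]] = {}
    for nb, sub in icc_table.groupby("n_bins"):
        row = {}
        for tp in ("base", "final"):
            for mod in modalities:
                m = sub[(sub.time_point == tp) & (sub.modality == mod)]
                row[f"{tp}_{mod}"] = int(m["robust"].sum())
        row["total"] = sum(row.values())
        counts_rows[int(nb)] = row
        for mod in modalities:
            per_tp = [
                set(
                    sub[(sub.time_point == tp) & (sub.modality == mod)
                        & sub.robust]["feature"]
                )
                for tp in ("base", "final")
            ]
            robust_sets[(int(nb), mod)] = sorted(set.intersection(*per_tp))
    counts = pd.DataFrame.from_dict(counts_rows, orient="index").sort_index()
    counts.index.name = "n_bins"

    report = RobustnessReport(
        icc_table=icc_table, counts=counts, robust_sets=robust_sets,
        threshold=threshold, skipped=skipped,
    )
    report.selected_bins = select_bins(report)
    return report


def select_bins(
    report: RobustnessReport | dict[int, int] | pd.Series,
    policy: str = "largest-of-tied",
) -> int:
    """Pick the working bin count from total robust-feature counts.

    The bin count with the maximal total wins. Ties are broken by
    ``policy``: ``"largest-of-tied"`` (default) or
    ``"smallest-of-tied"``.
    """
    if isinstance(report, RobustnessReport):
        totals = report.counts["total"]
    elif isinstance(report, dict):
        totals = pd.Series(report)
    else:
        totals = report
    if len(totals) == 0:
        raise ValueError("empty robustness report")
    best = totals.max()
    tied = sorted(int(b) for b in totals.index[totals == best])
    if policy == "largest-of-tied":
        return tied[-1]
    if policy == "smallest-of-tied":
        return tied[0]
    raise ValueError(f"unknown tie-break policy {policy!r}")


def acquisition_screen(
    features: pd.DataFrame,
    params: pd.DataFrame,
    alpha: float = 0.05,
) -> pd.DataFrame:
    """Spearman screen of features against acquisition parameters.

    ``features``: samples x features; ``params``: samples x acquisition
    scalars (aligned on index). Returns one row per (feature, param)
    with ``rho``, ``p_value`` and ``flagged`` (p < alpha, no
    multiplicity correction). A constant feature or parameter has no
    defined rank correlation: it is reported with NaN rho, not flagged,
    and a warning is emitted. Whether flagged features are excluded is
    left to the caller.
    """
    common = features.index.intersection(params.index)
    if len(common) < 3:
        raise ValueError("need >= 3 samples with paired observations")
    f = features.loc[common]
    q = params.loc[common]
    rows = []
    for feat in f.columns:
        for par in q.columns:
            x, y = f[feat].to_numpy(float), q[par].to_numpy(float)
            if np.ptp(x) == 0 or np.ptp(y) == 0:
                warnings.warn(
                    f"constant input for ({feat}, {par}); rho undefined"
                )
                rows.append(dict(feature=feat, param=par, rho=np.nan,
                                 p_value=np.nan, flagged=False))
                continue
            rho, p = stats.spearmanr(x, y)
            rows.append(dict(feature=feat, param=par, rho=float(rho),
                             p_value=float(p), flagged=bool(p < alpha)))
    return pd.DataFrame(rows)
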