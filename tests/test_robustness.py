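"""ICC, robustness filtering, bin selection and acquisition screen."""

import numpy as np
import pandas as pd
import pytest

import deltarad as dr
from deltarad.robustness import RobustnessReport, acquisition_screen, icc

#: printed robust-feature totals per bin count from the study's
#: calibration table (8..256 bins)
TABLE2_TOTALS = {8: 199, 16: 201, 32: 201, 64: 206, 128: 214, 256: 214}


def hand_icc_consistency(x):
    """Mean-squares ICC(3,1) written out step by step (test oracle)."""
    x = np.asarray(x, float)
    n, k = x.shape
    grand = x.mean()
    ms_rows = k * ((x.mean(axis=1) - grand) ** 2).sum() / (n - 1)
    ms_cols = n * ((x.mean(axis=0) - grand) ** 2).sum() / (k - 1)
    ss_err = ((x - grand) ** 2).sum() - ms_rows * (n - 1) - ms_cols * (k - 1)
    ms_err = ss_err / ((n - 1) * (k - 1))
    return (ms_rows - ms_err) / (ms_rows + (k - 1) * ms_err)


class TestICC:
    def test_hand_anova_table(self):
        """4 subjects x 2 replicates against a hand ANOVA computation."""
        x = np.array([[8.0, 9.0], [4.0, 5.0], [6.0, 8.0], [2.0, 2.0]])
        # by hand: row means (8.5, 4.5, 7, 2), grand 5.5, MS_rows ~ 2*47/3;
        # the helper spells out the same arithmetic
        assert icc(x) == pytest.approx(hand_icc_consistency(x), abs=1e-12)

    def test_perfect_agreement(self):
        x = np.tile(np.arange(5.0)[:, None], (1, 3))
        assert icc(x) == 1.0

    def test_all_identical_convention(self):
        assert icc(np.ones((5, 3))) == 1.0

    def test_noisy_replicates_below_threshold(self):
        """Replicate noise 10x the subject SD destroys robustness."""
        r = np.random.default_rng(0)
        subj = r.normal(0, 1, size=(20, 1))
        x = subj + r.normal(0, 10, size=(20, 3))
        assert icc(x) < 0.8

    def test_matches_pingouin_all_variants(self):
        pg = pytest.importorskip("pingouin")
        r = np.random.default_rng(1)
        x = r.normal(0, 1, size=(12, 1)) + r.normal(0, 0.3, size=(12, 3))
        df = pd.DataFrame({
            "subj": np.repeat(range(12), 3),
            "rater": list(range(3)) * 12,
            "y": x.ravel(),
        })
        ref = pg.intraclass_corr(df, targets="subj", raters="rater",
                                 ratings="y").set_index("Type")["ICC"]
        assert icc(x, "consistency") == pytest.approx(ref["ICC(C,1)"], abs=1e-9)
        assert icc(x, "agreement") == pytest.approx(ref["ICC(A,1)"], abs=1e-9)
        assert icc(x, "one_way") == pytest.approx(ref["ICC(1,1)"], abs=1e-9)

    def test_shift_scale_invariance(self):
        r = np.random.default_rng(2)
        x = r.normal(size=(10, 3))
        base = icc(x)
        assert icc(x + 100) == pytest.approx(base, abs=1e-10)
        assert icc(x * 3.5) == pytest.approx(base, abs=1e-10)

    def test_monotone_degradation_with_noise(self):
        """Mean ICC strictly decreases as replicate noise grows."""
        means = []
        for sd in (0.1, 0.5, 1.0, 3.0):
            vals = []
            for seed in range(10):
                r = np.random.default_rng(seed)
                x = r.normal(0, 1, (15, 1)) + r.normal(0, sd, (15, 3))
                vals.append(icc(x))
            means.append(np.mean(vals))
        assert all(a > b for a, b in zip(means, means[1:]))

    def test_input_validation(self):
        with pytest.raises(ValueError):
            icc(np.ones((1, 3)))
        with pytest.raises(ValueError):
            icc(np.array([[1.0, np.nan], [2.0, 3.0]]))


def long_table(values: dict) -> pd.DataFrame:
    """values: {(sample, modality, tp, bins, variant, feature): value}"""
    rows = [
        dict(sample_id=s, modality=m, time_point=tp, n_bins=nb, variant=v,
             feature=f, value=val)
        for (s, m, tp, nb, v, f), val in values.items()
    ]
    return pd.DataFrame(rows)


class TestComputeRobustness:
    def _synthetic_table(self, fragile_final_only=False, seed=0):
        r = np.random.default_rng(seed)
        vals = {}
        for s in range(12):
            for f, noise in (("stable", 0.01), ("fragile", 10.0)):
                for tp in ("base", "final"):
                    truth = r.normal(0, 5)
                    for v in ("original", "opened", "closed"):
                        sd = noise
                        if fragile_final_only and f == "fragile":
                            sd = 10.0 if tp == "final" else 0.01
                        jitter = 0.0 if v == "original" else r.normal(0, sd)
                        vals[(f"S{s}", "T2WI", tp, 16, v, f)] = truth + jitter
        return long_table(vals)

    def test_invariant_features_all_retained(self):
        report = dr.compute_robustness(self._synthetic_table())
        stable = report.icc_table[report.icc_table.feature == "stable"]
        assert stable.robust.all()
        assert "stable" in report.robust_set(16)["T2WI"]

    def test_final_only_instability_excluded(self):
        """High perturbation noise at the final time point alone removes a
        feature from the dual-time-point robust set."""
        report = dr.compute_robustness(
            self._synthetic_table(fragile_final_only=True, seed=1)
        )
        tab = report.icc_table.set_index(["feature", "time_point"])
        assert tab.loc[("fragile", "base"), "icc"].item() > 0.95
        assert not tab.loc[("fragile", "final"), "robust"].item()
        assert "fragile" not in report.robust_set(16)["T2WI"]

    def test_counts_table_layout(self):
        """One row per bin count; per-time-point, per-modality columns plus
        a total, mirroring the calibration-report layout."""
        r = np.random.default_rng(3)
        vals = {}
        for s in range(8):
            for mod in ("T2WI", "ADC"):
                for nb in (16, 32):
                    for tp in ("base", "final"):
                        truth = r.normal(0, 5)
                        for v in ("original", "opened", "closed"):
                            vals[(f"S{s}", mod, tp, nb, v, "feat")] = (
                                truth + (0 if v == "original"
                                         else r.normal(0, 0.01))
                            )
        report = dr.compute_robustness(long_table(vals))
        assert list(report.counts.index) == [16, 32]
        assert list(report.counts.columns) == [
            "base_ADC", "base_T2WI", "final_ADC", "final_T2WI", "total"
        ]
        assert (report.counts["total"] ==
                report.counts.drop(columns="total").sum(axis=1)).all()

    def test_intersection_bound(self):
        report = dr.compute_robustness(self._synthetic_table(seed=2))
        tab = report.icc_table
        for (nb, mod), feats in report.robust_sets.items():
            for tp in ("base", "final"):
                n_tp = tab[(tab.n_bins == nb) & (tab.modality == mod)
                           & (tab.time_point == tp)]["robust"].sum()
                assert len(feats) <= n_tp


class TestSelectBins:
    def test_printed_totals_both_policies(self):
        assert dr.select_bins(TABLE2_TOTALS) == 256
        assert dr.select_bins(TABLE2_TOTALS, policy="smallest-of-tied") == 128

    def test_single_bin_count(self):
        assert dr.select_bins({64: 10}) == 64

    def test_all_tied_takes_largest(self):
        assert dr.select_bins({8: 5, 16: 5, 32: 5}) == 32

    def test_empty_report_rejected(self):
        with pytest.raises(ValueError):
            dr.select_bins({})


class TestAcquisitionScreen:
    def test_monotone_transform_flagged(self):
        r = np.random.default_rng(4)
        tr = pd.Series(r.normal(5000, 200, 30))
        feats = pd.DataFrame({"f": np.exp(tr / 1000)})
        params = pd.DataFrame({"TR": tr})
        out = acquisition_screen(feats, params)
        assert out.loc[0, "rho"] == pytest.approx(1.0)
        assert out.loc[0, "flagged"]

    def test_constant_feature_warns_not_flagged(self):
        params = pd.DataFrame({"TR": np.arange(10.0)})
        feats = pd.DataFrame({"f": np.ones(10)})
        with pytest.warns(UserWarning, match="constant"):
            out = acquisition_screen(feats, params)
        assert not out.loc[0, "flagged"]
        assert np.isnan(out.loc[0, "rho"])

    def test_null_flag_fraction_binomial(self):
        """Independent feature/parameter pairs are flagged at ~alpha."""
        from scipy import stats
        r = np.random.default_rng(5)
        feats = pd.DataFrame(r.normal(size=(40, 100)))
        feats.columns = [f"f{i}" for i in range(100)]
        params = pd.DataFrame({"TR": r.normal(size=40)})
        out = acquisition_screen(feats, params)
        flagged = int(out.flagged.sum())
        lo, hi = stats.binom.interval(0.95, 100, 0.05)
        assert lo <= flagged <= hi

    def test_too_few_samples_rejected(self):
        with pytest.raises(ValueError):
            acquisition_screen(pd.DataFrame({"f": [1.0, 2.0]}),
                               pd.DataFrame({"TR": [1.0, 2.0]}))
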