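"""Statistical battery vs closed-form oracles, calibration, cohort bundle."""
import numpy as np
import pandas as pd
import pytest

import cvrkit as ck
from _oracles import ranova_ss_oracle


class TestTTests:
    def test_unpaired_matches_hand_computed_pooled_t(self):
        res = ck.ttest_unpaired([1.0, 2.0, 3.0], [4.0, 5.0, 6.0])
        # pooled SD 1, SE sqrt(2/3): t = -3 / sqrt(2/3)
        assert res.statistic == pytest.approx(-3.0 / np.sqrt(2.0 / 3.0), abs=1e-9)
        assert res.dof == 4
        assert res.direction == "a<b"

    def test_identical_samples_null(self):
        res = ck.ttest_unpaired([1.0, 2.0, 3.0], [1.0, 2.0, 3.0])
        assert res.statistic == pytest.approx(0.0)
        assert res.p_value == pytest.approx(1.0)

    def test_paired_constant_shift_degenerate(self):
        y = np.array([1.0, 2.0, 3.0])
        with pytest.raises(ValueError, match="zero variance"):
            ck.ttest_paired(y + 1.0, y)

    def test_paired_matches_one_sample_on_differences(self):
        x = np.array([0.10, 0.12, 0.09, 0.15])
        y = np.array([0.08, 0.13, 0.05, 0.11])
        res = ck.ttest_paired(x, y)
        d = x - y
        t_oracle = d.mean() / (d.std(ddof=1) / np.sqrt(d.size))
        assert res.statistic == pytest.approx(t_oracle, abs=1e-9)
        assert res.dof == 3


class TestRanova:
    def test_identical_sessions_give_null(self):
        w = np.array([[0.1, 0.1, 0.1], [0.2, 0.2, 0.2], [0.15, 0.15, 0.15]])
        res = ck.ranova_oneway(w)
        assert res.statistic == 0.0
        assert res.p_value == 1.0

    def test_matches_sum_of_squares_oracle(self):
        rng = np.random.default_rng(7)
        w = rng.normal(0.1, 0.02, size=(4, 3))
        res = ck.ranova_oneway(w)
        f, df1, df2 = ranova_ss_oracle(w)
        assert res.statistic == pytest.approx(f, abs=1e-9)
        assert res.dof == (df1, df2)

    def test_matches_statsmodels_anova_rm(self):
        from statsmodels.stats.anova import AnovaRM

        rng = np.random.default_rng(11)
        w = rng.normal(0.09, 0.02, size=(6, 3))
        long = pd.DataFrame(
            {
                "subject": np.repeat(np.arange(6), 3),
                "session": np.tile([1, 2, 3], 6),
                "value": w.ravel(),
            }
        )
        sm_res = AnovaRM(long, "value", "subject", within=["session"]).fit()
        f_sm = float(sm_res.anova_table["F Value"].iloc[0])
        assert ck.ranova_oneway(w).statistic == pytest.approx(f_sm, rel=1e-9)

    def test_incomplete_subjects_dropped(self):
        w = np.array([[0.1, 0.2, 0.3], [0.1, np.nan, 0.3],
                      [0.2, 0.1, 0.3], [0.3, 0.2, 0.1], [0.15, 0.2, 0.1]])
        res = ck.ranova_oneway(w)
        assert res.n == 4
        assert res.extra["excluded_incomplete"] == 1

    def test_power_at_session_effect(self):
        # true session means (0.091, 0.091, 0.107), subject SD 0.02,
        # residual SD 0.01, 20 subjects: detection well above chance
        rng = np.random.default_rng(0)
        means = np.array([0.091, 0.091, 0.107])
        hits = 0
        n_sim = 200
        for _ in range(n_sim):
            subj = rng.normal(0, 0.02, size=(20, 1))
            w = means + subj + rng.normal(0, 0.01, size=(20, 3))
            if ck.ranova_oneway(w).p_value < 0.05:
                hits += 1
        assert hits / n_sim > 0.8


class TestPearsonFisher:
    def test_perfect_correlation(self):
        assert ck.pearson([1, 2, 3], [1, 2, 3]).statistic == pytest.approx(1.0)

    def test_hand_computed_covariance(self):
        res = ck.pearson([1, 2, 3, 4], [2, 1, 4, 3])
        assert res.statistic == pytest.approx(0.6, abs=1e-9)

    def test_fisher_z(self):
        assert ck.fisher_z(0.0) == 0.0
        r = 0.6
        assert ck.fisher_z(r) == pytest.approx(0.5 * np.log((1 + r) / (1 - r)), abs=1e-12)

    def test_zero_variance_rejected(self):
        with pytest.raises(ValueError):
            ck.pearson([1.0, 1.0, 1.0], [1.0, 2.0, 3.0])


class TestKsNormality:
    def test_two_point_distribution_rejected(self):
        rng = np.random.default_rng(0)
        x = rng.choice([0.0, 1.0], size=200) + rng.normal(0, 1e-6, 200)
        assert ck.ks_normality(x).p_value < 0.01

    def test_statistic_in_unit_interval(self):
        rng = np.random.default_rng(1)
        for method in ("lilliefors", "naive"):
            res = ck.ks_normality(rng.normal(size=50), method=method)
            assert 0.0 <= res.statistic <= 1.0

    def test_gaussian_samples_rarely_rejected(self):
        rng = np.random.default_rng(2)
        ok = sum(
            ck.ks_normality(rng.normal(size=1000)).p_value > 0.05 for _ in range(100)
        )
        assert ok >= 95


class TestPretreatmentAverage:
    def _table(self, rows):
        return pd.DataFrame(rows)

    def test_mean_of_two_sessions(self):
        t = self._table(
            [
                {"subject": "MS01", "group": "MS", "session": 1, "cvr_gm": 0.08},
                {"subject": "MS01", "group": "MS", "session": 2, "cvr_gm": 0.10},
            ]
        )
        assert ck.pretreatment_average(t)["MS01"] == pytest.approx(0.09)

    def test_single_available_session_stands_in(self):
        t = self._table(
            [
                {"subject": "MS01", "group": "MS", "session": 1, "cvr_gm": 0.095},
                {"subject": "MS01", "group": "MS", "session": 2, "cvr_gm": np.nan},
            ]
        )
        assert ck.pretreatment_average(t)["MS01"] == pytest.approx(0.095)

    def test_subject_with_no_pretreatment_excluded(self):
        t = self._table(
            [
                {"subject": "MS01", "group": "MS", "session": 1, "cvr_gm": np.nan},
                {"subject": "MS01", "group": "MS", "session": 2, "cvr_gm": np.nan},
                {"subject": "MS02", "group": "MS", "session": 1, "cvr_gm": 0.09},
            ]
        )
        pre = ck.pretreatment_average(t)
        assert list(pre.index) == ["MS02"]

    def test_no_ms_subjects_fails(self):
        t = self._table([{"subject": "HC01", "group": "HC", "session": 1, "cvr_gm": 0.1}])
        with pytest.raises(ValueError):
            ck.pretreatment_average(t)


def _estimated_style_table(truth):
    """Rename truth columns to look like an estimated cohort table."""
    df = truth.rename(
        columns={"true_cvr_gm": "cvr_gm", "true_cvr_wm": "cvr_wm"}
    ).copy()
    df["vol_gm"] = 600.0 * df.get("vol_scale_gm", 1.0)
    df["vol_wm"] = 500.0 * df.get("vol_scale_wm", 1.0)
    return df


class TestAnalyzeCohort:
    def test_row_order_and_relabel_invariance(self):
        truth = ck.make_cohort(ck.CohortSpec(seed=3))
        table = _estimated_style_table(truth)
        a = ck.analyze_cohort(table)
        shuffled = table.sample(frac=1.0, random_state=0).reset_index(drop=True)
        relabeled = shuffled.copy()
        relabeled["subject"] = relabeled["subject"].map(lambda s: "x" + s[::-1])
        b = ck.analyze_cohort(relabeled)
        for key, res in a["results"].items():
            assert b["results"][key].statistic == pytest.approx(res.statistic, abs=1e-12)

    def test_restoration_correlation_detected(self):
        # true r ~ -0.5 at n ~ 21: sign should be stable across cohorts and
        # significance reached well above the 5% chance rate
        negative = significant = 0
        for seed in range(10):
            truth = ck.make_cohort(ck.CohortSpec(delta_slope=-0.6, seed=seed))
            out = ck.analyze_cohort(_estimated_style_table(truth))
            res = out["results"]["corr_gm_delta_vs_pre"]
            negative += res.direction == "negative"
            significant += res.p_value < 0.05
        assert negative >= 9
        assert significant >= 4

    def test_null_cohort_false_positive_rate_near_alpha(self):
        stats = dict(ck.CohortSpec().group_stats)
        # single population: no group, session or coupling effects anywhere
        for key in list(stats):
            stats[key] = (0.09, 0.026) if key[1] == "gm" else (0.055, 0.020)
        pvals = []
        for seed in range(60):
            spec = ck.CohortSpec(
                group_stats=stats, delta_slope=0.0, vol_cvr_corr=0.0,
                delta_sd={"gm": 0.012, "wm": 0.012}, session_sd=0.008,
                missing_sessions=(), seed=seed,
            )
            truth = ck.make_cohort(spec)
            out = ck.analyze_cohort(_estimated_style_table(truth))
            pvals.extend(
                r.p_value
                for name, r in out["results"].items()
                if not name.startswith("ks_") and np.isfinite(r.p_value)
            )
        rate = np.mean(np.asarray(pvals) < 0.05)
        assert 0.02 <= rate <= 0.09
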