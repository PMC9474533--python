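"""Voxel-wise GLM, ROI medians with lesion exclusion, subject pipeline."""
import numpy as np
import pytest

import cvrkit as ck
from cvrkit.cvr import fit_cvr_map, summarize_cvr
from cvrkit.preprocess import BoldSeries, TissueMasks


def _pct_series(data):
    return BoldSeries(np.asarray(data, float), (3, 3, 3), 3.0, units="percent")


@pytest.fixture(scope="module")
def xreg(regressor):
    return regressor.values - regressor.values.mean()


class TestFitCvrMap:
    def test_noiseless_identity(self, regressor, xreg):
        y = (0.1 * xreg)[None, None, None, :]
        cvr = fit_cvr_map(_pct_series(y), regressor)
        assert cvr.beta[0, 0, 0] == pytest.approx(0.1, abs=1e-9)
        assert cvr.residual_sd[0, 0, 0] == pytest.approx(0.0, abs=1e-9)
        assert cvr.dof == 92 - 2

    def test_null_data_t_statistics_centred(self, regressor):
        rng = np.random.default_rng(0)
        y = rng.standard_normal((10, 10, 10, 92))
        cvr = fit_cvr_map(_pct_series(y), regressor)
        assert abs(cvr.tstat.mean()) < 0.1

    def test_orthogonal_confound_leaves_beta(self, regressor, xreg):
        rng = np.random.default_rng(3)
        y = (0.07 * xreg + rng.standard_normal(92) * 0.1)[None, None, None, :]
        base = fit_cvr_map(_pct_series(y), regressor)
        raw = rng.standard_normal(92)
        design = np.column_stack([xreg, np.ones(92)])
        conf = raw - design @ np.linalg.lstsq(design, raw, rcond=None)[0]
        with_conf = fit_cvr_map(_pct_series(y), regressor, confounds=[conf])
        assert with_conf.beta[0, 0, 0] == pytest.approx(base.beta[0, 0, 0], abs=1e-9)

    def test_rank_deficient_design_fails(self, regressor, xreg):
        y = np.zeros((1, 1, 1, 92))
        with pytest.raises(ValueError, match="collinear"):
            fit_cvr_map(_pct_series(y), regressor, confounds=[xreg])

    def test_unit_contract_rescaled_regressor_halves_beta(self, regressor, xreg):
        y = (0.1 * xreg)[None, None, None, :]
        doubled = ck.PetCO2Regressor(values=regressor.values * 2.0, tr_s=3.0)
        cvr = fit_cvr_map(_pct_series(y), doubled)
        assert cvr.beta[0, 0, 0] == pytest.approx(0.05, abs=1e-9)


class TestSummarizeCvr:
    def _masks(self, shape, gm_sel, wm_sel):
        gm = np.zeros(shape, bool)
        wm = np.zeros(shape, bool)
        gm[gm_sel] = True
        wm[wm_sel] = True
        return TissueMasks(gm=gm, wm=wm, csf=np.zeros(shape, bool))

    def _map(self, beta):
        beta = np.asarray(beta, float)
        ones = np.ones_like(beta)
        return ck.CVRMap(beta=beta, tstat=ones, residual_sd=ones, dof=90,
                         mask=np.ones(beta.shape, bool))

    def test_uniform_gm_median(self):
        beta = np.full((4, 4, 4), 0.09)
        masks = self._masks(beta.shape, np.s_[:2], np.s_[2:])
        s = summarize_cvr(self._map(beta), masks)
        assert s.cvr_gm == pytest.approx(0.09)

    def test_lesion_voxels_excluded_from_wm(self):
        beta = np.full((4, 4, 4), 0.05)
        lesion = np.zeros(beta.shape, bool)
        lesion[3, :2, :2] = True
        beta[lesion] = -1.0
        masks = self._masks(beta.shape, np.s_[:2], np.s_[2:])
        s = summarize_cvr(self._map(beta), masks, lesion)
        assert s.cvr_wm == pytest.approx(0.05)
        assert s.cvr_lesion == pytest.approx(-1.0)
        # cvr_wm invariant to arbitrary lesion values
        beta2 = beta.copy()
        beta2[lesion] = 99.0
        s2 = summarize_cvr(self._map(beta2), masks, lesion)
        assert s2.cvr_wm == s.cvr_wm

    def test_median_robust_to_outlier(self):
        beta = np.zeros((4, 1, 1))
        beta[:, 0, 0] = [0.1, 0.2, 0.9, 0.0]
        masks = self._masks(beta.shape, np.s_[:3], np.s_[3:])
        s = summarize_cvr(self._map(beta), masks)
        assert s.cvr_gm == pytest.approx(0.2)  # mean would be 0.4

    def test_empty_roi_after_exclusion_fails(self):
        beta = np.zeros((2, 2, 2))
        masks = self._masks(beta.shape, np.s_[:1], np.s_[1:])
        lesion = np.zeros(beta.shape, bool)
        lesion[1:] = True
        with pytest.raises(ValueError, match="empty"):
            summarize_cvr(self._map(beta), masks, lesion)


class TestRunSubject:
    def test_noiseless_round_trip(self, phantom, paradigm, acq):
        trace = ck.make_capno_trace(paradigm, bh_rise=8.0, noise_sd=0.0)
        truth = ck.make_truth_maps(phantom, cvr_gm=0.105, cvr_wm=0.068)
        reg = ck.build_regressor(trace, acq)
        bold = ck.make_bold(phantom, truth, reg, acq, seed=0)
        res = ck.run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                             phantom.prob_csf, acq)
        assert res["summary"].cvr_gm == pytest.approx(0.105, abs=1e-6)
        assert res["summary"].cvr_wm == pytest.approx(0.068, abs=1e-6)

    def test_noisy_subject_median_concentrates(self, phantom, paradigm, acq):
        trace = ck.make_capno_trace(paradigm, bh_rise=8.0, noise_sd=0.0)
        truth = ck.make_truth_maps(phantom, cvr_gm=0.091, cvr_wm=0.055,
                                   noise_sd=0.005)
        reg = ck.build_regressor(trace, acq)
        bold = ck.make_bold(phantom, truth, reg, acq, seed=42)
        res = ck.run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                             phantom.prob_csf, acq)
        assert res["summary"].cvr_gm == pytest.approx(0.091, abs=0.01)

    def test_rerun_is_bit_identical(self, phantom, paradigm, acq):
        trace = ck.make_capno_trace(paradigm, bh_rise=8.0, noise_sd=1.0, seed=5)
        truth = ck.make_truth_maps(phantom, noise_sd=0.002)
        reg = ck.build_regressor(trace, acq)
        bold = ck.make_bold(phantom, truth, reg, acq, seed=5)
        r1 = ck.run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                            phantom.prob_csf, acq)
        r2 = ck.run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                            phantom.prob_csf, acq)
        assert r1["summary"].cvr_gm == r2["summary"].cvr_gm
        assert np.array_equal(r1["cvr_map"].beta, r2["cvr_map"].beta)

    def test_estimator_unbiased_over_replicates(self, phantom, paradigm, acq):
        trace = ck.make_capno_trace(paradigm, bh_rise=8.0, noise_sd=0.0)
        reg = ck.build_regressor(trace, acq)
        truth_val = 0.091
        estimates = []
        for seed in range(25):
            truth = ck.make_truth_maps(phantom, cvr_gm=truth_val, noise_sd=0.005)
            bold = ck.make_bold(phantom, truth, reg, acq, seed=seed)
            res = ck.run_subject(bold, trace, phantom.prob_gm, phantom.prob_wm,
                                 phantom.prob_csf, acq)
            estimates.append(res["summary"].cvr_gm)
        assert abs(np.mean(estimates) - truth_val) < 0.02 * truth_val
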