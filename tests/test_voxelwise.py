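"""TFCE against brute-force oracles; permutation inference properties."""
import numpy as np
import pytest

import cvrkit as ck
from cvrkit.voxelwise import PermutationScheme, TFCEParams
from _oracles import tfce_bruteforce


class TestTfceEnhance:
    def test_single_voxel_closed_form(self):
        stat = np.zeros((5, 5, 5))
        stat[2, 2, 2] = 1.0
        params = TFCEParams(E=0.5, H=2.0, dh=0.1)
        out = ck.tfce_enhance(stat, params=params)
        # sum over h = 0.1k, k = 1..10 of 1^0.5 * h^2 * 0.1 = 0.001 * sum k^2
        expected = 0.001 * sum(k**2 for k in range(1, 11))
        assert out[2, 2, 2] == pytest.approx(expected, abs=1e-9)
        assert expected == pytest.approx(0.385)

    def test_uniform_cuboid_shares_one_value(self):
        stat = np.zeros((8, 8, 8))
        stat[2:5, 2:6, 3:5] = 0.7
        n = 3 * 4 * 2
        params = TFCEParams(dh=0.07)
        out = ck.tfce_enhance(stat, params=params)
        member_vals = out[stat > 0]
        expected = sum(
            (n**0.5) * ((0.07 * k) ** 2) * 0.07 for k in range(1, 11)
        )
        assert np.allclose(member_vals, member_vals[0])
        assert member_vals[0] == pytest.approx(expected, rel=1e-9)
        assert np.all(out[stat == 0] == 0)

    @pytest.mark.parametrize("seed", [0, 1, 2])
    @pytest.mark.parametrize("connectivity", [6, 26])
    def test_matches_bruteforce_oracle_on_random_maps(self, seed, connectivity):
        rng = np.random.default_rng(seed)
        stat = rng.normal(size=(8, 8, 8))
        mask = rng.random((8, 8, 8)) > 0.2
        dh = 0.11
        params = TFCEParams(dh=dh, connectivity=connectivity)
        out = ck.tfce_enhance(stat, mask, params)
        oracle = tfce_bruteforce(stat, mask, 0.5, 2.0, dh, connectivity)
        assert np.allclose(out, oracle, atol=1e-6)

    def test_monotone_in_voxel_heights(self):
        rng = np.random.default_rng(3)
        stat = np.clip(rng.normal(0.5, 0.3, size=(6, 6, 6)), 0, None)
        params = TFCEParams(dh=0.05)
        base = ck.tfce_enhance(stat, params=params)
        bumped = stat.copy()
        bumped[3, 3, 3] += 0.4
        out = ck.tfce_enhance(bumped, params=params)
        assert np.all(out >= base - 1e-12)

    def test_all_zero_map(self):
        assert np.all(ck.tfce_enhance(np.zeros((6, 6, 6))) == 0)

    def test_negative_lobe_antisymmetric(self):
        rng = np.random.default_rng(4)
        stat = rng.normal(size=(6, 6, 6))
        params = TFCEParams(dh=0.1)
        assert np.allclose(
            ck.tfce_enhance(-stat, params=params),
            -ck.tfce_enhance(stat, params=params),
            atol=1e-12,
        )


def _noise_stack(n, shape, seed, effect=0.0, block=None):
    rng = np.random.default_rng(seed)
    data = rng.normal(0.0, 1.0, size=(n,) + shape)
    if block is not None:
        data[(slice(None),) + block] += effect
    return data


class TestPermutationPmap:
    def test_deterministic_given_seed(self):
        data = _noise_stack(8, (8, 8, 8), seed=0)
        scheme = PermutationScheme("one-sample", n_perm=150, seed=5)
        a = ck.permutation_pmap(data, scheme, smoothing_sigma_mm=0.0)
        b = ck.permutation_pmap(data, scheme, smoothing_sigma_mm=0.0)
        assert np.array_equal(a["p_map"], b["p_map"])

    def test_subject_order_invariance_with_exhaustive_flips(self):
        data = _noise_stack(7, (6, 6, 6), seed=1)
        scheme = PermutationScheme("one-sample", n_perm=128, seed=0)  # 2^7 = 128
        a = ck.permutation_pmap(data, scheme, smoothing_sigma_mm=0.0)
        b = ck.permutation_pmap(data[::-1], scheme, smoothing_sigma_mm=0.0)
        assert np.allclose(a["p_map"], b["p_map"])

    def test_focal_effect_detected_background_clean(self):
        block = (slice(5, 10), slice(5, 10), slice(5, 10))
        data = _noise_stack(20, (16, 16, 16), seed=2, effect=3.0, block=block)
        scheme = PermutationScheme("one-sample", n_perm=500, seed=3)
        out = ck.permutation_pmap(data, scheme, smoothing_sigma_mm=4.0,
                                  voxel_mm=(3.0, 3.0, 3.0))
        sig = out["p_map"] < 0.05
        in_block = np.zeros((16, 16, 16), bool)
        in_block[block] = True
        # the smoothed effect spreads ~sigma past the block edge; judge
        # specificity on background beyond that reach (Chebyshev dist >= 4)
        near = np.zeros((16, 16, 16), bool)
        near[2:13, 2:13, 2:13] = True
        far_bg = ~near & ~in_block
        assert sig[in_block].mean() >= 0.8
        assert sig[far_bg].mean() < 0.01

    def test_two_sample_detects_group_difference(self):
        shape = (10, 10, 10)
        a = _noise_stack(10, shape, seed=6, effect=2.5,
                         block=(slice(3, 7), slice(3, 7), slice(3, 7)))
        b = _noise_stack(10, shape, seed=7)
        out = ck.group_difference_maps(
            a, b, contrast="MS-vs-HC", paired=False,
            scheme=PermutationScheme("two-sample", n_perm=300, seed=1),
            smoothing_sigma_mm=4.0,
        )
        assert out["n_significant"] > 0
        assert out["p_map"].min() < 0.05

    def test_minimum_attainable_p_warning(self):
        data = _noise_stack(5, (6, 6, 6), seed=8)
        # 2^5 = 32 exhaustive sign flips: min p = 1/33 > 0.029... fine at 0.05
        # but 1/(n+1) > alpha triggers the warning for tiny n_perm requests
        scheme = PermutationScheme("one-sample", n_perm=100, seed=0)
        out = ck.permutation_pmap(data, scheme, smoothing_sigma_mm=0.0)
        assert out["n_permutations"] == 32


class TestGroupDifferenceMaps:
    def test_paired_mean_recovers_uniform_shift(self):
        rng = np.random.default_rng(9)
        diffs = 0.016 + rng.normal(0, 0.004, size=(12, 8, 8, 8))
        out = ck.group_difference_maps(
            diffs, contrast="on-vs-pre", paired=True,
            scheme=PermutationScheme("one-sample", n_perm=200, seed=2),
            smoothing_sigma_mm=0.0,
        )
        assert out["mean_map"].mean() == pytest.approx(0.016, abs=0.002)

    def test_contrast_flip_negates_maps(self):
        rng = np.random.default_rng(10)
        a = rng.normal(0.1, 0.02, size=(8, 6, 6, 6))
        b = rng.normal(0.09, 0.02, size=(8, 6, 6, 6))
        scheme = PermutationScheme("one-sample", n_perm=200, seed=4)
        fwd = ck.group_difference_maps(a, b, paired=True, scheme=scheme,
                                       smoothing_sigma_mm=0.0)
        rev = ck.group_difference_maps(b, a, paired=True, scheme=scheme,
                                       smoothing_sigma_mm=0.0)
        assert np.allclose(fwd["mean_map"], -rev["mean_map"], atol=1e-12)
        assert np.allclose(fwd["t_map"], -rev["t_map"], atol=1e-9)
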