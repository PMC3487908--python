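"""Kendall's W against independent oracles, map construction, smoothing."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st
from hypothesis.extra.numpy import arrays
from scipy.stats import spearmanr

from rehoscope import reho, synth
from rehoscope.core_io import Bold4D, BrainMask


# ---------------------------------------------------------------------------
# Independent oracles
# ---------------------------------------------------------------------------

def naive_midranks(x):
    """Rank with midranks by direct comparison counting (O(n^2))."""
    n = len(x)
    out = np.empty(n)
    for i in range(n):
        less = sum(1 for v in x if v < x[i])
        equal = sum(1 for v in x if v == x[i])
        out[i] = less + (equal + 1) / 2.0
    return out


def kendall_w_bruteforce(arr):
    """Direct rank-sum evaluation with explicit loops and tie correction."""
    K, n = arr.shape
    ranks = np.array([naive_midranks(arr[j]) for j in range(K)])
    R = [sum(ranks[j][i] for j in range(K)) for i in range(n)]
    Rbar = K * (n + 1) / 2.0
    S = sum((r - Rbar) ** 2 for r in R)
    T = 0.0
    for j in range(K):
        for val in set(arr[j]):
            t = int(np.sum(arr[j] == val))
            T += t ** 3 - t
    denom = (K * K * (n ** 3 - n) - K * T) / 12.0
    return S / denom if denom > 0 else 0.0


def kendall_w_from_spearman(arr):
    """Tie-free identity: W = ((K-1) * mean pairwise Spearman rho + 1) / K."""
    K = arr.shape[0]
    rhos = [spearmanr(arr[i], arr[j]).statistic
            for i in range(K) for j in range(i + 1, K)]
    return ((K - 1) * float(np.mean(rhos)) + 1.0) / K


class TestRankSeries:
    def test_strict_ordering(self):
        np.testing.assert_array_equal(reho.rank_series([3.1, 1.2, 2.0]), [3, 1, 2])

    def test_midranks_for_ties(self):
        np.testing.assert_array_equal(reho.rank_series([5, 5, 1]), [2.5, 2.5, 1])

    def test_invariant_under_monotone_transform(self, rng):
        x = rng.standard_normal(40)
        np.testing.assert_array_equal(reho.rank_series(x),
                                      reho.rank_series(np.exp(x)))

    def test_nonfinite_rejected(self):
        with pytest.raises(ValueError, match="non-finite"):
            reho.rank_series([1.0, np.nan, 2.0])


class TestKendallW:
    def test_identical_series_give_one(self):
        arr = np.tile(np.arange(12, dtype=float), (5, 1))
        assert reho.kendall_w(arr) == pytest.approx(1.0)

    def test_two_series_exact_negation_gives_zero(self, rng):
        x = rng.standard_normal(20)     # n even, continuous -> no ties
        assert reho.kendall_w(np.vstack([x, -x])) == pytest.approx(0.0, abs=1e-12)

    def test_matches_both_oracles_on_random_instances(self, rng):
        # 100 random instances spanning K up to 27 and n up to 30, checked
        # against the exhaustive rank-sum oracle and the Spearman identity.
        for trial in range(100):
            K = int(rng.integers(2, 28))
            n = int(rng.integers(3, 31))
            arr = rng.standard_normal((K, n))
            w = reho.kendall_w(arr)
            assert w == pytest.approx(kendall_w_bruteforce(arr), abs=1e-10)
            assert w == pytest.approx(kendall_w_from_spearman(arr), abs=1e-10)

    def test_tied_data_matches_bruteforce(self, rng):
        for trial in range(20):
            K = int(rng.integers(2, 8))
            n = int(rng.integers(4, 15))
            arr = rng.integers(0, 4, size=(K, n)).astype(float)
            if np.all(arr.std(axis=1) == 0):
                continue
            assert reho.kendall_w(arr) == pytest.approx(
                kendall_w_bruteforce(arr), abs=1e-10)

    def test_all_constant_series_degenerate_returns_zero(self):
        assert reho.kendall_w(np.ones((4, 10))) == 0.0

    def test_invariant_under_per_series_monotone_transform(self, rng):
        arr = rng.standard_normal((6, 25))
        transformed = np.vstack([np.exp(arr[0]), arr[1] ** 3 + 5,
                                 2 * arr[2] - 1, np.arctan(arr[3]),
                                 arr[4], np.expm1(arr[5])])
        assert reho.kendall_w(transformed) == pytest.approx(
            reho.kendall_w(arr), abs=1e-12)

    def test_independence_floor_near_one_over_k(self, rng):
        # For independent continuous series E[W] ~ 1/K; at K=27, n=230 the
        # Monte-Carlo mean sits in a narrow band (stability check).
        ws = [reho.kendall_w(rng.standard_normal((27, 230))) for _ in range(300)]
        assert 0.030 < np.mean(ws) < 0.045

    @settings(max_examples=50, deadline=None, derandomize=True)
    @given(arrays(np.float64, (4, 8),
                  elements=st.floats(-100.0, 100.0, allow_nan=False, width=16)),
           st.floats(0.1, 100.0), st.floats(-50.0, 50.0))
    def test_bounds_and_affine_invariance_property(self, arr, scale, shift):
        if np.any(arr.std(axis=1) == 0):
            w = reho.kendall_w(arr)
            assert 0.0 <= w <= 1.0
            return
        w = reho.kendall_w(arr)
        assert 0.0 <= w <= 1.0
        assert reho.kendall_w(scale * arr + shift) == pytest.approx(w, abs=1e-9)

    def test_monotone_in_planted_shared_fraction(self, rng):
        medians = []
        for rho in (0.0, 0.3, 0.6, 0.9):
            ws = []
            for _ in range(40):
                shared = rng.standard_normal(60)
                arr = (np.sqrt(rho) * shared
                       + np.sqrt(1 - rho) * rng.standard_normal((27, 60)))
                ws.append(reho.kendall_w(arr))
            medians.append(np.median(ws))
        assert all(b > a for a, b in zip(medians, medians[1:]))


class TestNeighborhood:
    @pytest.mark.parametrize("K,expected", [(7, 7), (19, 19), (27, 27)])
    def test_offset_counts(self, K, expected):
        offs = reho.neighborhood_offsets(K)
        assert len(offs) == expected
        assert (np.abs(offs) <= 1).all()
        assert any((o == 0).all() for o in offs)

    def test_invalid_K_rejected(self):
        with pytest.raises(ValueError, match="K"):
            reho.neighborhood_offsets(9)


class TestReHoMap:
    def _uniform_bold(self, series, shape=(5, 5, 5)):
        data = np.tile(series, shape + (1,))
        return Bold4D(data=data, affine=np.eye(4), tr=2.0)

    def test_identical_series_volume_gives_one_everywhere_in_mask(self, rng):
        series = rng.standard_normal(30)
        bold = self._uniform_bold(series)
        mask = BrainMask(data=np.ones((5, 5, 5), dtype=bool), affine=np.eye(4))
        m = reho.reho_map(bold, mask, K=27)
        assert np.allclose(m.w[mask.data], 1.0)

    def test_single_voxel_mask_gets_zero(self, rng):
        bold = Bold4D(data=rng.standard_normal((5, 5, 5, 30)),
                      affine=np.eye(4), tr=2.0)
        mask_data = np.zeros((5, 5, 5), dtype=bool)
        mask_data[2, 2, 2] = True
        m = reho.reho_map(bold, BrainMask(data=mask_data, affine=np.eye(4)))
        assert m.w[2, 2, 2] == 0.0

    def test_matches_direct_kendall_w_at_interior_voxel(self, rng):
        bold = Bold4D(data=rng.standard_normal((5, 5, 5, 25)),
                      affine=np.eye(4), tr=2.0)
        mask = BrainMask(data=np.ones((5, 5, 5), dtype=bool), affine=np.eye(4))
        m = reho.reho_map(bold, mask, K=27)
        offs = reho.neighborhood_offsets(27)
        centre = np.array([2, 2, 2])
        series = np.stack([bold.data[tuple(centre + o)] for o in offs])
        assert m.w[2, 2, 2] == pytest.approx(reho.kendall_w(series), abs=1e-10)

    def test_edge_voxel_uses_reduced_neighborhood(self, rng):
        bold = Bold4D(data=rng.standard_normal((4, 4, 4, 20)),
                      affine=np.eye(4), tr=2.0)
        mask = BrainMask(data=np.ones((4, 4, 4), dtype=bool), affine=np.eye(4))
        m = reho.reho_map(bold, mask, K=27)
        corner_series = np.stack([bold.data[i, j, k]
                                  for i in (0, 1) for j in (0, 1) for k in (0, 1)])
        assert m.w[0, 0, 0] == pytest.approx(reho.kendall_w(corner_series), abs=1e-10)

    def test_planted_synchrony_elevates_w_over_null_cohort(self, scaled_design):
        # One-sided Monte-Carlo: in-region W under planted rho=0.6 exceeds
        # in-region W of matched rho=0 subjects for every paired seed.
        import dataclasses

        from rehoscope import preprocess
        d6 = scaled_design
        d0 = dataclasses.replace(
            d6, effect_regions=synth.default_effect_regions(rho_hc=0.0,
                                                            rho_bd=0.0))
        mask = d6.brain_mask()
        r = d6.effect_regions[1]
        plant = synth.region_voxel_mask(d6.shape, d6.affine, r.center_mm,
                                        r.radius_mm) & mask.data
        diffs = []
        for seed in range(4):
            vals = []
            for d in (d6, d0):
                bold, motion = synth.generate_subject(d, "BD", 900 + seed)
                pre, _ = preprocess.preprocess_subject(bold, motion, mask,
                                                       band=d.band)
                vals.append(reho.reho_map(pre, mask).w[plant].mean())
            diffs.append(vals[0] - vals[1])
        assert all(x > 0.05 for x in diffs)

    def test_grid_mismatch_rejected(self, rng):
        bold = Bold4D(data=rng.standard_normal((5, 5, 5, 20)),
                      affine=np.eye(4), tr=2.0)
        mask = BrainMask(data=np.ones((6, 6, 6), dtype=bool), affine=np.eye(4))
        with pytest.raises(ValueError, match="grid"):
            reho.reho_map(bold, mask)


class TestNormalizeMap:
    def _map_from(self, w, mask_data):
        mask = BrainMask(data=mask_data, affine=np.eye(4))
        return reho.ReHoMap(w=w, mask=mask, K=27, n=100)

    def test_constant_map_becomes_ones(self):
        mask_data = np.ones((4, 4, 4), dtype=bool)
        m = self._map_from(np.full((4, 4, 4), 0.37), mask_data)
        out = reho.normalize_map(m)
        assert np.allclose(out.w[mask_data], 1.0)

    def test_mean_is_one_and_scale_invariant(self, rng):
        mask_data = rng.random((6, 6, 6)) > 0.4
        w = np.abs(rng.standard_normal((6, 6, 6))) * mask_data
        m = self._map_from(w, mask_data)
        out1 = reho.normalize_map(m)
        assert out1.w[mask_data].mean() == pytest.approx(1.0, abs=1e-6)
        out5 = reho.normalize_map(self._map_from(5 * w, mask_data))
        np.testing.assert_allclose(out5.w, out1.w, atol=1e-12)

    def test_nonpositive_mean_rejected(self):
        mask_data = np.ones((3, 3, 3), dtype=bool)
        with pytest.raises(ValueError, match="mean"):
            reho.normalize_map(self._map_from(np.zeros((3, 3, 3)), mask_data))


def dense_gaussian_convolution(img, sigmas, radius=5):
    """Direct dense convolution oracle with an explicitly built kernel."""
    ax = [np.arange(-radius, radius + 1)] * 3
    kern = np.ones((2 * radius + 1,) * 3)
    for d, s in enumerate(sigmas):
        shape = [1, 1, 1]
        shape[d] = -1
        g = np.exp(-ax[d] ** 2 / (2 * s * s))
        kern = kern * g.reshape(shape)
    kern /= kern.sum()
    out = np.zeros_like(img)
    n = img.shape[0]
    for i in range(n):
        for j in range(n):
            for k in range(n):
                if img[i, j, k] == 0:
                    continue
                for di in range(-radius, radius + 1):
                    for dj in range(-radius, radius + 1):
                        for dk in range(-radius, radius + 1):
                            ii, jj, kk = i + di, j + dj, k + dk
                            if 0 <= ii < n and 0 <= jj < n and 0 <= kk < n:
                                out[ii, jj, kk] += img[i, j, k] * \
                                    kern[di + radius, dj + radius, dk + radius]
    return out


class TestGaussianSmooth:
    def test_fwhm_zero_is_identity(self, rng):
        img = rng.standard_normal((5, 5, 5))
        np.testing.assert_array_equal(reho.gaussian_smooth(img, 0.0, np.eye(4)), img)

    def test_interior_impulse_matches_dense_convolution_oracle(self):
        aff = np.eye(4)
        aff[:3, :3] = np.diag([3.0, 3.0, 3.0])
        img = np.zeros((11, 11, 11))
        img[5, 5, 5] = 1.0
        out = reho.gaussian_smooth(img, 4.0, aff)
        sigma_vox = 4.0 * reho.FWHM_TO_SIGMA / 3.0
        # same truncation radius scipy uses (truncate=4 sigma)
        radius = int(4.0 * sigma_vox + 0.5)
        oracle = dense_gaussian_convolution(img, [sigma_vox] * 3, radius=radius)
        np.testing.assert_allclose(out, oracle, atol=1e-8)
        assert out.sum() == pytest.approx(1.0, abs=1e-5)   # kernel sums to 1

    def test_anisotropic_voxels_get_per_axis_sigma(self):
        aff = np.eye(4)
        aff[:3, :3] = np.diag([2.0, 4.0, 2.0])
        img = np.zeros((11, 11, 11))
        img[5, 5, 5] = 1.0
        out = reho.gaussian_smooth(img, 8.0, aff)
        # wider spread (more smoothing) along the finer-resolution axis
        assert out[3, 5, 5] > out[5, 3, 5]

    def test_constant_interior_preserved(self):
        img = np.ones((11, 11, 11))
        out = reho.gaussian_smooth(img, 4.0, np.eye(4) * 3)
        assert out[5, 5, 5] == pytest.approx(1.0, rel=1e-6)

    def test_negative_fwhm_rejected(self):
        with pytest.raises(ValueError, match="fwhm"):
            reho.gaussian_smooth(np.zeros((4, 4, 4)), -1.0, np.eye(4))
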