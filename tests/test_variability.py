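"""Windowed connectivity, the variability statistic, and group contrasts."""

import numpy as np
import pandas as pd
import pytest

from plastometrics import synthetic
from plastometrics.variability import (
    DEFAULT_WINDOW_LENGTHS,
    SUBNETWORKS,
    RegionTimeSeries,
    TemporalVariability,
    VariabilityProfile,
    WindowedConnectivity,
    flip_to_lesion_right,
    load_default_subnetworks,
    multiscale_variability,
    partition_windows,
    prepost_region_contrast,
    regional_variability,
    subnetwork_aggregate,
    windowlength_consistency,
)


def brute_force_variability(windows, k):
    """Independent oracle: materialise every profile pair, average np.corrcoef."""
    profiles = []
    for W in windows:
        row = np.delete(W[k], k)
        profiles.append(row)
    corrs = []
    for i in range(len(profiles)):
        for j in range(i + 1, len(profiles)):
            corrs.append(np.corrcoef(profiles[i], profiles[j])[0, 1])
    return 1.0 - float(np.mean(corrs))


def random_series(rng, n_regions=6, T=40):
    return rng.standard_normal((n_regions, T))


class TestPartitionWindows:
    @pytest.mark.parametrize("L,n_expected", [(10, 23), (28, 8)])
    def test_floor_division_window_count(self, L, n_expected):
        wc = partition_windows(np.random.default_rng(0).standard_normal((5, 230)), L)
        assert wc.n_windows == n_expected
        assert all(W.shape == (5, 5) for W in wc.windows)

    def test_perfectly_correlated_pair(self):
        rng = np.random.default_rng(1)
        base = rng.standard_normal(60)
        data = np.vstack([base, 2 * base + 3, rng.standard_normal(60)])
        wc = partition_windows(data, 20)
        for W in wc.windows:
            assert W[0, 1] == pytest.approx(1.0)

    def test_adjacency_is_symmetric_unit_diagonal(self):
        wc = partition_windows(np.random.default_rng(2).standard_normal((6, 80)), 20)
        for W in wc.windows:
            assert np.allclose(W, W.T)
            assert np.allclose(np.diag(W), 1.0)
            assert np.abs(W).max() <= 1.0

    def test_constant_region_zeroed_with_warning(self):
        data = np.random.default_rng(3).standard_normal((4, 40))
        data[2] = 5.0
        with pytest.warns(UserWarning, match="constant"):
            wc = partition_windows(data, 20)
        assert all(np.all(W[2, [0, 1, 3]] == 0.0) for W in wc.windows)

    def test_too_few_windows_error(self):
        with pytest.raises(ValueError, match="at least 2"):
            partition_windows(np.zeros((3, 25)) + np.random.default_rng(0).standard_normal((3, 25)), 20)


class TestRegionalVariability:
    def test_identical_profiles_give_zero(self):
        W = np.random.default_rng(0).uniform(-1, 1, size=(4, 4))
        W = (W + W.T) / 2
        np.fill_diagonal(W, 1.0)
        wc = WindowedConnectivity(10, [W.copy() for _ in range(5)])
        assert regional_variability(wc, 0) == pytest.approx(0.0, abs=1e-12)

    def test_anticorrelated_two_windows_give_two(self):
        # profile of region 0 flips sign between the two windows
        profile = np.array([0.5, -0.3, 0.8])
        W1 = np.eye(4)
        W1[0, 1:] = profile
        W1[1:, 0] = profile
        W2 = np.eye(4)
        W2[0, 1:] = -profile
        W2[1:, 0] = -profile
        wc = WindowedConnectivity(10, [W1, W2])
        assert regional_variability(wc, 0) == pytest.approx(2.0)

    def test_three_windows_pairwise_correlations_one_zero_zero(self):
        # profiles p, p, q with corr(p,q)=0 -> mean pair corr = 1/3 -> V = 2/3
        p = np.array([1.0, -1.0, 1.0, -1.0])
        q = np.array([1.0, 1.0, -1.0, -1.0])
        assert abs(np.corrcoef(p, q)[0, 1]) < 1e-12
        windows = []
        for prof in (p, p, q):
            W = np.eye(5)
            W[0, 1:] = prof
            W[1:, 0] = prof
            windows.append(W)
        wc = WindowedConnectivity(10, windows)
        assert regional_variability(wc, 0) == pytest.approx(2.0 / 3.0)

    @pytest.mark.parametrize("seed", range(10))
    def test_matches_brute_force_oracle(self, seed):
        rng = np.random.default_rng(seed)
        wc = partition_windows(random_series(rng), 10)
        fast = regional_variability(wc)
        for k in range(6):
            assert fast[k] == pytest.approx(brute_force_variability(wc.windows, k),
                                            abs=1e-12)

    def test_bounds_and_invariances(self):
        rng = np.random.default_rng(99)
        data = random_series(rng, n_regions=8, T=60)
        wc = partition_windows(data, 15)
        v = regional_variability(wc)
        assert np.all((v >= 0) & (v <= 2))
        # per-region affine rescaling of the BOLD series leaves V unchanged
        scaled = data * rng.uniform(0.5, 3.0, size=(8, 1)) + rng.normal(size=(8, 1))
        assert np.allclose(regional_variability(partition_windows(scaled, 15)), v)
        # permuting window order leaves the pair mean unchanged
        perm = WindowedConnectivity(15, [wc.windows[i] for i in (3, 0, 2, 1)])
        assert np.allclose(regional_variability(perm), v)


class TestMultiscale:
    def test_singleton_length_equals_single_scale(self, bold_dataset):
        ts, _, _ = bold_dataset
        profile = multiscale_variability(ts, window_lengths=(10,))
        direct = regional_variability(partition_windows(ts, 10))
        assert np.allclose(profile.values, direct)

    def test_flexible_regions_rank_higher(self, bold_dataset):
        ts, flexible, _ = bold_dataset
        v = multiscale_variability(ts).values
        stable = np.setdiff1d(np.arange(ts.n_regions), flexible)
        assert v[flexible].mean() - v[stable].mean() > 0.1

    def test_offending_lengths_reported(self, bold_dataset):
        ts, _, _ = bold_dataset
        with pytest.raises(ValueError, match="200"):
            multiscale_variability(ts, window_lengths=(10, 200))

    def test_transformer_matches_function_and_stacks(self, bold_dataset):
        ts, _, _ = bold_dataset
        est = TemporalVariability(window_lengths=(10, 20))
        single = est.fit(ts.data).transform(ts.data)
        assert np.allclose(single, multiscale_variability(ts, (10, 20)).values)
        stacked = est.transform(np.stack([ts.data, ts.data]))
        assert stacked.shape == (2, ts.n_regions)
        assert np.allclose(stacked[0], stacked[1])

    def test_transformer_get_set_params_round_trip(self):
        est = TemporalVariability()
        params = est.get_params()
        assert params["window_lengths"] == DEFAULT_WINDOW_LENGTHS
        est.set_params(window_lengths=(12, 14))
        assert est.fit(np.zeros((2, 60))).window_lengths_ == (12, 14)


class TestWindowlengthConsistency:
    def test_duplicate_length_is_unit_correlation(self, bold_dataset):
        ts, _, _ = bold_dataset
        frame = windowlength_consistency(ts, (10, 10))
        assert frame.iloc[0, 1] == pytest.approx(1.0)

    def test_independent_noise_shows_no_consistency(self):
        # the diagnostic is driven by shared structure in the data: V
        # vectors computed from unrelated homogeneous noise are uncorrelated
        rng = np.random.default_rng(0)
        rs = []
        for _ in range(5):
            a = rng.standard_normal((84, 230))
            b = rng.standard_normal((84, 230))
            v_a = regional_variability(partition_windows(a, 14))
            v_b = regional_variability(partition_windows(b, 16))
            rs.append(np.corrcoef(v_a, v_b)[0, 1])
        assert abs(np.mean(rs)) < 0.3
        # note: permuting the time axis of ONE dataset is not enough —
        # permutation-invariant marginal heterogeneity keeps V correlated


class TestFlip:
    @staticmethod
    def profile():
        return VariabilityProfile(
            region_labels=("M1_L", "M1_R", "SPL_L", "SPL_R"),
            values=np.array([1.0, 2.0, 3.0, 4.0]),
            window_lengths_used=(10,),
        )

    def test_right_lesion_identity(self):
        p = self.profile()
        assert flip_to_lesion_right(p, "R") is p

    def test_left_lesion_swaps_pairs_and_is_involutive(self):
        p = self.profile()
        flipped = flip_to_lesion_right(p, "L")
        assert list(flipped.values) == [2.0, 1.0, 4.0, 3.0]
        twice = flip_to_lesion_right(flipped, "L")
        assert np.allclose(twice.values, p.values)

    def test_unpaired_label_error(self):
        p = VariabilityProfile(("M1_L",), np.array([1.0]), (10,))
        with pytest.raises(ValueError, match="partner"):
            flip_to_lesion_right(p, "L")


class TestSubnetworks:
    def test_constant_values_give_constant_means(self):
        mapping = load_default_subnetworks()
        labels = tuple(mapping)
        profile = VariabilityProfile(labels, np.full(len(labels), 0.7), (10,))
        means = subnetwork_aggregate(profile, mapping)
        assert set(means) == set(SUBNETWORKS)
        assert all(v == pytest.approx(0.7) for v in means.values())

    def test_default_map_covers_84_paired_regions(self):
        mapping = load_default_subnetworks()
        assert len(mapping) == 84
        assert set(mapping.values()) == set(SUBNETWORKS)
        for label in mapping:
            mirror = label[:-1] + ("R" if label.endswith("L") else "L")
            assert mirror in mapping

    def test_unmapped_region_error(self):
        profile = VariabilityProfile(("X_L", "X_R"), np.array([1.0, 2.0]), (10,))
        with pytest.raises(ValueError, match="X_L"):
            subnetwork_aggregate(profile, {"X_R": "SMA"})


class TestPrepostContrast:
    def test_no_change_no_significance(self):
        rng = np.random.default_rng(0)
        pre = rng.uniform(0, 2, size=(8, 10))
        result = prepost_region_contrast(pre, pre.copy(), [f"r{i}" for i in range(10)])
        assert not result["significant"].any()

    def test_alpha_zero_empty_set(self):
        rng = np.random.default_rng(1)
        pre = rng.uniform(0, 2, size=(8, 5))
        post = pre + rng.normal(0, 0.1, size=pre.shape)
        result = prepost_region_contrast(pre, post, list("abcde"), alpha=0.0)
        assert not result["significant"].any()

    def test_power_to_recover_shifted_regions(self):
        # +delta on 3 designated regions, delta = 2x noise SD, n=8 subjects
        hits, total = 0, 0
        for seed in range(50):
            rng = np.random.default_rng(seed)
            pre = rng.uniform(0.5, 1.5, size=(8, 20))
            noise = rng.normal(0, 0.1, size=pre.shape)
            post = pre + noise
            post[:, :3] += 0.2
            res = prepost_region_contrast(pre, post, [f"r{i}" for i in range(20)])
            hits += res["significant"].iloc[:3].sum()
            total += 3
        assert hits / total >= 0.8

    def test_bh_option_is_no_looser(self):
        rng = np.random.default_rng(2)
        pre = rng.uniform(0, 2, size=(8, 12))
        post = pre + rng.normal(0, 0.2, size=pre.shape)
        raw = prepost_region_contrast(pre, post, [f"r{i}" for i in range(12)])
        bh = prepost_region_contrast(pre, post, [f"r{i}" for i in range(12)],
                                     correction="bh")
        assert bh["significant"].sum() <= raw["significant"].sum()

    def test_shape_mismatch_error(self):
        with pytest.raises(ValueError, match="same"):
            prepost_region_contrast(np.zeros((4, 3)), np.zeros((5, 3)), list("abc"))
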