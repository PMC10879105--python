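"""Synthetic generator: patterns, trial model, determinism, SNR control."""

import numpy as np
import pytest
from dataclasses import replace

from oracles import flood_fill_components
from suitas import glm, simulate
from suitas.images import unvectorize
from suitas.simulate import SyntheticSpec


class TestMakePattern:
    def test_unit_norm_and_compact_support(self, small_mask):
        pat = simulate.make_pattern(small_mask, n_blobs=1, blob_radius_mm=6.0, seed=0)
        assert np.isclose(np.linalg.norm(pat.values), 1.0)
        assert 0 < np.count_nonzero(pat.values) < small_mask.n_voxels

    def test_deterministic_given_seed(self, small_mask):
        a = simulate.make_pattern(small_mask, n_blobs=2, blob_radius_mm=6.0, seed=3)
        b = simulate.make_pattern(small_mask, n_blobs=2, blob_radius_mm=6.0, seed=3)
        np.testing.assert_array_equal(a.values, b.values)

    def test_three_blobs_are_three_components(self):
        mask = simulate.ellipsoid_mask(simulate.default_grid(shape=(18, 18, 15)))
        pat = simulate.make_pattern(mask, n_blobs=3, blob_radius_mm=7.5, seed=1)
        support = unvectorize((pat.values != 0).astype(float), mask) > 0
        assert flood_fill_components(support) == 3

    def test_impossible_placement_raises(self, small_mask):
        with pytest.raises(simulate.PatternPlacementError):
            simulate.make_pattern(small_mask, n_blobs=50, blob_radius_mm=9.0, seed=0)

    def test_avoid_support_respected(self, small_mask):
        a = simulate.make_pattern(small_mask, n_blobs=1, blob_radius_mm=5.0, seed=0)
        b = simulate.make_pattern(
            small_mask, n_blobs=1, blob_radius_mm=5.0, seed=1, avoid=a.values != 0
        )
        assert not np.any((a.values != 0) & (b.values != 0))


class TestSimulateTrials:
    def test_noiseless_limit_reproduces_scaled_pattern(self, small_mask):
        spec = SyntheticSpec(
            n_participants=1, n_runs=1, noise_sd=1e-12,
            confound_amplitude=0.0, visual_amplitude=0.0, gain_sigma=0.0,
        )
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        gt.per_participant_gain[:] = 1.0
        bs = simulate.simulate_trials(spec, gt, 0)
        for i, row in bs.table.iterrows():
            np.testing.assert_allclose(
                bs.data[i], row["rating"] * gt.anxiety_pattern.values, atol=1e-6
            )

    def test_condition_means_ordered(self, small_mask):
        spec = SyntheticSpec(n_participants=1, n_runs=6, rating_sd=1e-9)
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        table = simulate.simulate_trials(spec, gt, 0).table
        means = table.groupby("condition", sort=False)["rating"].mean()
        assert means["safety"] < means["low"] < means["medium"] < means["high"]

    def test_trial_count_and_shock_flags(self, small_cohort):
        spec, series, _, _ = small_cohort
        bs = series[0]
        assert len(bs.table) == spec.n_trials
        assert not bs.table.loc[bs.table.condition == "safety", "shock_followed"].any()

    def test_confound_correlation_calibrated(self, small_mask):
        # Monte-Carlo check of the shared-latent (Gaussian-copula) generator
        spec = SyntheticSpec(
            n_participants=1, n_runs=25, trials_per_condition_per_run=100,
            confound_rating_correlation=0.5,
        )
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        table = simulate.simulate_trials(spec, gt, 0).table
        assert len(table) == 10_000
        r = np.corrcoef(table["confound"], table["rating"])[0, 1]
        assert abs(r - 0.5) < 0.03

    def test_byte_identical_under_fixed_seed(self, small_mask):
        spec = SyntheticSpec(n_participants=2, n_runs=1, seed=5)
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        a = simulate.simulate_trials(spec, gt, 1)
        b = simulate.simulate_trials(spec, gt, 1)
        np.testing.assert_array_equal(a.data, b.data)
        assert a.table.equals(b.table)

    def test_snr_monotone_in_signal_amplitude(self, small_mask):
        # projection-rating correlation rises with signal_amplitude/noise_sd
        corrs = []
        for amp in (0.0, 0.3, 1.0, 3.0):
            spec = SyntheticSpec(
                n_participants=1, n_runs=8, signal_amplitude=amp,
                confound_amplitude=0.0, visual_amplitude=0.0, seed=11,
            )
            gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
            bs = simulate.simulate_trials(spec, gt, 0)
            proj = bs.data @ gt.anxiety_pattern.values
            corrs.append(np.corrcoef(proj, bs.table["rating"])[0, 1])
        assert corrs[0] < 0.25
        assert all(b > a - 0.05 for a, b in zip(corrs, corrs[1:]))
        assert corrs[-1] > corrs[0] + 0.3

    def test_null_mode_breaks_rating_map_link(self, small_mask):
        spec = simulate.null_spec(SyntheticSpec(n_participants=1, n_runs=8, seed=2))
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        bs = simulate.simulate_trials(spec, gt, 0)
        proj = bs.data @ gt.anxiety_pattern.values
        assert abs(np.corrcoef(proj, bs.table["rating"])[0, 1]) < 0.25


class TestAggregateByRating:
    def _series(self, small_mask, ratings, shocks):
        n = len(ratings)
        import pandas as pd

        table = pd.DataFrame(
            dict(
                participant=[0] * n,
                run=[0] * n,
                trial=range(n),
                condition=["low"] * n,
                rating=ratings,
                shock_followed=shocks,
            )
        )
        rng = np.random.default_rng(0)
        return simulate.BetaSeries(
            mask=small_mask, data=rng.normal(size=(n, small_mask.n_voxels)), table=table
        )

    def test_mean_of_matching_no_shock_trials(self, small_mask):
        bs = self._series(small_mask, [1, 1, 3], [False, False, False])
        maps = simulate.aggregate_by_rating(bs)
        assert [m.rating for m in maps] == [1, 3]
        np.testing.assert_allclose(maps[0].values, bs.data[:2].mean(axis=0))

    def test_shock_followed_trials_excluded(self, small_mask):
        bs = self._series(small_mask, [2, 2, 2, 4], [False, True, False, False])
        maps = simulate.aggregate_by_rating(bs)
        np.testing.assert_allclose(maps[0].values, bs.data[[0, 2]].mean(axis=0))
        assert maps[0].meta["n_trials"] == 2

    def test_unused_levels_absent(self, small_cohort):
        _, series, _, _ = small_cohort
        for bs in series:
            maps = simulate.aggregate_by_rating(bs)
            used = sorted(
                bs.table.loc[~bs.table.shock_followed.astype(bool), "rating"].unique()
            )
            assert [m.rating for m in maps] == used
            assert 3 <= len(maps) <= 5

    def test_all_shocked_warns_and_returns_empty(self, small_mask):
        bs = self._series(small_mask, [1, 2], [True, True])
        with pytest.warns(UserWarning, match="shock"):
            assert simulate.aggregate_by_rating(bs) == []


class TestSimulateBold:
    def _one_voxel_pattern(self, small_mask):
        values = np.zeros(small_mask.n_voxels)
        values[0] = 1.0
        from suitas.images import ActivationMap

        return ActivationMap(mask=small_mask, values=values, kind="contrast")

    def _table(self, onsets, durations, ratings):
        import pandas as pd

        return pd.DataFrame(
            dict(
                onset=onsets, duration=durations, rating=ratings,
                run=[0] * len(onsets), condition=["low"] * len(onsets),
                shock_followed=[False] * len(onsets),
            )
        )

    def test_noiseless_single_trial_matches_convolved_boxcar(self, small_mask):
        pat = self._one_voxel_pattern(small_mask)
        table = self._table([4.0], [8.0], [1])
        vol, _ = simulate.simulate_bold(table, pat, noise_sd=0.0, n_frames=30)
        frame_times = np.arange(30) * 2.0
        expected = glm.sampled_regressor([4.0], [8.0], frame_times, 2.0)
        series = vol.data.reshape(-1, 30, order="C")[small_mask.indices[0]]
        np.testing.assert_allclose(series, expected, atol=1e-12)

    def test_linearity_in_amplitude(self, small_mask):
        pat = self._one_voxel_pattern(small_mask)
        table = self._table([4.0, 20.0], [8.0, 6.0], [2, 1])
        v1, _ = simulate.simulate_bold(table, pat, noise_sd=0.0, n_frames=30)
        v2, _ = simulate.simulate_bold(table, pat, noise_sd=0.0, n_frames=30, signal_amplitude=2.0)
        np.testing.assert_allclose(v2.data, 2.0 * v1.data, atol=1e-12)

    def test_negative_duration_rejected(self, small_mask):
        pat = self._one_voxel_pattern(small_mask)
        with pytest.raises(ValueError, match="nonnegative"):
            simulate.simulate_bold(self._table([4.0], [-1.0], [1]), pat, n_frames=30)

    def test_ar1_lag_one_autocorrelation(self):
        # closed form: lag-1 autocorrelation of stationary AR(1) equals phi
        grid = simulate.default_grid(shape=(1, 1, 1))
        from suitas.images import ActivationMap, BrainMask

        mask = BrainMask(grid=grid, indices=np.array([0]))
        pat = ActivationMap(mask=mask, values=np.ones(1), kind="contrast")
        table = self._table([4.0], [8.0], [0])
        table["rating"] = 0  # pure noise series
        vol, _ = simulate.simulate_bold(
            table, pat, noise_sd=1.0, ar_phi=0.4, seed=9, n_frames=100_000
        )
        x = vol.data.ravel()
        rho = np.corrcoef(x[:-1], x[1:])[0, 1]
        assert abs(rho - 0.4) < 0.02


def test_smooth_noise_sd_calibrated(small_mask):
    noise = simulate.smooth_noise(np.random.default_rng(0), small_mask, 200, 3.0, 0.5)
    # interior voxels should have per-voxel sd close to the requested value
    assert abs(noise.std() - 0.5) < 0.05


def test_spec_validation():
    with pytest.raises(ValueError, match="nondecreasing"):
        SyntheticSpec(condition_rating_means=(3.0, 2.0, 3.5, 4.0))
    with pytest.raises(ValueError, match="noise_sd"):
        SyntheticSpec(noise_sd=0.0)
    with pytest.raises(ValueError):
        SyntheticSpec(shock_probability={"safety": 0.0, "low": 1.4, "medium": 0.6, "high": 0.6})
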