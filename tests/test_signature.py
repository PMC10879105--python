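"""SVR training against the QP oracle, grouped CV, evaluation metrics."""

import numpy as np
import pytest
from dataclasses import replace

from oracles import svr_kkt_oracle
from suitas import simulate
from suitas.signature import (
    CVScheme,
    DegenerateLabelsError,
    TrainConfig,
    apply_signature,
    cross_validate,
    evaluate,
    group_folds,
    r_to_z,
    stack_maps,
    train,
    train_within_individual,
    z_to_r,
)


class TestTrain:
    def test_realizable_function_with_zero_epsilon_is_interpolated(self):
        rng = np.random.default_rng(0)
        X = rng.normal(size=(20, 5))
        w_true = rng.normal(size=5) * 0.3
        y = X @ w_true + 1.0
        model = train(X, y, TrainConfig(epsilon=0.0, tol=1e-6))
        np.testing.assert_allclose(apply_signature(model, X), y, atol=1e-6)

    def test_permutation_of_map_order_leaves_model_unchanged(self):
        rng = np.random.default_rng(1)
        X = rng.normal(size=(15, 8))
        y = rng.integers(1, 6, size=15).astype(float)
        perm = rng.permutation(15)
        m1 = train(X, y, TrainConfig(tol=1e-10))
        m2 = train(X[perm], y[perm], TrainConfig(tol=1e-10))
        np.testing.assert_allclose(m1.weights, m2.weights, atol=1e-7)
        assert m1.intercept == pytest.approx(m2.intercept, abs=1e-7)

    def test_one_voxel_five_points_matches_qp_oracle(self):
        X = np.array([[1.0], [2.0], [3.0], [4.0], [5.0]])
        y = np.array([1.2, 2.1, 2.8, 4.4, 4.9])
        model = train(X, y, TrainConfig(cost_C=1.0, epsilon=0.1, tol=1e-12))
        w_o, b_o, b_unique = svr_kkt_oracle(X, y, C=1.0, epsilon=0.1)
        np.testing.assert_allclose(model.weights, w_o, atol=1e-6)
        if b_unique:
            assert model.intercept == pytest.approx(b_o, abs=1e-6)

    @pytest.mark.parametrize("seed", range(6))
    def test_small_problems_match_qp_oracle(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(3, 7))
        p = int(rng.integers(1, 3))
        X = rng.normal(size=(n, p))
        y = 2.0 * rng.normal(size=n) + 3.0
        model = train(X, y, TrainConfig(tol=1e-12))
        w_o, b_o, b_unique = svr_kkt_oracle(X, y)
        np.testing.assert_allclose(model.weights, w_o, atol=1e-6)
        if b_unique:
            assert model.intercept == pytest.approx(b_o, abs=1e-6)

    def test_scale_covariance(self):
        # scaling maps by k with C -> C/k^2 rescales weights by 1/k
        rng = np.random.default_rng(4)
        X = rng.normal(size=(12, 4))
        y = rng.integers(1, 6, size=12).astype(float)
        k = 3.0
        m1 = train(X, y, TrainConfig(cost_C=1.0, tol=1e-12))
        m2 = train(k * X, y, TrainConfig(cost_C=1.0 / k**2, tol=1e-12))
        np.testing.assert_allclose(m2.weights, m1.weights / k, atol=1e-6)

    def test_constant_ratings_rejected(self):
        with pytest.raises(DegenerateLabelsError):
            train(np.random.default_rng(0).normal(size=(5, 3)), np.full(5, 3.0))

    def test_zscore_scaling_folds_into_weights(self):
        rng = np.random.default_rng(2)
        X = rng.normal(size=(30, 6)) * np.array([1, 10, 0.1, 5, 2, 1])
        y = rng.integers(1, 6, size=30).astype(float)
        model = train(X, y, TrainConfig(feature_scaling="zscore"))
        # application is still a raw dot product on unscaled maps
        from sklearn.svm import SVR

        ref = SVR(kernel="linear", C=1.0, epsilon=0.1, tol=1e-6)
        mu, sd = X.mean(0), X.std(0)
        ref.fit((X - mu) / sd, y)
        np.testing.assert_allclose(
            apply_signature(model, X), ref.predict((X - mu) / sd), atol=1e-5
        )


class TestApply:
    def _model(self):
        w = np.array([0.5, -1.0, 2.0])
        from suitas.signature import SignatureModel

        return SignatureModel(weights=w, intercept=1.5)

    def test_zero_map_returns_intercept(self):
        assert apply_signature(self._model(), np.zeros((1, 3)))[0] == 1.5

    def test_affinity(self):
        model = self._model()
        rng = np.random.default_rng(0)
        a, b = rng.normal(size=3), rng.normal(size=3)
        ra = apply_signature(model, a[None])[0]
        rb = apply_signature(model, b[None])[0]
        rab = apply_signature(model, (a + b)[None])[0]
        assert rab == pytest.approx(ra + rb - model.intercept)

    def test_response_to_own_unit_weight_map(self):
        model = self._model()
        unit = model.weights / np.linalg.norm(model.weights)
        resp = apply_signature(model, unit[None])[0]
        assert resp == pytest.approx(np.linalg.norm(model.weights) + model.intercept)


class TestEvaluate:
    def test_perfect_prediction(self):
        res = evaluate(np.arange(1.0, 6.0), np.arange(1.0, 6.0))
        assert res.overall_r == pytest.approx(1.0)
        assert res.evs == pytest.approx(1.0)

    def test_constant_shift_hand_value(self):
        # actual 1..5, predicted 2..6: r = 1, EVS = 1 - 1/2 = 0.5
        res = evaluate(np.arange(2.0, 7.0), np.arange(1.0, 6.0))
        assert res.overall_r == pytest.approx(1.0)
        assert res.evs == pytest.approx(0.5)

    def test_constant_prediction_flagged(self):
        res = evaluate(np.full(5, 3.0), np.arange(1.0, 6.0))
        assert res.constant_prediction and np.isnan(res.overall_r)
        assert res.evs == pytest.approx(0.0)

    def test_zero_variance_actual_rejected(self):
        with pytest.raises(ValueError, match="zero variance"):
            evaluate(np.arange(1.0, 6.0), np.full(5, 2.0))

    def test_fisher_z_round_trip_and_unit_value(self):
        assert r_to_z(0.5) == pytest.approx(0.5493, abs=1e-4)
        assert z_to_r(r_to_z(0.87)) == pytest.approx(0.87)
        assert np.isfinite(r_to_z(1.0))

    def test_within_participant_averaging(self):
        actual = np.array([1, 3, 5, 1, 3, 5], dtype=float)
        predicted = np.array([1, 3, 5, 5, 3, 1], dtype=float)  # r=+1 and r=-1
        res = evaluate(predicted, actual, groups=np.array([0, 0, 0, 1, 1, 1]))
        assert res.within_r[0] == pytest.approx(1.0)
        assert res.within_r[1] == pytest.approx(-1.0)
        assert res.within_mean_r == pytest.approx(0.0, abs=1e-9)


class TestCrossValidate:
    def test_folds_partition_participants_without_leakage(self):
        groups = np.repeat(np.arange(12), 4)
        for folds in group_folds(groups, CVScheme(n_folds=4, n_repeats=3, seed=0)):
            seen = []
            for train_idx, test_idx in folds:
                assert not set(groups[train_idx]) & set(groups[test_idx])
                seen.extend(groups[test_idx].tolist())
            assert sorted(set(seen)) == list(range(12))

    def test_pure_noise_cv_r_centred_at_or_below_zero(self):
        rs = []
        for seed in range(8):
            rng = np.random.default_rng(seed)
            X = rng.normal(size=(40, 60))
            y = np.tile([1.0, 2.0, 4.0, 5.0], 10)
            groups = np.repeat(np.arange(10), 4)
            res = cross_validate(X, y, groups, CVScheme(n_folds=5, n_repeats=2, seed=seed))
            rs.append(res.overall_r)
        assert np.mean(rs) < 0.1

    def test_signal_makes_cv_r_rise_with_amplitude(self, small_mask):
        rs = []
        for amp in (0.0, 0.5, 1.0, 2.0):
            spec = simulate.SyntheticSpec(
                n_participants=8, n_runs=1, signal_amplitude=amp, seed=13,
                confound_amplitude=0.0, visual_amplitude=0.0,
            )
            gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
            series = [simulate.simulate_trials(spec, gt, p) for p in range(8)]
            maps = [m for bs in series for m in simulate.aggregate_by_rating(bs)]
            X, y, g = stack_maps(maps)
            res = cross_validate(X, y, g, CVScheme(n_folds=4, n_repeats=2, seed=1))
            rs.append(res.overall_r)
        assert rs[-1] > rs[0] + 0.3
        assert all(b > a - 0.1 for a, b in zip(rs, rs[1:]))

    def test_needs_enough_participants(self):
        X = np.zeros((6, 4))
        y = np.arange(6.0)
        with pytest.raises(ValueError, match="participants"):
            cross_validate(X, y, np.arange(6), CVScheme(n_folds=10))


class TestWithinIndividual:
    def test_noiseless_recovery_of_single_pattern(self, small_mask):
        spec = simulate.SyntheticSpec(
            n_participants=1, n_runs=2, noise_sd=1e-6,
            confound_amplitude=0.0, visual_amplitude=0.0, gain_sigma=0.0,
        )
        gt = simulate.make_ground_truth(spec, small_mask, n_blobs=1, blob_radius_mm=5.0)
        bs = simulate.simulate_trials(spec, gt, 0)
        results = train_within_individual([bs], CVScheme(n_folds=5, n_repeats=1))
        w = results[0].model.weights
        cosine = w @ gt.anxiety_pattern.values / np.linalg.norm(w)
        assert cosine >= 0.99

    def test_shuffled_ratings_give_null_cv_r(self, small_cohort):
        _, series, _, _ = small_cohort
        rs = []
        for seed in range(4):
            bs = series[seed]
            shuffled = bs.table.copy()
            shuffled["rating"] = np.random.default_rng(seed).permutation(
                shuffled["rating"].to_numpy()
            )
            bs2 = simulate.BetaSeries(mask=bs.mask, data=bs.data, table=shuffled)
            res = train_within_individual([bs2], CVScheme(n_folds=5, n_repeats=1, seed=seed))
            rs.append(res[0].cv_result.overall_r)
        assert np.mean(rs) < 0.15

    def test_ineligible_participants_skipped(self, small_mask):
        import pandas as pd

        rng = np.random.default_rng(0)
        ok = simulate.BetaSeries(
            mask=small_mask,
            data=rng.normal(size=(20, small_mask.n_voxels)),
            table=pd.DataFrame(
                dict(participant=[0] * 20, rating=rng.integers(1, 6, 20),
                     shock_followed=[False] * 20)
            ),
        )
        too_few = simulate.BetaSeries(
            mask=small_mask,
            data=rng.normal(size=(4, small_mask.n_voxels)),
            table=pd.DataFrame(
                dict(participant=[1] * 4, rating=[1, 2, 3, 4], shock_followed=[False] * 4)
            ),
        )
        results = train_within_individual([ok, too_few], CVScheme(n_folds=5, n_repeats=1))
        assert [r.participant for r in results] == [0]
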