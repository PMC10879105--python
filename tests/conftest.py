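import numpy as np
import pytest

from suitas import signature, simulate


@pytest.fixture(scope="session")
def small_mask():
    """~200-voxel ellipsoid mask for cheap unit tests."""
    return simulate.ellipsoid_mask(simulate.default_grid(shape=(10, 10, 8)))


@pytest.fixture(scope="session")
def small_cohort():
    """Ten-participant, two-run cohort at default SNR with its ground truth."""
    spec = simulate.SyntheticSpec(n_participants=10, n_runs=2, seed=7)
    mask = simulate.ellipsoid_mask(simulate.default_grid(shape=(14, 14, 12)))
    gt = simulate.make_ground_truth(spec, mask, blob_radius_mm=6.0)
    series = [simulate.simulate_trials(spec, gt, p) for p in range(spec.n_participants)]
    return spec, series, gt, mask


@pytest.fixture(scope="session")
def small_cohort_maps(small_cohort):
    """(X, ratings, participants) of the small cohort's per-rating maps."""
    _, series, _, _ = small_cohort
    maps = [m for bs in series for m in simulate.aggregate_by_rating(bs)]
    return signature.stack_maps(maps)
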