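import numpy as np
import pytest

from nichehybrid import (
    AnalysisConfig,
    NearestDistanceSample,
    SilvermanResult,
    classify_assembly,
    count_modes,
    critical_bandwidth,
    rule_of_thumb_bandwidth,
    silverman_test,
    smoothed_bootstrap,
)
from nichehybrid.errors import DegenerateSampleError, InsufficientDataError

import _oracles


def _mixture_sample(n=200, separation=8.0, seed=5):
    rng = np.random.default_rng(seed)
    component = rng.integers(0, 2, n)
    return rng.standard_normal(n) + separation * component


class TestCountModes:
    def test_two_separated_kernels(self):
        assert count_modes([0.0, 10.0], h=0.1).n_modes == 2

    def test_oversmoothed_to_one(self):
        assert count_modes([0.0, 10.0], h=100.0).n_modes == 1

    def test_degenerate_sample_one_mode(self):
        mc = count_modes([2.0, 2.0, 2.0], h=0.5)
        assert mc.n_modes == 1
        assert mc.locations.tolist() == [2.0]

    def test_nonpositive_bandwidth_rejected(self):
        with pytest.raises(ValueError):
            count_modes([0.0, 1.0, 2.0], h=0.0)

    def test_mixture_matches_direct_kde_oracle(self):
        x = _mixture_sample(n=200, separation=8.0, seed=5)
        assert count_modes(x, h=0.5).n_modes == 2
        assert _oracles.count_modes_direct(x, h=0.5) == 2

    def test_mode_locations_near_mixture_centers(self):
        x = _mixture_sample(n=400, separation=8.0, seed=6)
        mc = count_modes(x, h=0.5)
        locs = np.sort(mc.locations)
        assert abs(locs[0] - 0.0) < 0.5
        assert abs(locs[-1] - 8.0) < 0.5

    @pytest.mark.parametrize(
        "sample_seed, maker",
        [
            (0, lambda rng: rng.standard_normal(150)),
            (1, lambda rng: np.concatenate([rng.standard_normal(80),
                                            rng.standard_normal(80) + 6])),
            (2, lambda rng: rng.choice([0.0025, 0.005, 0.0075], 300)),
            (3, lambda rng: rng.uniform(0, 1, 200)),
        ],
    )
    def test_mode_count_non_increasing_in_bandwidth(self, sample_seed, maker):
        rng = np.random.default_rng(sample_seed)
        x = maker(rng)
        spread = x.max() - x.min()
        ladder = np.geomspace(1e-3 * spread, 3 * spread, 40)
        counts = [count_modes(x, h).n_modes for h in ladder]
        assert all(a >= b for a, b in zip(counts, counts[1:]))


class TestCriticalBandwidth:
    def test_defining_property_on_unimodal_sample(self):
        rng = np.random.default_rng(7)
        x = rng.standard_normal(200)
        h = critical_bandwidth(x, n_null=1)
        assert count_modes(x, h).n_modes == 1
        assert count_modes(x, 0.99 * h).n_modes >= 2

    def test_defining_property_on_mixture(self):
        x = _mixture_sample(n=300, separation=8.0, seed=8)
        h = critical_bandwidth(x, n_null=1)
        assert count_modes(x, h).n_modes == 1
        assert count_modes(x, 0.99 * h).n_modes >= 2
        # merging two bumps 8 sd apart takes a bandwidth of order the gap
        assert 1.0 < h < 8.0

    def test_already_satisfied_null_gives_vanishing_bandwidth(self):
        h = critical_bandwidth([0.0, 10.0], n_null=2)
        assert h < 1e-6

    def test_matches_dense_grid_scan_oracle(self):
        x = _mixture_sample(n=200, separation=8.0, seed=9)
        tol = 1e-3
        h = critical_bandwidth(x, n_null=1, tol=tol)
        ladder = np.geomspace(h / 4, h * 4, 10_000)
        scan = ladder[
            next(i for i, hh in enumerate(ladder) if count_modes(x, hh).n_modes <= 1)
        ]
        assert abs(scan - h) <= 2 * tol * h + (ladder[1] - ladder[0])

    def test_zero_spread_rejected(self):
        with pytest.raises(InsufficientDataError):
            critical_bandwidth([1.0, 1.0, 1.0])


class TestSmoothedBootstrap:
    def test_vanishing_bandwidth_is_ordinary_bootstrap(self):
        rng = np.random.default_rng(0)
        x = np.sort(rng.standard_normal(50))
        y = smoothed_bootstrap(x, h=1e-14, rng=np.random.default_rng(1))
        # every resampled point coincides with an original observation
        nearest = x[np.searchsorted(x, y).clip(1, x.size - 1)]
        prev = x[np.searchsorted(x, y).clip(1, x.size - 1) - 1]
        assert np.all(
            (np.abs(y - nearest) < 1e-9) | (np.abs(y - prev) < 1e-9)
        )

    def test_seeded_determinism(self):
        x = np.random.default_rng(2).standard_normal(80)
        y1 = smoothed_bootstrap(x, h=0.3, rng=np.random.default_rng(42))
        y2 = smoothed_bootstrap(x, h=0.3, rng=np.random.default_rng(42))
        assert np.array_equal(y1, y2)

    def test_variance_rescaling(self):
        rng = np.random.default_rng(3)
        x = rng.standard_normal(200)
        target = x.var(ddof=1)
        h = 0.8 * x.std(ddof=1)
        variances = [
            smoothed_bootstrap(x, h, rng).var(ddof=1) for _ in range(2000)
        ]
        assert np.mean(variances) == pytest.approx(target, rel=0.05)

    def test_zero_variance_rejected(self):
        with pytest.raises(DegenerateSampleError):
            smoothed_bootstrap([1.0, 1.0, 1.0], 0.1, np.random.default_rng(0))


class TestSilvermanTest:
    def test_seeded_bit_reproducibility(self):
        x = _mixture_sample(n=120, separation=6.0, seed=10)
        r1 = silverman_test(x, n_boot=99, seed=123)
        r2 = silverman_test(x, n_boot=99, seed=123)
        assert r1 == r2

    def test_p_value_lower_bound(self):
        x = _mixture_sample(n=200, separation=8.0, seed=11)
        res = silverman_test(x, n_boot=99, seed=0)
        assert res.p_value >= 1.0 / 100.0

    def test_clear_bimodality_rejected_unimodality(self):
        x = _mixture_sample(n=500, separation=8.0, seed=12)
        res = silverman_test(x, n_boot=199, seed=1)
        assert res.p_value < 0.05

    def test_gaussian_sample_not_rejected(self):
        x = np.random.default_rng(13).standard_normal(500)
        res = silverman_test(x, n_boot=199, seed=2)
        assert res.p_value > 0.05

    def test_kde_at_h_crit_satisfies_null(self):
        x = _mixture_sample(n=200, separation=8.0, seed=14)
        res = silverman_test(x, n_null=1, n_boot=49, seed=3)
        assert len(res.mode_locations) <= 1
        assert count_modes(x, res.h_crit).n_modes == 1

    def test_too_small_sample_flagged(self):
        with pytest.raises(InsufficientDataError):
            silverman_test([0.1, 0.2], n_boot=49, seed=0)

    def test_zero_spread_flagged(self):
        with pytest.raises(InsufficientDataError):
            silverman_test([0.5] * 10, n_boot=49, seed=0)


def _distance_sample(values, expected=0.60):
    values = np.asarray(values, dtype=float)
    return NearestDistanceSample(
        sample_id="s",
        rare_otu_ids=[f"r{i}" for i in range(values.size)],
        nearest_modal_ids=["m"] * values.size,
        values=values,
        L=400,
        M=80,
        expected_neutral_mean=expected,
        n_modal=5,
    )


def _result(p_value, mode_locations, mode_heights=None):
    if mode_heights is None:
        mode_heights = [1.0] * len(mode_locations)
    return SilvermanResult(
        n_null=1, h_crit=0.05, p_value=p_value, n_boot=999, seed=1,
        n_sample=200, mode_locations=mode_locations, mode_heights=mode_heights,
    )


class TestClassifyAssembly:
    config = AnalysisConfig(min_rare=50, seed=1)

    def test_rejection_with_neutral_end_member_mode_is_hybrid(self):
        rng = np.random.default_rng(20)
        values = np.concatenate(
            [rng.uniform(0.0, 0.02, 100), rng.normal(0.55, 0.02, 100)]
        )
        call = classify_assembly(
            _distance_sample(values), _result(0.01, [0.3]), self.config
        )
        assert call.classification == "HYBRID"

    def test_rejection_confined_to_niche_region_is_niche(self):
        # lattice satellites only: fine-scale multimodality, no neutral bulk
        rng = np.random.default_rng(21)
        values = rng.choice([1 / 400, 2 / 400, 3 / 400], 200)
        call = classify_assembly(
            _distance_sample(values), _result(0.01, [0.005]), self.config
        )
        assert call.classification == "NICHE"

    def test_unimodal_low_mode_is_niche(self):
        rng = np.random.default_rng(22)
        values = rng.uniform(0.0, 0.1, 200)
        call = classify_assembly(
            _distance_sample(values), _result(0.40, [0.05]), self.config
        )
        assert call.classification == "NICHE"
        assert call.primary_mode_location == 0.05

    def test_unimodal_high_mode_is_neutral(self):
        rng = np.random.default_rng(23)
        values = rng.normal(0.58, 0.02, 200)
        call = classify_assembly(
            _distance_sample(values), _result(0.40, [0.58]), self.config
        )
        assert call.classification == "NEUTRAL"

    def test_small_sample_withheld(self):
        values = np.random.default_rng(24).uniform(0.0, 0.1, 10)
        call = classify_assembly(_distance_sample(values), None, self.config)
        assert call.sufficient_data is False
        assert call.classification is None

    def test_primary_mode_is_highest_density_mode(self):
        rng = np.random.default_rng(25)
        values = np.concatenate(
            [rng.uniform(0.0, 0.02, 150), rng.normal(0.55, 0.02, 50)]
        )
        call = classify_assembly(
            _distance_sample(values),
            _result(0.40, [0.01, 0.55], mode_heights=[5.0, 1.0]),
            self.config,
        )
        assert call.primary_mode_location == 0.01


class TestRuleOfThumbBandwidth:
    def test_scales_with_spread_and_size(self):
        rng = np.random.default_rng(30)
        x = rng.standard_normal(500)
        h = rule_of_thumb_bandwidth(x)
        assert 0.1 < h < 1.0
        assert rule_of_thumb_bandwidth(x * 2) == pytest.approx(2 * h, rel=0.05)
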