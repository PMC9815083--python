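"""Division-time statistics, growth classification and Monod fitting."""

import math

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from picophys import (
    DivisionTrack, GeneratorConfig, GrowthPoint, MonodModel, MonodParams,
    classify_growth, doubling_times, fit_monod, geometric_mean_mu, ks_distribution,
    monod_mu, simulate_mother_machine_tracks,
)
from picophys.kinetics import growth_points_from_tracks, tracks_from_frame

LN2 = math.log(2.0)


def _track(times, glucose=1.0, lineage=0):
    return DivisionTrack(lineage, tuple(times),
                         tuple(range(len(times))), glucose)


class TestDoublingTimes:
    def test_first_interval_dropped(self):
        tds = doubling_times(_track([0, 60, 120, 180]), 5.0)
        assert tds == [(60.0, 1), (60.0, 1)]

    def test_consecutive_division_weighted_zero(self):
        tds = doubling_times(_track([0, 60, 65, 125]), 5.0)
        assert tds == [(5.0, 0), (60.0, 1)]

    def test_single_division_empty(self):
        assert doubling_times(_track([30.0]), 5.0) == []

    def test_decreasing_timestamps_rejected(self):
        with pytest.raises(ValueError, match="strictly increasing"):
            _track([0, 60, 50])


class TestClassifyGrowth:
    def test_single_lineage_50_events_is_valid(self):
        track = _track(np.arange(55) * 60.0)
        assert classify_growth([track]) == "valid"

    def test_pooled_lineages(self):
        tracks = [_track(np.arange(4) * 60.0, lineage=i) for i in range(3)]
        # 12 events, 3+3+3 = 9 generations >= 4, < 50 events
        assert classify_growth(tracks) == "pooled"

    def test_no_growth_below_four_generations(self):
        tracks = [_track([0.0, 60.0], lineage=0), _track([0.0, 70.0], lineage=1)]
        assert classify_growth(tracks) == "no_growth"

    def test_order_independent(self):
        tracks = [_track(np.arange(n) * 60.0, lineage=i)
                  for i, n in enumerate((10, 3, 7))]
        assert classify_growth(tracks) == classify_growth(tracks[::-1])


class TestGeometricMeanMu:
    def test_gm_of_2_and_8_hours(self):
        mu, _ = geometric_mean_mu([(120.0, 1), (480.0, 1)])
        assert mu == pytest.approx(LN2 / 4.0, rel=1e-9)
        assert mu == pytest.approx(0.173, abs=1e-3)

    def test_identical_times_zero_sd(self):
        tds = [(LN2 * 60.0, 1)] * 5
        mu, sd = geometric_mean_mu(tds)
        assert mu == pytest.approx(1.0)
        assert sd == 0.0

    def test_weight_zero_outlier_ignored(self):
        base = [(90.0, 1)] * 4
        with_outlier = base + [(5.0, 0)]
        assert geometric_mean_mu(with_outlier) == geometric_mean_mu(base)

    def test_all_weights_zero_raises(self):
        with pytest.raises(ValueError, match="no admissible events"):
            geometric_mean_mu([(5.0, 0), (5.0, 0)])

    @given(st.lists(st.floats(10.0, 600.0), min_size=2, max_size=30))
    @settings(max_examples=50, deadline=None)
    def test_geometric_not_above_arithmetic_mean(self, tds):
        mu_gm, _ = geometric_mean_mu([(td, 1) for td in tds])
        td_gm = LN2 / mu_gm * 60.0
        assert td_gm <= np.mean(tds) * (1 + 1e-12)


class TestMonodMu:
    def test_zero_at_zero(self):
        assert monod_mu(0.0, MonodParams(0.66, 4.86e-4)) == 0.0

    def test_half_saturation(self):
        p = MonodParams(0.66, 4.86e-4)
        assert monod_mu(4.86e-4, p) == pytest.approx(0.33)

    def test_near_saturation_value(self):
        p = MonodParams(0.66, 4.86e-4)
        assert monod_mu(1.0, p) == pytest.approx(0.6597, abs=2e-4)

    @given(st.floats(1e-7, 10.0), st.floats(1e-7, 10.0))
    @settings(max_examples=100, deadline=None)
    def test_monotone_and_bounded(self, s1, s2):
        p = MonodParams(0.66, 4.86e-4)
        lo, hi = sorted((s1, s2))
        assert monod_mu(lo, p) <= monod_mu(hi, p) < p.mu_max


class TestFitMonod:
    def test_noiseless_exact_recovery(self, noiseless_cfg):
        tracks = simulate_mother_machine_tracks(noiseless_cfg, quantize=False)
        res = MonodModel.from_dataframe(tracks, frame_interval_min=0.001).fit()
        for p in res.params:
            assert p.mu_max == pytest.approx(0.66, rel=1e-4)
            assert p.ks == pytest.approx(4.86e-4, rel=1e-3)
            assert p.fit_r2 == pytest.approx(1.0, abs=1e-6)

    def test_all_zero_rates_rejected(self):
        points = [GrowthPoint(10.0 ** -k, 0.0, 0.0, 10, "valid")
                  for k in range(4)]
        with pytest.raises(ValueError, match="no sigmoid"):
            fit_monod(points)

    def test_too_few_points_rejected(self):
        points = [GrowthPoint(1.0, 0.5, 0.05, 10, "valid")] * 3
        with pytest.raises(ValueError, match="at least 4"):
            MonodModel(points)

    def test_boundary_ordering(self):
        """Upper boundary (mu + sd) fits faster growth, hence smaller KS."""
        tracks = simulate_mother_machine_tracks(GeneratorConfig(seed=1))
        res = MonodModel.from_dataframe(tracks, 5.0).fit()
        assert res.upper_boundary.mu_max > res.mean.mu_max > res.lower_boundary.mu_max

    def test_bias_shrinks_with_events_per_level(self):
        """Estimation error of mu_max decreases as events per level grow."""
        errs = {}
        for n in (10, 50, 200):
            per_seed = []
            for seed in range(5):
                cfg = GeneratorConfig(events_per_level=n, seed=seed)
                res = MonodModel.from_dataframe(
                    simulate_mother_machine_tracks(cfg), 5.0).fit()
                per_seed.append(abs(res.mean.mu_max - 0.66) / 0.66)
            errs[n] = np.mean(per_seed)
        assert errs[200] < errs[50] < errs[10]

    def test_summary_contains_all_variants(self):
        tracks = simulate_mother_machine_tracks(GeneratorConfig(seed=1))
        text = MonodModel.from_dataframe(tracks, 5.0).fit().summary()
        for word in ("mean", "upper_boundary", "lower_boundary", "mu_max"):
            assert word in text


class TestGrowthPointsFromTracks:
    def test_levels_and_statuses(self):
        tracks = simulate_mother_machine_tracks(GeneratorConfig(seed=0))
        points = growth_points_from_tracks(tracks, 5.0)
        assert len(points) == 8
        assert all(p.status == "valid" for p in points)  # 60 events/level

    def test_growth_rate_increases_with_glucose(self):
        tracks = simulate_mother_machine_tracks(
            GeneratorConfig(seed=0, noise_cv=0.0, ks_cv=0.0,
                            consecutive_division_rate=0.0))
        mus = [p.mu_gm for p in growth_points_from_tracks(tracks, 5.0)]
        assert mus == sorted(mus)


class TestKsDistribution:
    def test_inversion_identity(self):
        """A cell at mu = mu_max/2 observed at S has ks = S."""
        s = 3.3e-4
        td_min = 2 * LN2 / 0.66 * 60.0  # exactly half-maximal growth
        track = _track([0.0, td_min, 2 * td_min], glucose=s)
        dist = ks_distribution([track], mu_max=0.66, frame_interval_min=1.0)
        assert dist.values == pytest.approx([s])

    def test_fast_cells_skipped(self):
        fast = _track([0.0, 10.0, 20.0], glucose=1.0)  # mu >> mu_max
        slow = _track([0.0, 100.0, 200.0], glucose=1.0)
        dist = ks_distribution([fast, slow], mu_max=0.66, frame_interval_min=1.0)
        assert dist.n_skipped == 1

    def test_ks_vanishes_as_mu_approaches_mu_max(self):
        td_min = LN2 / 0.6599 * 60.0
        track = _track([0.0, td_min, 2 * td_min], glucose=1.0)
        dist = ks_distribution([track], mu_max=0.66, frame_interval_min=1.0)
        assert dist.values[0] == pytest.approx(0.0, abs=1e-3)

    def test_recovers_generating_distribution(self):
        """Noiseless cells with truncated-normal KS give back its mean."""
        cfg = GeneratorConfig(noise_cv=0.0, consecutive_division_rate=0.0,
                              glucose_levels=(4.86e-4,),
                              events_per_level=400, seed=3)
        tracks = simulate_mother_machine_tracks(cfg, quantize=False)
        dist = ks_distribution(tracks_from_frame(tracks), 0.66,
                               frame_interval_min=0.0)
        # zero-truncation at cv 0.48 lifts the realised mean a few percent
        assert dist.mean == pytest.approx(4.86e-4, rel=0.10)
        assert dist.counts.sum() == len(dist.values)
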