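"""Synchrony measure and burst statistics against direct-definition oracles."""

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from conftest import brute_force_synchrony, brute_force_trace
from eisync.fixtures import FixtureSpec, make_burst_raster
from eisync.measures import (BurstSet, activity_trace, active_cells,
                             burst_detect, burst_frequency, burst_width,
                             default_threshold, measure_report,
                             synchrony_measure)
from eisync.raster import SpikeRaster


class TestSynchrony:
    def test_identical_trains_give_unity(self, periodic_raster):
        res = synchrony_measure(periodic_raster, "E", (0.0, 1000.0))
        assert res.s == pytest.approx(1.0, abs=1e-9)
        assert res.n_active_used == 10

    def test_single_active_cell_gives_unity(self):
        raster = SpikeRaster.from_lists(
            [[100.0, 300.0, 500.0], []], duration=1000.0)
        res = synchrony_measure(raster, "E", (0.0, 1000.0))
        assert res.s == pytest.approx(1.0)
        assert res.n_active_used == 1

    def test_no_active_cells_undefined(self):
        raster = SpikeRaster.from_lists([[], []], duration=500.0)
        res = synchrony_measure(raster, "E", (0.0, 500.0))
        assert not res.defined

    def test_jitter_ordering_and_oracle_agreement(self):
        """S falls with jitter; every value matches the direct definition."""
        window = (0.0, 1000.0)
        values = []
        for sigma_j in (0.0, 2.0, 5.0):
            rng = np.random.default_rng(5)
            spec = FixtureSpec(n_cells=15, duration=1000.0,
                               packet_times=tuple(range(100, 1000, 100)),
                               jitter=sigma_j)
            raster, _ = make_burst_raster(spec, rng)
            s = synchrony_measure(raster, "E", window).s
            oracle = brute_force_synchrony(raster.spikes, window)
            assert s == pytest.approx(oracle, rel=1e-9)
            values.append(s)
        assert values[0] > values[1] > values[2]

    def test_bounded_on_varied_rasters(self):
        rng = np.random.default_rng(8)
        for jitter in (0.0, 1.0, 3.0):
            spec = FixtureSpec(n_cells=20, duration=800.0,
                               packet_times=(200.0, 400.0, 600.0),
                               jitter=jitter, participation=0.8,
                               background_rate=5.0)
            raster, _ = make_burst_raster(spec, rng)
            s = synchrony_measure(raster, "E", (0.0, 800.0)).s
            assert 0.0 <= s <= 1.0 + 1e-6

    @settings(deadline=None, max_examples=10, derandomize=True)
    @given(st.integers(min_value=0, max_value=60))
    def test_time_shift_invariance(self, shift_steps):
        """Translating spikes by grid multiples leaves S unchanged."""
        shift = shift_steps * 0.1
        rng = np.random.default_rng(3)
        spec = FixtureSpec(n_cells=10, duration=1000.0,
                           packet_times=(300.0, 500.0, 700.0), jitter=1.5)
        raster, _ = make_burst_raster(spec, rng)
        shifted = SpikeRaster(spikes=[s + shift for s in raster.spikes],
                              is_exc=raster.is_exc, duration=1100.0)
        w = (0.0, 1000.0)
        ws = (shift, 1000.0 + shift)
        a = synchrony_measure(raster, "E", w).s
        b = synchrony_measure(shifted, "E", ws).s
        assert b == pytest.approx(a, rel=1e-9)


class TestBurstDetection:
    def test_empty_raster_no_bursts(self):
        raster = SpikeRaster.from_lists([[]], duration=100.0)
        bursts = burst_detect(raster, "E", (0.0, 100.0), threshold=40.0)
        assert bursts.n_bursts == 0
        assert burst_width(bursts) is None
        assert burst_frequency(bursts) is None

    def test_two_population_spikes_two_bursts(self):
        """800 coincident cells at 500 and 550 ms -> centers within 1 ms."""
        spikes = [np.array([500.0, 550.0]) for _ in range(800)]
        raster = SpikeRaster(spikes=spikes, is_exc=np.ones(800, bool),
                             duration=1000.0)
        bursts = burst_detect(raster, "E", (0.0, 1000.0), threshold=40.0)
        assert bursts.n_bursts == 2
        assert abs(bursts.centers[0] - 500.0) < 1.0
        assert abs(bursts.centers[1] - 550.0) < 1.0

    def test_subthreshold_coincidence_not_detected(self):
        """30 coincident spikes stay under the full-size threshold 40."""
        spikes = [np.array([500.0]) for _ in range(30)]
        raster = SpikeRaster(spikes=spikes, is_exc=np.ones(30, bool),
                             duration=1000.0)
        bursts = burst_detect(raster, "E", (0.0, 1000.0), threshold=40.0)
        assert bursts.n_bursts == 0

    def test_trace_matches_brute_force(self):
        rng = np.random.default_rng(17)
        spikes = np.sort(rng.uniform(10.0, 90.0, 80))
        grid = 0.0 + np.arange(1000) * 0.1
        fast = activity_trace(spikes, (0.0, 100.0))
        brute = brute_force_trace(spikes, grid)
        np.testing.assert_allclose(fast, brute, rtol=1e-9, atol=1e-12)

    def test_threshold_monotonicity(self):
        rng = np.random.default_rng(2)
        spec = FixtureSpec(n_cells=50, duration=1000.0,
                           packet_times=tuple(range(100, 1000, 150)),
                           jitter=2.0, background_rate=10.0)
        raster, _ = make_burst_raster(spec, rng)
        cover = [burst_detect(raster, "E", (0.0, 1000.0),
                              threshold=thr).total_duration
                 for thr in (5.0, 10.0, 20.0, 40.0)]
        assert all(a >= b for a, b in zip(cover, cover[1:]))

    def test_default_threshold_scales_with_population(self):
        assert default_threshold("E", 800) == 40.0
        assert default_threshold("E", 200) == 10.0
        assert default_threshold("I", 200) == 10.0
        assert default_threshold("I", 50) == 2.5


class TestBurstStatistics:
    def test_frequency_uniform_spacing(self):
        b = BurstSet(onsets=[98.0, 148.0, 198.0],
                     offsets=[102.0, 152.0, 202.0],
                     threshold=40.0, population="E")
        assert burst_frequency(b) == pytest.approx(20.0)

    def test_frequency_mean_of_uneven_gaps(self):
        # centers 100, 140, 200 -> gaps 40, 60 -> mean 50 ms -> 20 Hz
        b = BurstSet(onsets=[99.0, 139.0, 199.0],
                     offsets=[101.0, 141.0, 201.0],
                     threshold=40.0, population="E")
        assert burst_frequency(b) == pytest.approx(20.0)

    def test_single_burst_no_frequency(self):
        b = BurstSet(onsets=[10.0], offsets=[14.0], threshold=40.0,
                     population="E")
        assert burst_frequency(b) is None
        assert burst_width(b) == pytest.approx(4.0)

    def test_width_mean(self):
        b = BurstSet(onsets=[10.0, 50.0], offsets=[12.0, 56.0],
                     threshold=40.0, population="E")
        assert burst_width(b) == pytest.approx(4.0)

    def test_invalid_interval_ordering_rejected(self):
        with pytest.raises(ValueError):
            BurstSet(onsets=[10.0], offsets=[8.0], threshold=1.0,
                     population="E")
        with pytest.raises(ValueError):
            BurstSet(onsets=[10.0, 11.0], offsets=[12.0, 13.0],
                     threshold=1.0, population="E")


class TestActiveCellsAndReport:
    def test_active_cell_counting(self):
        raster = SpikeRaster.from_lists(
            [[100.0], [], [900.0]], [[500.0]], duration=1000.0)
        assert active_cells(raster, "E", (0.0, 1000.0)) == 2
        assert active_cells(raster, "I", (0.0, 1000.0)) == 1
        assert active_cells(raster, "E", (200.0, 800.0)) == 0

    def test_report_burst_fields_absent_iff_not_detected(self):
        rng = np.random.default_rng(4)
        bursty, _ = make_burst_raster(FixtureSpec(
            n_cells=100, duration=1000.0,
            packet_times=(200.0, 400.0, 600.0, 800.0)), rng)
        quiet, _ = make_burst_raster(FixtureSpec(
            n_cells=100, duration=1000.0, packet_times=(),
            background_rate=5.0), rng)
        for raster in (bursty, quiet):
            rep = measure_report(raster, (0.0, 1000.0),
                                 thresholds={"E": 40.0, "I": 10.0})
            assert (rep.burst_freq_exc is None) == (not rep.bursting_exc)
            assert (rep.burst_width_exc is None) == (not rep.bursting_exc)
        rep = measure_report(bursty, (0.0, 1000.0),
                             thresholds={"E": 40.0, "I": 10.0})
        assert rep.bursting_exc
        assert rep.burst_freq_exc == pytest.approx(5.0, abs=0.1)
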