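"""Measurement chain: histograms, bursts, regimes, phases, deletions."""

import numpy as np
import pytest
from hypothesis import given, settings, strategies as st

from cpgnet.analysis import (
    ActivityTrace,
    BurstSeries,
    classify_deletions,
    classify_regime,
    detect_bursts,
    frequency_amplitude_series,
    phase_duration_slopes,
    phase_relation,
    rate_histogram,
)
from cpgnet.engine import SpikeRecord
from cpgnet.neuron import InsufficientObservationError


def make_record(times_by_pop: dict, duration: float, sizes: dict) -> SpikeRecord:
    """Assemble a SpikeRecord from per-population spike-time arrays."""
    slices, ids, ts = {}, [], []
    start = 0
    for name, size in sizes.items():
        slices[name] = (start, start + size)
        for t in times_by_pop.get(name, ()):
            ids.append(start)  # all spikes on the population's first neuron
            ts.append(t)
        start += size
    order = np.argsort(ts) if ts else []
    return SpikeRecord(
        neuron_ids=np.asarray(ids, dtype=np.int32)[order] if ts else np.empty(0, np.int32),
        times=np.asarray(ts)[order] if ts else np.empty(0),
        n_neurons=start,
        duration=duration,
        pop_slices=slices,
    )


class TestRateHistogram:
    def test_no_spikes_gives_zero_trace(self):
        rec = make_record({}, 1000.0, {"l-RG-F": 10})
        tr = rate_histogram(rec, 100.0)["l-RG-F"]
        assert np.all(tr.rate == 0)

    def test_direct_arithmetic_example(self):
        """50 neurons each firing once inside one 100 ms bin ->
        10 spikes/(neuron*s) in that bin."""
        times = np.linspace(205.0, 295.0, 50)
        rec = SpikeRecord(
            neuron_ids=np.arange(50, dtype=np.int32),
            times=times,
            n_neurons=50,
            duration=1000.0,
            pop_slices={"l-RG-F": (0, 50)},
        )
        tr = rate_histogram(rec, 100.0)["l-RG-F"]
        assert tr.rate[2] == pytest.approx(10.0)
        assert tr.rate.sum() == pytest.approx(10.0)

    @given(st.lists(st.floats(0.0, 9_999.0), max_size=200))
    @settings(max_examples=30, deadline=None)
    def test_matches_naive_counting_and_conserves_spikes(self, times):
        times = np.sort(np.asarray(times))
        rec = SpikeRecord(
            neuron_ids=np.zeros(times.size, dtype=np.int32),
            times=times,
            n_neurons=7,
            duration=10_000.0,
            pop_slices={"p": (0, 7)},
        )
        tr = rate_histogram(rec, 100.0)["p"]
        # naive per-bin counting oracle
        for b in range(0, 10_000, 100):
            count = np.sum((times >= b) & (times < b + 100))
            assert tr.rate[b // 100] == pytest.approx(count / (7 * 0.1))
        # conservation: sum over bins * |P| * bin_s == total spikes
        assert tr.rate.sum() * 7 * 0.1 == pytest.approx(times.size)


def square_wave_trace(period_ms=2000.0, duty=0.5, duration=60_000.0,
                      amplitude=20.0, bin_ms=100.0) -> ActivityTrace:
    t = np.arange(0.0, duration, bin_ms)
    rate = amplitude * ((t % period_ms) < duty * period_ms)
    return ActivityTrace("p", bin_ms, t, rate.astype(float))


class TestDetectBursts:
    def test_square_wave_onsets_at_rising_edges(self):
        tr = square_wave_trace()
        b = detect_bursts(tr)
        periods = np.diff(b.onsets)
        assert abs(1000.0 / periods.mean() - 0.5) < 0.01
        assert np.all(np.abs(b.onsets % 2000.0) <= 100.0)

    def test_constant_trace_has_no_bursts(self):
        t = np.arange(0.0, 60_000.0, 100.0)
        tr = ActivityTrace("p", 100.0, t, np.full(t.size, 15.0))
        assert detect_bursts(tr).n == 0

    def test_flat_zero_trace_is_empty(self):
        t = np.arange(0.0, 30_000.0, 100.0)
        tr = ActivityTrace("p", 100.0, t, np.zeros(t.size))
        assert detect_bursts(tr).n == 0

    def test_recovers_noisy_synthetic_ground_truth(self):
        """>= 95% of known burst onsets recovered within one bin."""
        rng = np.random.default_rng(0)
        bin_ms, duration = 100.0, 120_000.0
        t = np.arange(0.0, duration, bin_ms)
        rate = rng.uniform(0.0, 1.5, t.size)  # low background noise
        true_onsets = np.arange(2_000.0, duration - 3_000.0, 1_700.0)
        for on in true_onsets:
            sel = (t >= on) & (t < on + 500.0)
            rate[sel] += 30.0 * (1.0 + 0.2 * rng.standard_normal(sel.sum()))
        b = detect_bursts(ActivityTrace("p", bin_ms, t, rate))
        hits = sum(np.min(np.abs(b.onsets - on)) <= bin_ms for on in true_onsets)
        assert hits / true_onsets.size >= 0.95

    def test_invalid_thresholds_rejected(self):
        with pytest.raises(ValueError):
            detect_bursts(square_wave_trace(), on_frac=0.1, off_frac=0.2)


class TestClassifyRegime:
    def test_all_zero_is_silence(self):
        t = np.arange(0.0, 20_000.0, 100.0)
        tr = ActivityTrace("p", 100.0, t, np.zeros(t.size))
        assert classify_regime(tr) == "silence"

    def test_square_wave_is_bursting(self):
        tr = square_wave_trace(duration=30_000.0)
        assert classify_regime(tr) == "bursting"

    def test_sustained_activity_is_tonic(self):
        t = np.arange(0.0, 20_000.0, 100.0)
        tr = ActivityTrace("p", 100.0, t, np.full(t.size, 25.0))
        assert classify_regime(tr) == "tonic"

    def test_short_window_rejected(self):
        t = np.arange(0.0, 5_000.0, 100.0)
        with pytest.raises(InsufficientObservationError):
            classify_regime(ActivityTrace("p", 100.0, t, np.zeros(t.size)))


def bursts_from_onsets(onsets, dur=300.0, peak=20.0) -> BurstSeries:
    onsets = np.asarray(onsets, dtype=float)
    return BurstSeries("p", onsets, onsets + dur, np.full(onsets.size, peak))


class TestFrequencyAmplitude:
    def test_periodic_bursts_give_constant_frequency(self):
        b = bursts_from_onsets(np.arange(0.0, 60_000.0, 2_000.0))
        df = frequency_amplitude_series(b, window_ms=10_000.0, duration=60_000.0)
        full = df.dropna()
        assert np.allclose(full["frequency_hz"], 0.5)

    def test_sparse_windows_marked_undefined(self):
        b = bursts_from_onsets([100.0, 25_000.0])
        df = frequency_amplitude_series(b, window_ms=10_000.0, duration=30_000.0)
        assert df["frequency_hz"].isna().all()


class TestPhaseRelation:
    def test_half_period_shift_is_alternation(self):
        ref = bursts_from_onsets(np.arange(0.0, 40_000.0, 1_000.0))
        other = bursts_from_onsets(np.arange(500.0, 40_000.0, 1_000.0))
        st_ = phase_relation(ref, other)
        assert st_.label == "alternation"
        assert st_.mean_phase == pytest.approx(0.5, abs=0.01)
        assert st_.R > 0.99

    def test_identical_series_is_synchrony(self):
        ref = bursts_from_onsets(np.arange(0.0, 40_000.0, 1_000.0))
        other = bursts_from_onsets(np.arange(1.0, 40_000.0, 1_000.0))
        st_ = phase_relation(ref, other)
        assert st_.label == "synchrony"

    def test_uniform_random_onsets_are_uncoordinated(self):
        rng = np.random.default_rng(7)
        ref = bursts_from_onsets(np.arange(0.0, 200_000.0, 1_000.0))
        raw = np.sort(rng.uniform(0.0, 200_000.0, 400))
        keep = np.concatenate([[True], np.diff(raw) > 400.0])
        other = bursts_from_onsets(raw[keep])
        st_ = phase_relation(ref, other)
        assert st_.label == "uncoordinated"
        assert st_.R < 0.3

    def test_invariant_to_common_shift_and_rescale(self):
        rng = np.random.default_rng(3)
        base = np.cumsum(rng.uniform(800.0, 1_200.0, 40))
        ref = bursts_from_onsets(base)
        other = bursts_from_onsets(base + 0.5 * np.diff(base, append=base[-1] + 1000.0))
        st1 = phase_relation(ref, other)
        for shift, scale in ((5_000.0, 1.0), (0.0, 3.0), (7_500.0, 0.5)):
            ref2 = bursts_from_onsets(base * scale + shift)
            other2 = bursts_from_onsets(other.onsets * scale + shift)
            st2 = phase_relation(ref2, other2)
            assert st2.label == st1.label
            assert st2.mean_phase == pytest.approx(st1.mean_phase, abs=1e-9)

    def test_insufficient_cycles_rejected(self):
        ref = bursts_from_onsets([0.0, 1_000.0, 2_000.0])
        with pytest.raises(InsufficientObservationError):
            phase_relation(ref, ref)


class TestClassifyDeletions:
    def _antagonist(self, duration=60_000.0, level=25.0):
        t = np.arange(0.0, duration, 100.0)
        return ActivityTrace("E", 100.0, t, np.full(t.size, level))

    def test_unperturbed_periodic_series_has_no_deletions(self):
        target = bursts_from_onsets(np.arange(1_000.0, 50_000.0, 1_000.0))
        rep = classify_deletions(
            target, self._antagonist(), target, (30_000.0, 31_500.0)
        )
        assert rep.n_deletions == 0
        assert not rep.resetting

    def test_missing_burst_is_detected_and_antagonist_sustained(self):
        onsets = [t for t in np.arange(1_000.0, 50_000.0, 1_000.0)
                  if not 30_000.0 <= t < 32_000.0]
        target = bursts_from_onsets(onsets)
        rep = classify_deletions(
            target, self._antagonist(), target, (29_800.0, 32_200.0)
        )
        assert rep.n_deletions == 2
        assert all(e["antagonist"] == "sustained" for e in rep.events)
        assert not rep.resetting  # grid resumes unshifted

    def test_phase_shifted_resumption_is_resetting(self):
        pre = np.arange(1_000.0, 30_000.0, 1_000.0)
        post = np.arange(32_400.0, 50_000.0, 1_000.0)  # 0.4-cycle shift
        target = bursts_from_onsets(np.concatenate([pre, post]))
        rep = classify_deletions(
            target, self._antagonist(), target, (29_800.0, 32_200.0)
        )
        assert rep.resetting

    def test_unstable_pre_rhythm_refused(self):
        rng = np.random.default_rng(0)
        onsets = np.cumsum(rng.uniform(300.0, 2_500.0, 40))
        target = bursts_from_onsets(onsets)
        with pytest.raises(InsufficientObservationError):
            classify_deletions(
                target, self._antagonist(), target,
                (onsets[20], onsets[20] + 1_000.0), max_period_cv=0.2,
            )


class TestPhaseDurationSlopes:
    def test_constant_flexor_duration_gives_slopes_zero_and_one(self):
        rng = np.random.default_rng(1)
        periods = rng.uniform(800.0, 2_400.0, 40)
        onsets = np.concatenate([[0.0], np.cumsum(periods)])
        b = BurstSeries("F", onsets, onsets + 350.0, np.full(onsets.size, 20.0))
        fit = phase_duration_slopes(b)
        assert fit.flexor_slope == pytest.approx(0.0, abs=1e-9)
        assert fit.extensor_slope == pytest.approx(1.0, abs=1e-9)

    def test_matches_normal_equations_oracle(self):
        rng = np.random.default_rng(2)
        periods = rng.uniform(700.0, 2_500.0, 60)
        onsets = np.concatenate([[0.0], np.cumsum(periods)])
        durs = 200.0 + 0.15 * np.concatenate([periods, [1_000.0]]) \
            + rng.normal(0.0, 20.0, onsets.size)
        b = BurstSeries("F", onsets, onsets + durs, np.full(onsets.size, 20.0))
        fit = phase_duration_slopes(b)
        T = np.diff(onsets)
        y = durs[:-1]
        # closed-form least squares via the normal equations
        xm, ym = T.mean(), y.mean()
        slope = ((T - xm) * (y - ym)).sum() / ((T - xm) ** 2).sum()
        assert fit.flexor_slope == pytest.approx(slope, abs=1e-9)
        assert fit.extensor_slope == pytest.approx(1.0 - slope, abs=1e-9)

    def test_insufficient_period_range_rejected(self):
        onsets = np.arange(0.0, 30_000.0, 1_000.0)
        b = BurstSeries("F", onsets, onsets + 300.0, np.full(onsets.size, 20.0))
        with pytest.raises(InsufficientObservationError):
            phase_duration_slopes(b)
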