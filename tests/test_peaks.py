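"""Cycle peaks, first contact, central moving average, fit-point selection."""

import numpy as np
import pytest

import gawvot as gv
from gawvot.errors import InputError, InsufficientDataError
from gawvot.peaks import Peak


def make_peaks(amps, closed=None, dt_ms=5.0):
    closed = [True] * len(amps) if closed is None else closed
    return [Peak(i, i * dt_ms, float(a), bool(c))
            for i, (a, c) in enumerate(zip(amps, closed))]


class TestDetectCyclePeaks:
    def test_rectified_sine_one_peak_per_cycle(self):
        fps, f0, n_cycles = 8000.0, 200.0, 10
        t = np.arange(int(n_cycles * fps / f0)) / fps
        gaw = gv.GAWSignal(np.abs(np.sin(np.pi * f0 * t)), fps, f0=f0)
        peaks = gv.detect_cycle_peaks(gaw)
        assert len(peaks) == n_cycles
        # antinodes of |sin| sit at odd multiples of the quarter period
        expected = (np.arange(n_cycles) + 0.5) / f0 * 1000.0
        got = np.array([p.time_ms for p in peaks])
        assert np.max(np.abs(got - expected)) < 1000.0 / fps

    def test_generator_peak_count_matches_ground_truth(self):
        spec = gv.SyntheticSpec(seed=11, noise_sd=0.0)
        gaw, truth = gv.generate_gaw(spec)
        peaks = gv.detect_cycle_peaks(gaw.replace(f0=spec.f0))
        assert len(peaks) == truth.n_cycles

    def test_growing_envelope_peaks_nondecreasing(self):
        gaw, truth = gv.generate_gaw(gv.SyntheticSpec(seed=1, noise_sd=0.0))
        peaks = gv.detect_cycle_peaks(gaw.replace(f0=truth.f0))
        amps = np.array([p.amplitude for p in peaks])
        sat = int(0.6 * len(amps))  # strictly growing part of the onset
        assert np.all(np.diff(amps[:sat]) > -1e-9)

    def test_tie_break_earliest_sample(self):
        fps, f0 = 8000.0, 200.0
        x = np.zeros(200)
        for c in range(4):
            x[c * 40 + 18:c * 40 + 22] = 1.0  # flat-top cycles
        peaks = gv.detect_cycle_peaks(gv.GAWSignal(x, fps, f0=f0))
        assert all(p.index % 40 == 18 for p in peaks)

    def test_filtered_cycles_from_zero_crossings(self):
        fps, f0 = 8000.0, 200.0
        t = np.arange(4000) / fps
        x = np.sin(2 * np.pi * f0 * t)
        gaw = gv.GAWSignal(x, fps, filtered=True, f0=f0)
        peaks = gv.detect_cycle_peaks(gaw)
        assert len(peaks) >= 90
        assert np.allclose([p.amplitude for p in peaks], 1.0, atol=1e-3)


class TestFirstContact:
    def test_constructed_zero_sample(self):
        fps = 8000.0
        x = np.abs(np.sin(np.pi * 200.0 * np.arange(400) / fps)) + 0.01
        x[200] = 0.0  # closure at 25 ms, reopening after
        t = gv.detect_first_contact(gv.GAWSignal(x, fps))
        assert t == pytest.approx(25.0, abs=1e-9)

    def test_strictly_positive_signal_returns_none(self):
        x = 0.1 + np.abs(np.sin(np.linspace(0, 30, 1000)))
        assert gv.detect_first_contact(gv.GAWSignal(x, 8000.0)) is None

    def test_noise_floor_below_epsilon(self):
        gaw, truth = gv.generate_gaw(gv.SyntheticSpec(seed=2))
        norm = gv.normalize_gaw(gaw)
        t = gv.detect_first_contact(norm, closure_epsilon=0.005)
        assert t == pytest.approx(truth.first_contact_ms, abs=1000.0 / gaw.fps)

    def test_trailing_closure_without_reopening_ignored(self):
        x = np.concatenate([0.1 + np.abs(np.sin(np.linspace(0, 30, 500))), np.zeros(50)])
        assert gv.detect_first_contact(gv.GAWSignal(x, 8000.0)) is None

    def test_filtered_signal_rejected(self):
        sig = gv.GAWSignal(np.sin(np.linspace(0, 30, 500)), 8000.0, filtered=True)
        with pytest.raises(InputError):
            gv.detect_first_contact(sig)


class TestCentralMovingAverage:
    def test_constant_peaks(self):
        cma = gv.central_moving_average(make_peaks([0.7] * 9), kernel=5)
        assert np.allclose(cma.values, 0.7)

    def test_hand_computed_values(self):
        cma = gv.central_moving_average(
            make_peaks([0.2, 0.4, 0.6, 0.8, 1.0, 1.0, 1.0]), kernel=5)
        assert np.allclose(cma.values, [0.60, 0.76, 0.88])

    def test_ineligible_peaks_excluded_and_cma_starts_at_fifth_peak(self):
        # 2 peaks without preceding closure + 7 with: the first cma value is
        # centered on the 5th overall peak (3rd eligible)
        closed = [False, False] + [True] * 7
        amps = list(np.linspace(0.2, 1.0, 9))
        peaks = make_peaks(amps, closed)
        cma = gv.central_moving_average(peaks, kernel=5)
        assert len(cma.eligible_peaks) == 7
        assert cma.center_peaks[0] is peaks[4]
        assert cma.values[0] == pytest.approx(np.mean(amps[2:7]))

    def test_too_few_eligible_rejected(self):
        with pytest.raises(InsufficientDataError):
            gv.central_moving_average(make_peaks([1.0] * 6, [False, False] + [True] * 4))

    def test_bounded_by_window(self):
        rng = np.random.default_rng(8)
        amps = rng.uniform(0.1, 1.0, 20)
        cma = gv.central_moving_average(make_peaks(amps), kernel=5)
        for j, v in enumerate(cma.values):
            w = amps[j:j + 5]
            assert w.min() - 1e-12 <= v <= w.max() + 1e-12


class TestSaturationAmplitude:
    def test_argmax_and_last_fit_peak(self):
        peaks = make_peaks([0.2, 0.4, 0.6, 0.8, 1.0, 1.0, 1.0])
        cma = gv.central_moving_average(peaks, kernel=5)
        sat = gv.saturation_amplitude(cma, total_duration_ms=100.0)
        assert sat.r_sat == pytest.approx(0.88)
        assert sat.last_fit_peak is peaks[6]

    def test_monotone_decreasing_cma_takes_first_value(self):
        peaks = make_peaks(list(np.linspace(1.0, 0.2, 9)))
        cma = gv.central_moving_average(peaks, kernel=5)
        sat = gv.saturation_amplitude(cma, total_duration_ms=200.0)
        assert sat.r_sat == pytest.approx(cma.values[0])

    def test_long_plateau_recovers_true_saturation(self):
        gaw, truth = gv.generate_gaw(gv.SyntheticSpec(seed=4, noise_sd=0.0))
        rep = gv.analyze_gaw(gaw)
        assert 0.98 <= rep.r_sat["GAW_o"] <= 1.0 + 1e-9

    def test_window_restriction(self):
        peaks = make_peaks([0.2, 0.4, 0.6, 0.8, 1.0, 1.0, 1.0], dt_ms=10.0)
        cma = gv.central_moving_average(peaks, kernel=5)
        with pytest.raises(InsufficientDataError):
            gv.saturation_amplitude(cma, total_duration_ms=200.0, syllable_fraction=0.05)


class TestSelectFitPeaks:
    def setup_method(self):
        self.peaks = make_peaks(np.linspace(0.1, 1.0, 12),
                                [False, False] + [True] * 10, dt_ms=5.0)

    def test_unfiltered_after_contact_up_to_last(self):
        sel = gv.select_fit_peaks(self.peaks, "unfiltered",
                                  first_contact_ms=9.0, last_fit_peak=self.peaks[8])
        assert sel == self.peaks[2:9]

    def test_filtered_includes_pre_contact_peaks(self):
        sel = gv.select_fit_peaks(self.peaks, "filtered",
                                  first_contact_ms=9.0, last_fit_peak=self.peaks[8])
        assert sel == self.peaks[:9]

    def test_filtered_selection_is_superset(self):
        unf = gv.select_fit_peaks(self.peaks, "unfiltered", 9.0, self.peaks[8])
        fil = gv.select_fit_peaks(self.peaks, "filtered", 9.0, self.peaks[8])
        assert set(p.index for p in unf) <= set(p.index for p in fil)

    def test_no_contact_unfiltered_rejected(self):
        with pytest.raises(InsufficientDataError):
            gv.select_fit_peaks(self.peaks, "unfiltered", None, self.peaks[8])

    def test_fewer_than_three_rejected(self):
        with pytest.raises(InsufficientDataError):
            gv.select_fit_peaks(self.peaks, "unfiltered", 50.0, self.peaks[11])
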