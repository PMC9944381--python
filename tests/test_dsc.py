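"""DSC analysis: baseline, deconvolution recovery, onset, domain rules,
fraction-unfolded curve."""

import numpy as np
import pytest
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.signal import savgol_filter

from mabdev.conditions import FormulationCondition
from mabdev.dsc import (Thermogram, UnfoldingTransition, assign_domains,
                        choose_n_transitions, compute_tonset,
                        deconvolve_transitions, fraction_unfolded_curve,
                        subtract_baseline)
from mabdev.errors import NoSignalError
from mabdev.synth import (AggregationTruth, SampleTruth, TransitionTruth,
                          simulate_thermogram)


def make_truth(transitions, cond=None):
    return SampleTruth(condition=cond or FormulationCondition("mAb-X", 6.0, 0.0),
                       transitions=tuple(transitions), aggregation=AggregationTruth())


SINGLE = (TransitionTruth(70.0, 400.0, 100.0, "Fab"),)
TRIPLE = (TransitionTruth(70.0, 500.0, 80.0, "CH2"),
          TransitionTruth(82.0, 450.0, 300.0, "Fab"),
          TransitionTruth(89.0, 500.0, 60.0, "CH3"))


class TestBaseline:
    def test_constant_offset_removed(self, cond):
        t = np.linspace(20, 110, 901)
        tg = subtract_baseline(Thermogram(cond, t, np.full_like(t, 3.0)))
        assert np.allclose(tg.cp_excess, 0.0, atol=1e-9)

    def test_affine_drift_removed(self, cond):
        t = np.linspace(20, 110, 901)
        tg = subtract_baseline(Thermogram(cond, t, 1.5 + 0.02 * t))
        assert np.max(np.abs(tg.cp_excess)) < 1e-9

    def test_area_recovered_under_drift(self):
        raw = simulate_thermogram(make_truth(SINGLE), noise_sd=0.0)
        drifted = Thermogram(raw.condition, raw.temperature,
                             raw.cp_excess + 2.0 - 0.01 * raw.temperature)
        corrected = subtract_baseline(drifted)
        area = trapezoid(corrected.cp_excess, corrected.temperature)
        assert area == pytest.approx(100.0, rel=0.02)

    def test_signal_in_window_flags_warning(self, cond):
        t = np.linspace(20, 110, 901)
        y = np.exp(-0.5 * ((t - 25.0) / 2.0) ** 2)  # peak inside the low window
        with pytest.warns(UserWarning, match="baseline window"):
            tg = subtract_baseline(Thermogram(cond, t, y))
        assert tg.meta["warnings"]


class TestDeconvolution:
    def test_three_transition_recovery(self):
        raw = simulate_thermogram(make_truth(TRIPLE), noise_sd=1.0, seed=0)
        fit, _ = deconvolve_transitions(subtract_baseline(raw), 3)
        for tr, truth in zip(fit, TRIPLE):
            assert tr.tm == pytest.approx(truth.tm_true, abs=0.3)
        assert [tr.tm for tr in fit] == sorted(tr.tm for tr in fit)

    def test_single_noiseless_exactly_recovered(self):
        raw = simulate_thermogram(make_truth(SINGLE), noise_sd=0.0)
        fit, rms = deconvolve_transitions(raw, 1)
        assert fit[0].tm == pytest.approx(70.0, abs=0.1)
        assert fit[0].area == pytest.approx(100.0, rel=0.01)

    def test_overfit_yields_degenerate_component(self):
        raw = simulate_thermogram(make_truth(SINGLE), noise_sd=0.0)
        fit, _ = deconvolve_transitions(raw, 2)
        areas = sorted(tr.area for tr in fit)
        assert areas[0] < 0.05 * areas[1]

    def test_model_selection_counts_peaks(self):
        three = simulate_thermogram(make_truth(TRIPLE), noise_sd=1.0, seed=1)
        fit3, _ = choose_n_transitions(subtract_baseline(three))
        assert len(fit3) == 3
        one = simulate_thermogram(make_truth(SINGLE), noise_sd=1.0, seed=1)
        fit1, _ = choose_n_transitions(subtract_baseline(one))
        assert len(fit1) == 1

    def test_fitted_area_sum_matches_total_integral(self):
        raw = simulate_thermogram(make_truth(TRIPLE), noise_sd=1.0, seed=2)
        tg = subtract_baseline(raw)
        fit, _ = deconvolve_transitions(tg, 3)
        total = trapezoid(tg.cp_excess, tg.temperature)
        assert sum(tr.area for tr in fit) == pytest.approx(total, rel=0.05)


class TestOnset:
    def test_onset_precedes_midpoint(self):
        raw = simulate_thermogram(make_truth(SINGLE), noise_sd=0.0)
        fit, _ = deconvolve_transitions(raw, 1)
        tonset = compute_tonset(raw, fit)
        assert 60.0 < tonset < 70.0

    def test_threshold_monotonicity(self):
        raw = simulate_thermogram(make_truth(SINGLE), noise_sd=1.0, seed=3)
        tg = subtract_baseline(raw)
        fit, _ = deconvolve_transitions(tg, 1)
        assert compute_tonset(tg, fit, 0.01) <= compute_tonset(tg, fit, 0.05)

    def test_matches_direct_scan_oracle(self):
        raw = simulate_thermogram(make_truth(TRIPLE), noise_sd=1.0, seed=4)
        tg = subtract_baseline(raw)
        fit, _ = deconvolve_transitions(tg, 3)
        got = compute_tonset(tg, fit, 0.05)
        # independent scan: smoothed signal above 5% of max for 10 points
        smooth = savgol_filter(tg.cp_excess, 21, 3)
        above = smooth > 0.05 * smooth.max()
        runs = [i for i in range(len(above) - 9) if all(above[i:i + 10])]
        assert got == pytest.approx(tg.temperature[runs[0]], abs=1e-9)

    def test_no_signal_raises(self, cond):
        t = np.linspace(20, 110, 901)
        rng = np.random.default_rng(0)
        tg = Thermogram(cond, t, rng.normal(0, 1e-3, t.size))
        fit = [UnfoldingTransition(70.0, 100.0, 2.0)]
        with pytest.raises(NoSignalError):
            compute_tonset(tg, fit, threshold_frac=5.0)


class TestDomainAssignment:
    @pytest.mark.parametrize("peaks, expected", [
        ([(70, 100), (82, 300), (89, 80)], {82: "Fab", 70: "CH2", 89: "CH3"}),
        ([(70, 50), (84, 400)], {84: "Fab", 70: "CH2"}),
        ([(68, 500), (80, 100), (90, 100)], {68: "Fab", 80: "CH2", 90: "CH3"}),
    ])
    def test_largest_area_fab_then_lowest_ch2(self, peaks, expected):
        trs = [UnfoldingTransition(tm, area, 2.0) for tm, area in peaks]
        labelled = assign_domains(trs)
        assert {tr.tm: tr.domain for tr in labelled} == expected
        assert [tr.tm for tr in labelled] == [tm for tm, _ in peaks]  # order kept

    def test_area_tie_breaks_to_lower_midpoint(self):
        trs = [UnfoldingTransition(70.0, 300.0, 2.0),
               UnfoldingTransition(82.0, 300.0, 2.0)]
        with pytest.warns(UserWarning, match="tie"):
            labelled = assign_domains(trs)
        assert labelled[0].domain == "Fab" and labelled[1].domain == "CH2"

    def test_exactly_one_fab_and_ch2(self):
        rng = np.random.default_rng(42)
        for _ in range(25):
            n = rng.integers(1, 4)
            trs = [UnfoldingTransition(float(60 + 30 * rng.random()),
                                       float(rng.uniform(10, 500)), 2.0)
                   for _ in range(n)]
            domains = [tr.domain for tr in assign_domains(trs)]
            assert domains.count("Fab") == 1
            assert domains.count("CH2") == (1 if n >= 2 else 0)
            assert domains.count("CH3") == (1 if n == 3 else 0)


class TestFractionUnfolded:
    def test_half_at_midpoint_single_transition(self):
        tg = simulate_thermogram(make_truth(SINGLE), noise_sd=0.0)
        curve = fraction_unfolded_curve(tg)
        assert curve(70.0) == pytest.approx(0.5, abs=0.01)

    def test_half_between_two_equal_transitions(self):
        trs = (TransitionTruth(70.0, 300.0, 100.0, "CH2"),
               TransitionTruth(85.0, 300.0, 100.0, "Fab"))
        tg = simulate_thermogram(make_truth(trs), noise_sd=0.0)
        assert fraction_unfolded_curve(tg)(77.5) == pytest.approx(0.5, abs=0.02)

    def test_monotone_and_normalised(self):
        tg = simulate_thermogram(make_truth(TRIPLE), noise_sd=2.0, seed=5)
        curve = fraction_unfolded_curve(subtract_baseline(tg))
        assert np.all(np.diff(curve.fraction) >= -1e-12)
        assert curve.fraction[0] == pytest.approx(0.0, abs=1e-6)
        assert curve.fraction[-1] == pytest.approx(1.0, abs=1e-6)

    def test_equals_cumulative_trapezoid_oracle(self):
        tg = simulate_thermogram(make_truth(TRIPLE), noise_sd=0.0)
        curve = fraction_unfolded_curve(tg)
        oracle = cumulative_trapezoid(tg.cp_excess, tg.temperature, initial=0.0)
        oracle /= trapezoid(tg.cp_excess, tg.temperature)
        assert np.max(np.abs(curve.fraction - np.clip(oracle, 0, 1))) < 1e-9

    def test_no_signal_raises(self, cond):
        t = np.linspace(20, 110, 901)
        with pytest.raises(NoSignalError):
            fraction_unfolded_curve(Thermogram(cond, t, np.full_like(t, -1e-3)))
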