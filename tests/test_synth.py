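"""Generator contracts: two-state thermodynamics, onset coupling,
dilution series, chromatograms and panel reproducibility."""

import numpy as np
import pytest
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from mabdev.conditions import FormulationCondition
from mabdev.errors import InvalidInputError, ScanDomainError
from mabdev.synth import (AggregationTruth, PanelDesign, SampleTruth, SECPeakParams,
                          TransitionTruth, make_panel, onset_temperature_for_fraction,
                          simulate_aggregation_trace, simulate_chromatogram,
                          simulate_dilution_series, simulate_thermogram)
from mabdev.thermo import unfolded_fraction


def truth_of(transitions, cond=None, agg=None, **kw):
    cond = cond or FormulationCondition("mAb-X", 6.0, 0.0)
    agg = agg or AggregationTruth()
    return SampleTruth(condition=cond, transitions=tuple(transitions),
                       aggregation=agg, **kw)


SINGLE = (TransitionTruth(70.0, 100.0, 100.0, "Fab"),)


class TestThermogram:
    def test_peak_maximum_at_midpoint(self):
        tg = simulate_thermogram(truth_of(SINGLE), noise_sd=0.0)
        assert abs(tg.temperature[np.argmax(tg.cp_excess)] - 70.0) <= 0.1

    def test_total_integral_equals_calorimetric_enthalpy(self):
        # trapezoid oracle on a 0.01 °C grid
        grid = np.arange(20.0, 110.0, 0.01)
        tg = simulate_thermogram(truth_of(SINGLE), grid=grid, noise_sd=0.0)
        assert trapezoid(tg.cp_excess, tg.temperature) == pytest.approx(100.0, rel=0.01)

    def test_two_transitions_give_two_maxima(self):
        trs = (TransitionTruth(70.0, 300.0, 100.0, "CH2"),
               TransitionTruth(82.0, 300.0, 100.0, "Fab"))
        tg = simulate_thermogram(truth_of(trs), noise_sd=0.0)
        peaks, _ = find_peaks(tg.cp_excess, height=0.05 * tg.cp_excess.max())
        assert len(peaks) == 2

    def test_single_transition_population_is_half_at_midpoint(self):
        assert unfolded_fraction(np.array([70.0]), 70.0, 300.0)[0] == pytest.approx(0.5, abs=1e-3)

    def test_invalid_grid_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_thermogram(truth_of(SINGLE), grid=np.array([20.0, 19.0] * 10))

    def test_midpoint_outside_grid_rejected(self):
        with pytest.raises(ScanDomainError):
            simulate_thermogram(truth_of(SINGLE), grid=np.linspace(80.0, 110.0, 100))

    def test_fixed_seed_is_bit_identical(self):
        a = simulate_thermogram(truth_of(SINGLE), noise_sd=2.0, seed=5)
        b = simulate_thermogram(truth_of(SINGLE), noise_sd=2.0, seed=5)
        assert np.array_equal(a.cp_excess, b.cp_excess)


class TestAggregationTrace:
    def test_tiny_reactivity_onsets_at_first_unfolding(self):
        truth = truth_of(SINGLE, agg=AggregationTruth("Fab", 1e-6))
        tr = simulate_aggregation_trace(truth, noise_cv=0.0)
        f = unfolded_fraction(tr.temperature, 70.0, 100.0)
        first_nonzero = tr.temperature[np.nonzero(f >= 1e-6)[0][0]]
        assert tr.meta["onset_true"] == pytest.approx(first_nonzero, abs=0.11)

    def test_half_reactivity_onsets_at_midpoint(self):
        truth = truth_of(SINGLE, agg=AggregationTruth("Fab", 0.5))
        tr = simulate_aggregation_trace(truth, noise_cv=0.0)
        assert tr.meta["onset_true"] == pytest.approx(70.0, abs=0.11)

    def test_threshold_crossing_strictly_after_onset(self):
        truth = truth_of(SINGLE, agg=AggregationTruth("Fab", 0.5, growth_rate=2.0,
                                                      baseline_kcps=200.0))
        tr = simulate_aggregation_trace(truth, noise_cv=0.0)
        crossing = tr.temperature[np.nonzero(tr.intensity >= 3000.0)[0][0]]
        assert crossing > tr.meta["onset_true"]

    def test_unreachable_reactivity_gives_flat_trace(self):
        trs = (TransitionTruth(88.0, 100.0, 100.0, "Fab"),)
        truth = truth_of(trs, agg=AggregationTruth("Fab", 0.9999999))
        tr = simulate_aggregation_trace(truth, noise_cv=0.0)
        assert tr.meta["onset_true"] is None
        assert np.ptp(tr.intensity) == 0.0

    def test_noiseless_trace_is_non_decreasing(self):
        truth = truth_of(SINGLE, agg=AggregationTruth("Fab", 0.3))
        tr = simulate_aggregation_trace(truth, noise_cv=0.0)
        assert np.all(np.diff(tr.intensity) >= 0)


class TestDilutionSeries:
    def test_affine_model_ratio(self):
        truth = truth_of(SINGLE, kd_true=0.01, d0_true=5e-7)
        s = simulate_dilution_series(truth, concentrations=[1, 2, 3, 4, 5])
        assert s.diffusion[4] / s.diffusion[0] == pytest.approx(1.05 / 1.01)

    def test_zero_kd_is_constant(self):
        truth = truth_of(SINGLE, kd_true=0.0, d0_true=5e-7)
        s = simulate_dilution_series(truth)
        assert np.allclose(s.diffusion, 5e-7)

    def test_negative_kd_strictly_decreasing(self):
        truth = truth_of(SINGLE, kd_true=-0.02, d0_true=5e-7)
        s = simulate_dilution_series(truth)
        assert np.all(np.diff(s.diffusion) < 0)

    def test_single_concentration_rejected(self):
        with pytest.raises(InvalidInputError):
            simulate_dilution_series(truth_of(SINGLE), concentrations=[2.0, 2.0])


def _valley_oracle_composition(t, y):
    """Independent composition oracle: valley-bounded trapezoid areas."""
    apexes, _ = find_peaks(y, height=0.005 * y.max())
    bounds = [0]
    for a, b in zip(apexes[:-1], apexes[1:]):
        bounds.append(a + int(np.argmin(y[a:b + 1])))
    bounds.append(len(y) - 1)
    areas = [trapezoid(y[i:j + 1], t[i:j + 1]) for i, j in zip(bounds[:-1], bounds[1:])]
    return 100.0 * np.array(areas) / np.sum(areas)


class TestChromatogram:
    def test_three_peak_composition_matches_oracle(self):
        truth = truth_of(SINGLE, sec_fractions_true=(5.0, 90.0, 5.0))
        ch = simulate_chromatogram(truth, noise_sd=0.0)
        comp = _valley_oracle_composition(ch.time, ch.a280)
        assert np.allclose(comp, [5, 90, 5], atol=0.5)

    def test_monomer_only_gives_single_peak(self):
        truth = truth_of(SINGLE, sec_fractions_true=(0.0, 100.0, 0.0))
        ch = simulate_chromatogram(truth, noise_sd=0.0)
        peaks, _ = find_peaks(ch.a280, height=0.01 * ch.a280.max())
        assert len(peaks) == 1

    def test_total_area_invariant_under_fraction_permutation(self):
        a = simulate_chromatogram(truth_of(SINGLE, sec_fractions_true=(10.0, 85.0, 5.0)),
                                  noise_sd=0.0)
        b = simulate_chromatogram(truth_of(SINGLE, sec_fractions_true=(5.0, 10.0, 85.0)),
                                  noise_sd=0.0)
        assert (trapezoid(a.a280, a.time)
                == pytest.approx(trapezoid(b.a280, b.time), rel=1e-6))

    def test_overlapping_peaks_flagged(self):
        truth = truth_of(SINGLE)
        ch = simulate_chromatogram(truth, peaks=SECPeakParams((8.0, 8.1, 9.8), 0.12))
        assert any("overlap" in w for w in ch.meta["warnings"])


class TestPanel:
    def test_default_study_design_has_75_samples(self):
        from mabdev.designs import study_design
        panel = make_panel(study_design(), seed=0)
        assert len(panel) == 75

    def test_minimal_design_has_one_sample(self):
        design = PanelDesign(mab_ids=["m1"], ph_values=(6.0,), nacl_values=(0.0,),
                             truth_fn=lambda m, p, n: truth_of(
                                 SINGLE, cond=FormulationCondition(m, p, n)))
        assert len(make_panel(design, seed=0)) == 1

    def test_same_seed_gives_identical_traces(self):
        design = PanelDesign(mab_ids=["m1"], ph_values=(6.0,), nacl_values=(0.0, 150.0),
                             truth_fn=lambda m, p, n: truth_of(
                                 SINGLE, cond=FormulationCondition(m, p, n)))
        a = make_panel(design, seed=3)
        b = make_panel(design, seed=3)
        for sa, sb in zip(a, b):
            assert np.array_equal(sa.thermogram.cp_excess, sb.thermogram.cp_excess)
            assert np.array_equal(sa.aggregation_trace.intensity,
                                  sb.aggregation_trace.intensity)

    def test_onset_temperature_for_fraction_inverts_the_model(self):
        trs = (TransitionTruth(70.0, 100.0, 300.0, "Fab"),)
        t = onset_temperature_for_fraction(trs, 0.5)
        assert t == pytest.approx(70.0, abs=1e-3)
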