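"""Salt-effect deltas, RAG classification and the designed trade-off panel."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from mabdev.conditions import FormulationCondition
from mabdev.dsc import DSCResult, FractionUnfoldedCurve, UnfoldingTransition
from mabdev.light_scattering import AggregationResult
from mabdev.salt import (LiabilityThresholds, SaltPair, build_salt_map,
                         classify_liability, compute_delta_tagg2,
                         compute_delta_tm, evaluate_salt_pair)


def fake_dsc(tms_by_domain, nacl, mab="mAb-X", ph=6.0):
    cond = FormulationCondition(mab, ph, nacl)
    transitions = [UnfoldingTransition(tm, 100.0 + 100 * i, 2.0, dom)
                   for i, (dom, tm) in enumerate(sorted(tms_by_domain.items(),
                                                        key=lambda kv: kv[1]))]
    curve = FractionUnfoldedCurve([20.0, 110.0], [0.0, 1.0])
    return DSCResult(cond, min(tms_by_domain.values()) - 5.0, transitions, curve, 0.0)


def pair(tms_low, tms_high, tagg2_low=None, tagg2_high=None, mab="mAb-X", ph=6.0):
    return SaltPair(mab, ph,
                    (fake_dsc(tms_low, 0.0, mab, ph),
                     AggregationResult(None, tagg2_low)),
                    (fake_dsc(tms_high, 150.0, mab, ph),
                     AggregationResult(None, tagg2_high)))


class TestDeltaTagg2:
    def test_salt_raised_tagg2_reads_negative(self):
        p = pair({"Fab": 80.0}, {"Fab": 80.0}, tagg2_low=70.0, tagg2_high=72.6)
        assert compute_delta_tagg2(p) == pytest.approx(-2.6)

    def test_identical_traces_give_zero(self):
        p = pair({"Fab": 80.0}, {"Fab": 80.0}, 70.0, 70.0)
        assert compute_delta_tagg2(p) == 0.0

    def test_antisymmetric_under_swap(self):
        p = pair({"Fab": 80.0}, {"Fab": 79.0}, 70.0, 74.0)
        swapped = SaltPair(p.mab_id, p.pH, p.high, p.low)
        assert compute_delta_tagg2(p) == -compute_delta_tagg2(swapped)

    def test_undetected_condition_flagged_nan(self):
        p = pair({"Fab": 80.0}, {"Fab": 80.0}, 70.0, None)
        assert np.isnan(compute_delta_tagg2(p))


class TestDeltaTm:
    def test_max_abs_shift_across_domains(self):
        p = pair({"CH2": 70.0, "Fab": 82.0}, {"CH2": 67.6, "Fab": 77.8})
        assert compute_delta_tm(p) == pytest.approx(4.2)
        assert compute_delta_tm(p, mode="per_domain", domain="CH2") == pytest.approx(2.4)

    def test_identical_results_give_zero(self):
        p = pair({"CH2": 70.0, "Fab": 82.0}, {"CH2": 70.0, "Fab": 82.0})
        assert compute_delta_tm(p) == 0.0

    def test_invariant_to_common_temperature_shift(self):
        p1 = pair({"CH2": 70.0, "Fab": 82.0}, {"CH2": 68.0, "Fab": 79.0})
        p2 = pair({"CH2": 75.0, "Fab": 87.0}, {"CH2": 73.0, "Fab": 84.0})
        assert compute_delta_tm(p1) == pytest.approx(compute_delta_tm(p2))

    def test_unmatched_counts_fall_back_to_rank(self):
        p = pair({"CH2": 70.0, "Fab": 82.0}, {"Fab": 80.0})
        with pytest.warns(UserWarning, match="rank"):
            got = compute_delta_tm(p)
        assert got == pytest.approx(10.0)  # rank1: 70 vs 80


class TestClassification:
    @pytest.mark.parametrize("dtm, dtagg2, expected_rag, coll, conf", [
        (0.5, -7.0, "amber", True, False),   # colloidal only
        (12.2, +5.0, "amber", False, True),  # conformational only
        (5.0, -1.0, "red", True, True),
        (1.0, +1.0, "green", False, False),
        (3.0, 0.0, "green", False, False),   # exact thresholds are non-liable
    ])
    def test_truth_table(self, dtm, dtagg2, expected_rag, coll, conf):
        res = classify_liability(dtm, dtagg2)
        assert res.rag == expected_rag
        assert res.colloidal_liability == coll
        assert res.conformational_liability == conf

    def test_rag_consistency_invariant(self):
        rng = np.random.default_rng(0)
        for _ in range(200):
            r = classify_liability(rng.uniform(0, 15), rng.uniform(-10, 15))
            n = r.colloidal_liability + r.conformational_liability
            assert r.rag == {0: "green", 1: "amber", 2: "red"}[n]

    @settings(max_examples=50, deadline=None)
    @given(dtm=st.floats(0.0, 15.0), bump=st.floats(0.0, 5.0),
           dtagg2=st.floats(-10.0, 15.0))
    def test_monotone_in_both_axes(self, dtm, bump, dtagg2):
        base = classify_liability(dtm, dtagg2)
        worse_conf = classify_liability(dtm + bump, dtagg2)
        worse_coll = classify_liability(dtm, dtagg2 - bump)
        assert worse_conf.conformational_liability >= base.conformational_liability
        assert worse_coll.colloidal_liability >= base.colloidal_liability

    def test_custom_thresholds(self):
        res = classify_liability(2.5, 1.0, LiabilityThresholds(dtm_threshold=2.0))
        assert res.conformational_liability


class TestSaltMap:
    def test_row_count_and_quadrant_counts(self):
        results = [classify_liability(1.0, 1.0, mab_id=f"m{i}", pH=6.0)
                   for i in range(25)]
        table = build_salt_map(results)
        assert len(table) == 25
        assert table.attrs["quadrant_counts"] == {"red": 0, "amber": 0, "green": 25}

    def test_incomplete_pairs_excluded(self):
        results = [classify_liability(1.0, float("nan"), mab_id="m", pH=6.0),
                   classify_liability(1.0, 1.0, mab_id="m", pH=7.0)]
        table = build_salt_map(results)
        assert len(table) == 1
        assert table.attrs["n_excluded_incomplete"] == 1

    def test_tradeoff_panel_quadrant_membership(self):
        """Low-pH formulations land on the conformational-liability side,
        neutral/high-pH ones on the colloidal-liability side."""
        from mabdev.designs import tradeoff_design
        from mabdev.dsc import analyze_thermogram
        from mabdev.light_scattering import detect_aggregation
        from mabdev.synth import PanelDesign, make_panel

        base = tradeoff_design(("mAb-A", "mAb-B"))
        design = PanelDesign(mab_ids=base.mab_ids, ph_values=(4.0, 5.0, 7.0, 8.0),
                             nacl_values=(0.0, 150.0), truth_fn=base.truth_fn)
        panel = make_panel(design, seed=5)
        per = {}
        with warnings.catch_warnings():
            warnings.simplefilter("ignore")
            for s in panel:
                dsc = analyze_thermogram(s.thermogram, n_transitions=3)
                agg = detect_aggregation(s.aggregation_trace)
                per[(s.condition.mab_id, s.condition.pH, s.condition.nacl_mM)] = (dsc, agg)
        for mab in design.mab_ids:
            for ph in design.ph_values:
                p = SaltPair(mab, ph, per[(mab, ph, 0.0)], per[(mab, ph, 150.0)])
                res = evaluate_salt_pair(p)
                if ph <= 5:
                    assert res.conformational_liability and not res.colloidal_liability
                else:
                    assert res.colloidal_liability and not res.conformational_liability
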