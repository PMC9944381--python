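"""Built-in screening-panel designs.

``study_design()`` returns the default 5 mAb x 5 pH x 3 NaCl (75-sample)
panel.  Its truth tables encode the behaviours the analysis workflows are
meant to surface:

* per-domain unfolding midpoints with pH trends and salt-induced shifts,
  including one antibody (mAb-2) whose structure is strongly salt-flexible
  at low pH (midpoint shift 12.2 °C at pH 4, 4.2 °C at pH 5 with a 2.4 °C
  C_H2 component) and salt-inert near neutral pH (< 0.3 °C at pH 7);
* aggregation onsets coupled to the unfolded fraction, with designed
  salt effects on the fast-aggregation temperature T_agg_2 spanning both
  electrostatic screening (T_agg_2 raised by salt, e.g. -7.0 °C for
  mAb-3 at pH 7, -2.6 °C for mAb-2 at pH 7) and salting-out behaviour
  (T_agg_2 lowered by salt, e.g. +12.5 °C for mAb-5 and +1.9 °C for
  mAb-4 at pH 5);
* domain-specific aggregation: roughly 30% of detectable onsets coincide
  with C_H2 unfolding rather than Fab unfolding, including mAb-1 whose
  pH-5 behaviour moves from C_H2-mediated aggregation at an unfolded
  fraction of 0.09 (150 mM NaCl) to Fab-mediated at 0.48 (no salt);
* stratified Fab midpoints: mAb-4 occupies the 67-73 °C band alone while
  mAb-5 supplies 13 of the 17 datapoints in 74-78 °C;
* realistic data pathology for ML curation: mAb-1's SEC stream is
  QC-flagged (15 samples) and 12 further samples never cross the
  fast-aggregation threshold inside the ramp, leaving missing T_agg_2.

Temperatures at (pH, NaCl) follow  tm(pH, c) = tm[pH] + salt[pH] * c/150,
i.e. tables are anchored at 0 mM with a linear-in-salt shift.
"""

from __future__ import annotations

import numpy as np

from .conditions import FormulationCondition
from .synth import (
    AggregationTruth,
    PanelDesign,
    SampleTruth,
    TransitionTruth,
    onset_temperature_for_fraction,
)
from .thermo import global_unfolded_fraction

__all__ = ["study_design", "planted_salt_effects", "tradeoff_design", "STUDY_MABS"]

STUDY_MABS = ["mAb-1", "mAb-2", "mAb-3", "mAb-4", "mAb-5"]

# --- per-domain unfolding truth: area & dH_vH (kcal/mol), tm[pH] at 0 mM (°C),
#     salt[pH] = midpoint change from 0 to 150 mM NaCl (°C)

_DOMAINS = {
    "mAb-1": {
        "CH2": dict(area=100.0, dhvh=550.0,
                    tm={4: 69.0, 5: 70.5, 6: 71.5, 7: 72.0, 8: 72.5},
                    salt={4: -2.0, 5: -2.5, 6: -1.5, 7: -1.0, 8: -1.0}),
        "CH3": dict(area=80.0, dhvh=500.0,
                    tm={4: 80.0, 5: 81.5, 6: 82.0, 7: 82.5, 8: 83.0},
                    salt={4: -2.0, 5: -2.0, 6: -1.5, 7: -1.0, 8: -1.0}),
        "Fab": dict(area=400.0, dhvh=450.0,
                    tm={4: 86.0, 5: 88.0, 6: 88.5, 7: 89.0, 8: 89.0},
                    salt={4: -4.5, 5: -4.0, 6: -2.0, 7: -1.0, 8: -1.0}),
    },
    "mAb-2": {
        "CH2": dict(area=110.0, dhvh=550.0,
                    tm={4: 66.0, 5: 68.0, 6: 69.5, 7: 70.5, 8: 71.0},
                    salt={4: -12.2, 5: -2.4, 6: -1.2, 7: -0.25, 8: -0.2}),
        "Fab": dict(area=380.0, dhvh=450.0,
                    tm={4: 79.5, 5: 80.5, 6: 81.5, 7: 82.0, 8: 82.3},
                    salt={4: -1.0, 5: -4.2, 6: -2.0, 7: -0.2, 8: -0.2}),
        "CH3": dict(area=70.0, dhvh=500.0,
                    tm={4: 84.5, 5: 85.5, 6: 86.0, 7: 86.5, 8: 87.0},
                    salt={4: -2.0, 5: -2.0, 6: -1.0, 7: -0.2, 8: -0.2}),
    },
    "mAb-3": {
        "CH2": dict(area=100.0, dhvh=550.0,
                    tm={4: 69.0, 5: 70.0, 6: 71.0, 7: 71.5, 8: 72.0},
                    salt={4: -1.5, 5: -1.0, 6: -1.0, 7: -0.8, 8: -0.8}),
        "Fab": dict(area=400.0, dhvh=450.0,
                    tm={4: 77.0, 5: 79.5, 6: 80.0, 7: 80.8, 8: 81.5},
                    salt={4: -2.0, 5: -0.5, 6: -1.0, 7: -0.8, 8: -0.8}),
        "CH3": dict(area=80.0, dhvh=500.0,
                    tm={4: 84.0, 5: 84.5, 6: 85.0, 7: 85.5, 8: 86.0},
                    salt={4: -1.0, 5: -1.0, 6: -1.0, 7: -0.8, 8: -0.8}),
    },
    "mAb-4": {
        "CH2": dict(area=110.0, dhvh=550.0,
                    tm={4: 61.0, 5: 62.0, 6: 63.0, 7: 63.5, 8: 64.0},
                    salt={4: -1.0, 5: -1.0, 6: -1.0, 7: -1.0, 8: -0.5}),
        "Fab": dict(area=400.0, dhvh=450.0,
                    tm={4: 68.5, 5: 69.5, 6: 70.5, 7: 71.5, 8: 72.3},
                    salt={4: -1.0, 5: -1.0, 6: -0.8, 7: -0.5, 8: -0.5}),
        "CH3": dict(area=80.0, dhvh=500.0,
                    tm={4: 80.0, 5: 80.5, 6: 81.0, 7: 81.5, 8: 82.0},
                    salt={4: -0.5, 5: -0.5, 6: -0.5, 7: -0.5, 8: -0.5}),
    },
    "mAb-5": {
        "CH2": dict(area=100.0, dhvh=550.0,
                    tm={4: 64.0, 5: 65.0, 6: 66.0, 7: 66.5, 8: 67.0},
                    salt={4: -0.5, 5: -0.5, 6: -0.5, 7: -0.5, 8: -0.5}),
        "Fab": dict(area=400.0, dhvh=450.0,
                    tm={4: 74.8, 5: 75.8, 6: 76.5, 7: 77.3, 8: 79.2},
                    salt={4: -0.3, 5: -0.8, 6: -0.5, 7: -0.5, 8: -2.0}),
        "CH3": dict(area=80.0, dhvh=500.0,
                    tm={4: 81.0, 5: 82.0, 6: 82.5, 7: 83.0, 8: 83.5},
                    salt={4: -0.5, 5: -0.5, 6: -0.5, 7: -0.5, 8: -0.5}),
    },
}

# --- aggregation-onset design -------------------------------------------------
# Two description modes per (mAb, pH):
#   anchor:   onset sits at (anchor-domain midpoint + delta), with delta
#             interpolating linearly between its 0 mM and 150 mM values; the
#             resulting salt effect is dTagg2 = delta0 - delta150 - salt_anchor.
#   fraction: onset is wherever the global unfolded fraction reaches the
#             designed value (used for mAb-1, whose overlay statistic is
#             specified in fraction space).
# detectable=False gives a slow-growth trace that never reaches the
# fast-aggregation threshold inside the 25-90 °C ramp (missing T_agg_2).

_GROWTH_FAST = 2.0  # per °C; threshold crossing lags onset by ln(15)/2 ~ 1.35 °C
_GROWTH_SLOW = 0.10  # per °C; never reaches 3000 kcps inside the ramp
_BASELINE_KCPS = 200.0

_ONSETS = {
    "mAb-1": {ph: dict(mode="fraction",
                       frac={0.0: (0.48 if ph == 5 else 0.35),
                             50.0: 0.12,
                             150.0: (0.09 if ph == 5 else 0.08)},
                       reactive={0.0: "Fab", 50.0: "CH2", 150.0: "CH2"})
              for ph in (4, 5, 6, 7, 8)},
    "mAb-2": {
        4: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-1.0, detectable=False),
        5: dict(mode="anchor", anchor="Fab", delta0=1.5, delta150=-2.3),   # dTagg2 = +8.0
        6: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-0.5),  # dTagg2 = +1.5
        7: dict(mode="anchor", anchor="Fab", delta0=-1.5, delta150=1.3),   # dTagg2 = -2.6
        8: dict(mode="anchor", anchor="Fab", delta0=-1.5, delta150=1.7),   # dTagg2 = -3.0
    },
    "mAb-3": {
        4: dict(mode="anchor", anchor="CH2", delta0=0.5, delta150=0.5, detectable=False),
        5: dict(mode="anchor", anchor="Fab", delta0=1.5, delta150=-2.0),   # dTagg2 = +4.0
        6: dict(mode="anchor", anchor="Fab", delta0=-1.5, delta150=2.5),   # dTagg2 = -3.0
        7: dict(mode="anchor", anchor="Fab", delta0=-1.5, delta150=6.3),   # dTagg2 = -7.0
        8: dict(mode="anchor", anchor="Fab", delta0=-1.5, delta150=4.3),   # dTagg2 = -5.0
    },
    "mAb-4": {
        4: dict(mode="anchor", anchor="CH2", delta0=0.3, delta150=-0.2),   # dTagg2 = +1.5
        5: dict(mode="anchor", anchor="CH2", delta0=0.5, delta150=-0.4),   # dTagg2 = +1.9
        6: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-1.2),  # dTagg2 = +1.0
        7: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-1.3),  # dTagg2 = +0.8
        8: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-1.0, detectable=False),
    },
    "mAb-5": {
        4: dict(mode="anchor", anchor="Fab", delta0=-1.0, delta150=-1.0, detectable=False),
        5: dict(mode="anchor", anchor="Fab", delta0=1.7, delta150=-10.0),  # dTagg2 = +12.5
        6: dict(mode="anchor", anchor="Fab", delta0=1.5, delta150=-4.0),   # dTagg2 = +6.0
        7: dict(mode="anchor", anchor="Fab", delta0=1.0, delta150=-1.5),   # dTagg2 = +3.0
        8: dict(mode="anchor", anchor="CH2", delta0=0.5, delta150=2.0),    # dTagg2 = -1.0
    },
}

# --- colloidal / size / purity truth -----------------------------------------

_KD_BASE = {"mAb-1": 0.010, "mAb-2": -0.002, "mAb-3": 0.004, "mAb-4": -0.004, "mAb-5": 0.012}
_Z_BASE = {"mAb-1": 10.8, "mAb-2": 10.2, "mAb-3": 11.2, "mAb-4": 10.5, "mAb-5": 11.0}
_PDI_BASE = {"mAb-1": 0.05, "mAb-2": 0.06, "mAb-3": 0.07, "mAb-4": 0.03, "mAb-5": 0.05}
_HMW_BASE = {"mAb-1": 1.5, "mAb-2": 4.0, "mAb-3": 3.0, "mAb-4": 5.0, "mAb-5": 1.0}
_MAB_IDX = {m: i for i, m in enumerate(STUDY_MABS)}

#: Stokes-Einstein scale: D_0 [cm^2/s] = _D0_SCALE / z_average [nm]
#: (water at 25 °C; a 10.5 nm hydrodynamic diameter gives ~4.7e-7 cm^2/s).
_D0_SCALE = 4.9e-6


def _tm(mab, domain, ph, nacl):
    d = _DOMAINS[mab][domain]
    return d["tm"][ph] + d["salt"][ph] * (nacl / 150.0)


def _transitions(mab, ph, nacl):
    return tuple(
        TransitionTruth(tm_true=_tm(mab, dom, ph, nacl),
                        dh_vanthoff=_DOMAINS[mab][dom]["dhvh"],
                        dh_cal=_DOMAINS[mab][dom]["area"],
                        domain_label=dom)
        for dom in ("CH2", "Fab", "CH3")
    )


def _onset_temperature(mab, ph, nacl):
    """Designed onset temperature (°C) of a sample, or None when the design
    marks its fast aggregation as unreachable."""
    spec = _ONSETS[mab][ph]
    if spec["mode"] == "fraction":
        frac = np.interp(nacl, [0.0, 50.0, 150.0],
                         [spec["frac"][0.0], spec["frac"][50.0], spec["frac"][150.0]])
        return onset_temperature_for_fraction(_transitions(mab, ph, nacl), float(frac))
    delta = spec["delta0"] + (spec["delta150"] - spec["delta0"]) * (nacl / 150.0)
    return _tm(mab, spec["anchor"], ph, nacl) + delta


def _aggregation_truth(mab, ph, nacl):
    spec = _ONSETS[mab][ph]
    transitions = _transitions(mab, ph, nacl)
    t_on = _onset_temperature(mab, ph, nacl)
    frac = float(global_unfolded_fraction(np.array([t_on]),
                                          [tr.triple for tr in transitions])[0])
    if spec["mode"] == "fraction":
        reactive = spec["reactive"][min(spec["reactive"], key=lambda c: abs(c - nacl))]
    else:
        reactive = spec["anchor"]
    growth = _GROWTH_FAST if spec.get("detectable", True) else _GROWTH_SLOW
    return AggregationTruth(reactive_domain=reactive,
                            reactivity_fraction=min(max(frac, 1e-9), 1.0),
                            growth_rate=growth,
                            baseline_kcps=_BASELINE_KCPS)


def _sample_truth(mab, ph, nacl):
    ph = int(round(ph))
    z = _Z_BASE[mab] + 0.06 * (ph - 4) + 0.0008 * nacl
    hmw = _HMW_BASE[mab] + 0.3 * (ph - 4) + 0.004 * nacl
    lmw = 0.4 + 0.02 * (ph - 4) + 0.05 * _MAB_IDX[mab]
    return SampleTruth(
        condition=FormulationCondition(mab, float(ph), float(nacl)),
        transitions=_transitions(mab, ph, nacl),
        aggregation=_aggregation_truth(mab, ph, nacl),
        kd_true=_KD_BASE[mab] + 0.003 * (6 - ph) - 0.00004 * nacl,
        d0_true=_D0_SCALE / z,
        sec_fractions_true=(hmw, 100.0 - hmw - lmw, lmw),
        z_average_nm_true=z,
        pdi_true=_PDI_BASE[mab] + 0.005 * (ph - 4),
        qc_flag=(mab == "mAb-1"),  # SEC stream classed below standard
    )


def study_design() -> PanelDesign:
    """The default 75-sample screening panel (5 mAbs x pH 4-8 x 0/50/150 mM)."""
    return PanelDesign(mab_ids=list(STUDY_MABS), truth_fn=_sample_truth)


def planted_salt_effects():
    """Ground-truth salt-effect table for the default panel.

    One row per (mAb, pH): true dT_m (max absolute per-domain midpoint
    shift, °C), true dT_agg_2 (0 mM minus 150 mM fast-aggregation
    temperature, °C), completeness, and the planted liability labels
    under the default thresholds (dT_m > 3 °C conformational,
    dT_agg_2 < 0 colloidal).
    """
    import pandas as pd

    rows = []
    for mab in STUDY_MABS:
        for ph in (4, 5, 6, 7, 8):
            dtm = max(abs(_DOMAINS[mab][dom]["salt"][ph]) for dom in _DOMAINS[mab])
            spec = _ONSETS[mab][ph]
            complete = spec.get("detectable", True)
            if complete:
                t0 = _onset_temperature(mab, ph, 0.0)
                t150 = _onset_temperature(mab, ph, 150.0)
                dtagg2 = t0 - t150
            else:
                dtagg2 = np.nan
            conf = dtm > 3.0
            coll = bool(dtagg2 < 0.0) if complete else None
            if not complete:
                rag = None
            elif conf and coll:
                rag = "red"
            elif conf or coll:
                rag = "amber"
            else:
                rag = "green"
            rows.append(dict(mab_id=mab, pH=ph, dtm_true=dtm, dtagg2_true=dtagg2,
                             complete=complete, conformational_true=conf,
                             colloidal_true=coll, rag_true=rag))
    return pd.DataFrame(rows)


def tradeoff_design(mab_ids=("mAb-A", "mAb-B", "mAb-C")) -> PanelDesign:
    """A deliberately polarised panel for the colloidal/conformational
    trade-off: every antibody is salt-flexible at pH <= 5 (large midpoint
    shifts, salt lowers T_agg_2) and salt-screened at pH >= 7 (rigid
    midpoints, salt raises T_agg_2)."""

    def truth_fn(mab, ph, nacl):
        i = list(mab_ids).index(mab)
        flexible = ph <= 5
        tm_shift = (-6.0 if flexible else -0.5) * (nacl / 150.0)
        base_fab = 78.0 + i + 0.8 * (ph - 6)
        transitions = (
            TransitionTruth(base_fab - 8.0 + tm_shift * 0.5, 550.0, 100.0, "CH2"),
            TransitionTruth(base_fab + tm_shift, 450.0, 400.0, "Fab"),
            TransitionTruth(base_fab + 6.0 + tm_shift * 0.3, 500.0, 80.0, "CH3"),
        )
        onset_delta = (-4.0 if flexible else +4.0) * (nacl / 150.0)  # vs 0 mM
        t_on = base_fab + tm_shift - 1.0 + onset_delta
        frac = float(global_unfolded_fraction(np.array([t_on]),
                                              [tr.triple for tr in transitions])[0])
        return SampleTruth(
            condition=FormulationCondition(mab, float(ph), float(nacl)),
            transitions=transitions,
            aggregation=AggregationTruth("Fab", min(max(frac, 1e-9), 1.0),
                                         _GROWTH_FAST, _BASELINE_KCPS),
            kd_true=0.005 - 0.002 * (ph - 6),
        )

    return PanelDesign(mab_ids=list(mab_ids), truth_fn=truth_fn)
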