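# mabdev

Analytical workflows for monoclonal-antibody (mAb) developability
screening: turn raw biophysical thermal-ramp and chromatography exports
into liability calls that a T_m-only ranking would miss.

The package is aimed at protein formulation / developability scientists
and at method developers who need a fully synthetic, ground-truth-known
test bed for this class of assays. It implements three workflows over a
standard screen (5 antibodies × pH 4–8 × 0/50/150 mM NaCl in the
built-in design):

1. **DSC + SLS overlay (site-specific aggregation propensity).**
   A DSC thermogram is deconvolved into two-state transitions
   (K(T) = exp[(ΔH_vH/R)(1/T_m − 1/T)], excess heat capacity
   ΣᵢΔH_cal,i·dfᵢ/dT); the largest-area peak is Fab, the lowest-midpoint
   remaining peak C_H2. The cumulative fraction-unfolded curve
   F(T) = ∫Cp dT / ∫Cp dT|total is evaluated at the aggregation onset
   T_agg1 detected from the SLS ramp. A small F(T_agg1) means a highly
   reactive aggregation-prone region; the transition contributing most
   heat capacity at T_agg1 names the responsible domain.
2. **Salt-effect liability map.** For each (mAb, pH), the 0 and 150 mM
   NaCl formulations are compared: ΔT_agg2 = T_agg2(0 mM) − T_agg2(150 mM),
   where T_agg2 is the interpolated crossing of a fixed 3,000 kcps
   fast-aggregation threshold, and ΔT_m is the maximum absolute
   salt-induced midpoint shift. ΔT_agg2 < 0 ⇒ colloidal liability
   (salt screens electrostatic attraction); ΔT_m > 3 °C ⇒ conformational
   liability (salt-flexible structure). Red = both, amber = one,
   green = neither.
3. **Transition-temperature prediction.** T_onset and T_m1–T_m3 are
   predicted from light-scattering (k_D, D_0, k_D SE, Z-average, PDI,
   T_agg1/2), SEC (%HMW/%Monomer/%LMW) and formulation (pH, NaCl)
   metrics with one gradient-boosting regressor per target, evaluated by
   5-fold × 5-repeat cross-validation (mean MAE over 25 validation
   splits) and ranked by impurity (Gini) feature importance. Curation
   removes QC-flagged rows, rows with missing values and collinear
   predictors (|r| ≥ 0.95).

A synthetic-data module (`mabdev.synth` / `mabdev.designs`) generates
all four instrument streams with known ground truth, so every stage has
a parameter-recovery test surface without any external data.

## Worked example

```python
from mabdev.designs import study_design
from mabdev.dsc import analyze_thermogram
from mabdev.light_scattering import detect_aggregation
from mabdev.overlay import overlay_sample
from mabdev.synth import simulate_sample

design = study_design()
for nacl in (150.0, 0.0):
    s = simulate_sample(design.truth_fn("mAb-1", 5, nacl), seed=3)
    ov = overlay_sample(analyze_thermogram(s.thermogram),
                        detect_aggregation(s.aggregation_trace))
    print(nacl, ov.tm_fab, ov.frac_unfolded_at_onset, ov.coinciding_domain)
```

prints (run as `examples/03_aggregation_overlay.py`):

```
[NaCl] =   150 mM : T_m(Fab) = 84.0 °C, T_agg1 = 68.1 °C, fraction unfolded at onset = 0.07, coinciding domain = CH2
[NaCl] =     0 mM : T_m(Fab) = 88.0 °C, T_agg1 = 87.4 °C, fraction unfolded at onset = 0.47, coinciding domain = Fab
```

At 150 mM NaCl this antibody aggregates while its C_H2 domain unfolds,
with only ~7% of the protein unfolded — a reactive aggregation-prone
region exposed early. Removing salt suppresses that pathway (fraction
≈ 0.47, Fab-mediated onset) and raises T_m(Fab) from 84 to 88 °C: the
formulation change, not a different molecule, fixed the liability.

The other capabilities are demonstrated in `examples/01–05` (panel
simulation, DSC deconvolution, the salt-effect map with quadrant
counts, and the cross-validated T_m prediction, which on the built-in
panel reaches mean MAE ≈ 0.4–0.6 °C with Pearson r ≥ 0.97 per target).

There is also a thin CLI over the batch pipeline:

```bash
mabdev all --panel-dir panel --output-dir results --seed 1
```

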