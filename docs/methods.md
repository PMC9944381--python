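# Methods

## Thermodynamic model

All unfolding is modelled as a sum of independent two-state transitions.
For a transition with midpoint T_m (°C, converted to kelvin internally)
and van't Hoff enthalpy ΔH_vH (kcal/mol),

    K(T) = exp[(ΔH_vH / R)(1/T_m − 1/T)],   f(T) = K/(1+K),

and the excess heat capacity is Σᵢ ΔH_cal,i · dfᵢ/dT with
dfᵢ/dT = ΔH_vH/(R T²)·f(1−f). R = 1.987204×10⁻³ kcal/(mol·K) because
enthalpies are carried in kcal/mol. Fitted peaks are reported as
(T_m, area, width) where width is the FWHM of the Cp peak; width and
ΔH_vH are interchangeable through FWHM = 3.5255·R·T_m²/ΔH_vH. The
model ignores reversibility, scan-rate effects and absolute heat
capacity; it describes the shape information the workflows actually
consume.

The *calorimetric* fraction-unfolded curve is the running integral of
the baseline-subtracted thermogram normalised by the total integral,
clipped to [0,1] and forced non-decreasing. For noiseless two-state
data it coincides with the ΔH_cal-weighted sum of populations; a
population-based variant computed from the fitted transitions is
available as `fraction_unfolded_from_fit` for thermograms whose
baseline is untrustworthy.

## DSC analysis choices

* **Baseline.** An affine baseline is fitted by least squares jointly
  over the first and last 8 °C of the scan (defaults; both windows must
  be transition-free). Pooling the two windows matters: any offset or
  tilt error integrates linearly into the fraction-unfolded curve, and
  with the default synthetic noise (σ = 2 kcal/mol/°C) the joint fit
  keeps the mid-scan fraction error near 0.01–0.02 SD. If the residual
  inside an anchor window exceeds 5% of the signal span the result is
  flagged (signal leaking into the window).
* **Deconvolution.** Bounded trust-region least squares over
  (T_m, area, ΔH_vH) per component, with up to three starts built from
  Savitzky–Golay-smoothed peak picks (±1 °C perturbed copies) or, when
  too few peaks are resolvable, moment-based spreading. Iteration
  exhaustion returns the best-so-far fit — deliberate, because the
  model-selection loop needs honest residuals for underfits. If two
  fitted components collapse onto the same midpoint (closer than half a
  width), the parsimonious merged representation is preferred whenever
  it fits equally well; the surplus component is parked at the scan edge
  with near-zero area, which is what "overfitted" should look like in a
  report.
* **Number of transitions.** Fit n = 1..3 and keep the smallest n whose
  successor improves the RMS residual by less than 10% — shoulders that
  are only noise do not earn a component.
* **T_onset.** Lowest temperature at which the smoothed, baseline-
  subtracted signal exceeds 5% (configurable) of its maximum for ≥10
  consecutive grid points. Monotone in the threshold by construction.
* **Domain assignment.** Largest calorimetric area → Fab; lowest
  midpoint of the remainder → C_H2; third peak → C_H3. With two peaks
  the non-Fab peak is C_H2 (the rule degenerates to that). Area ties
  (≤1e-9) break toward the lower midpoint with a warning.

## Light scattering

* **k_D.** D(c) = D_0(1 + k_D c) fitted by OLS; k_D = slope/intercept,
  with its standard error from first-order (delta-method) propagation
  of the OLS covariance of (intercept, slope). Two-point designs return
  k_D_SE = 0 with a warning; a non-positive intercept is rejected as a
  nonphysical D_0.
* **T_agg1** ("earliest detectable sign of aggregation") uses a
  confirm-then-backdate scheme: a sustained excursion of the 5-point
  moving-average intensity above baseline mean + 5σ for ≥10 consecutive
  points confirms aggregation, and the onset is then backdated to the
  sub-grid (interpolated) point where the smoothed signal first left the
  baseline band (mean + 3 smoothed-σ). Dating the onset at the 5σ run
  start would be biased late by ~0.2 °C, which on a steep unfolding
  flank shifts the fraction-unfolded statistic by up to 0.06; the
  backdate removes the bias while the 5σ/run-length gate still rejects
  spikes. The criterion is invariant to positive rescaling of the trace.
* **T_agg2** is the linearly interpolated first upward crossing of a
  fixed intensity threshold (default 3,000 kcps — an instrument-setup
  convention, therefore exposed in the detection parameters). A trace
  already above threshold at scan start is rejected as pre-aggregated.

## SEC

Linear baseline between the chromatogram's end windows, peak apexes by
prominence, boundaries at valley minima between apexes, signed
trapezoid areas per segment (zero-mean noise then cancels instead of
rectifying into small peaks; only a net-negative segment is clipped,
with a warning). Largest area → Monomer; earlier peaks sum to HMW,
later to LMW; percentages close to exactly 100. Shoulders are split by
the valley (perpendicular-drop convention), not tangent-skimmed.

## Salt-effect classification

ΔT_agg2 = T_agg2(0 mM) − T_agg2(150 mM), so negative values mean salt
*raises* the fast-aggregation temperature (screened electrostatic
attraction). ΔT_m defaults to the maximum absolute shift across
domain-matched transitions — a C_H2 shift of 2.4 °C coexisting with a
4.2 °C shift elsewhere must read as 4.2 — with per-domain and
first-transition modes available. Thresholds (3 °C, 0 °C) are strict
inequalities: a sample exactly on a border is non-liable, matching the
reading that the border belongs to the robust side. Pairs missing a
T_agg2 in either condition are flagged incomplete and excluded from the
map (their ΔT_m is still reported).

## Transition-temperature prediction

Curation order: QC-flagged rows out, then rows with any missing value,
then collinear predictors — for each pair with |Pearson r| ≥ 0.95 the
member with the larger mean absolute correlation to the remaining
predictors is dropped (deterministic and order-independent; ties fall
to the later column). One `GradientBoostingRegressor` (300 trees,
learning rate 0.05, depth 3, subsample 0.8) per target, evaluated with
`RepeatedKFold` (5 folds × 5 repeats); the seed fixes both the split
assignment and every model's initialisation. An optional random search
(≤50 parameter draws over the same splits) can replace the fixed
configuration; it is off by default because the evaluation protocol,
not the hyperparameter optimum, is the point. Impurity importances are
collected per split and summarised as median/quartiles/mean, ranked by
median. Out-of-fold predictions are averaged over repeats with their
across-repeat SD, supporting measured-vs-predicted plots with error
bars.

## Synthetic panel: what it emulates and what it does not

The generator produces the four instrument streams with known truth:
multi-transition thermograms (additive Gaussian noise), aggregation
ramps whose onset fires when the ΔH_cal-weighted global unfolded
fraction reaches a designed reactivity threshold — gated on the
designated reactive domain actually unfolding — followed by exponential
intensity growth capped at 10⁶ kcps (multiplicative log-normal noise,
since scattering noise scales with signal), affine D(c) dilution series
(Gaussian noise) and three-Gaussian chromatograms (HMW < Monomer < LMW
elution order). Default grids: DSC 20–110 °C, SLS 25–90 °C, step
0.1 °C. Default noise levels — DSC σ = 2 kcal/mol/°C (~1% of a typical
Fab peak), SLS cv = 5%, DLS σ = 0.5% of D_0, SEC σ = 0.002 AU — are
conservative stand-ins chosen once; real instrument noise
characteristics are not published for this assay suite.

`designs.study_design()` fixes the 75-sample screening design with
explicit per-domain truth tables: pH-monotone midpoints, per-pH salt
shifts (one antibody flexible at low pH, inert at neutral pH),
aggregation onsets anchored to unfolding flanks so that the 0-vs-150 mM
T_agg2 differences equal designed values, a stratified Fab-midpoint
layout (one molecule alone in 67–73 °C; another carrying 13 of 17
points in 74–78 °C), ~30% C_H2-coinciding onsets, one QC-flagged SEC
stream (15 samples) and 12 samples whose slow-growth aggregation never
crosses 3,000 kcps inside the ramp (missing T_agg2). Because D_0 is
tied to the Z-average through Stokes–Einstein, %Monomer to %HMW through
closure, and T_agg1 to T_agg2 through a constant growth lag, the
curation stage has exactly three collinear pairs to find.

Passing tests on this panel shows the pipeline recovers designed truth
through realistic trace shapes and noise; it does not show robustness
to hallmarks of real data the generator omits: irreversible/scan-rate-
dependent unfolding, non-two-state intermediates, curved D(c) at high
concentration, tailing/fronting SEC peaks, drifting baselines beyond
affine, Hofmeister-specific ion effects, or inter-replicate instrument
drift.

## Numerical notes and degenerate inputs

Two-state populations are evaluated through a numerically stable
logistic in ln K. Onset search and T_agg2 both interpolate between grid
samples, so results are grid-resolution independent to first order.
Zero-variance SLS baselines fall back to a 1 kcps noise stand-in (flat
zero trace) or a relative floor (flat nonzero trace), with warnings.
Empty chromatograms, thermograms with non-positive total integral,
degenerate dilution designs and config files with unknown keys all
raise typed errors; batch analysis isolates per-sample failures into an
error column and continues.

## Known limitations

* The overlay statistic inherits the cumulative-integral convention;
  for strongly non-two-state or exothermic-aggregation-distorted
  thermograms the calorimetric fraction and the population fraction
  diverge, and only the former is produced by default.
* Domain assignment is rule-based (area/order); atypical molecules
  (e.g. Fab transitions smaller than C_H3) will be mislabelled, which
  propagates into domain-matched ΔT_m.
* The ML stage's accuracy on the synthetic panel (~0.5 °C MAE) reflects
  the panel's clean structure and should not be read as an expected
  accuracy on laboratory data.
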