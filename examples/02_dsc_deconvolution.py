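"""Deconvolve one DSC thermogram into domain-level unfolding transitions.

A three-transition IgG thermogram is simulated with known ground truth
(C_H2 at 70 °C, Fab at 82 °C, C_H3 at 89 °C) and analysed: baseline
subtraction, bounded multi-start least-squares deconvolution, onset
extraction and domain assignment (largest area -> Fab; lowest remaining
midpoint -> C_H2).
"""

from mabdev.conditions import FormulationCondition
from mabdev.dsc import analyze_thermogram
from mabdev.synth import (AggregationTruth, SampleTruth, TransitionTruth,
                          simulate_thermogram)

truth = SampleTruth(
    condition=FormulationCondition("mAb-demo", 6.0, 0.0),
    transitions=(TransitionTruth(70.0, 550.0, 90.0, "CH2"),
                 TransitionTruth(82.0, 450.0, 320.0, "Fab"),
                 TransitionTruth(89.0, 500.0, 70.0, "CH3")),
    aggregation=AggregationTruth(),
)
tg = simulate_thermogram(truth, noise_sd=2.0, seed=0)
result = analyze_thermogram(tg)

print(f"T_onset = {result.tonset:.1f} °C")
for tr in result.transitions:
    print(f"  {tr.domain:>3}: T_m = {tr.tm:.2f} °C, "
          f"area = {tr.area:.0f} kcal/mol, FWHM = {tr.width:.2f} °C")
print(f"fit residual (RMS) = {result.fit_residual:.2f} kcal/mol/°C")
# The fitted midpoints should sit within ~0.1 °C of the designed 70/82/89,
# and the 320 kcal/mol peak carries the Fab label.
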