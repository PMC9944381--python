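"""Synthetic instrument-trace generator with known ground truth.

Emulates the four data streams of an antibody developability screen so
every analysis stage has a parameter-recovery test surface:

* DSC thermograms built from 2-3 independent two-state transitions
  (excess heat capacity = sum of dH_cal * df/dT peaks) with additive
  Gaussian noise;
* SLS thermal-aggregation ramps whose onset is coupled to the global
  unfolded fraction reaching a designed reactivity threshold, followed
  by exponential intensity growth capped at a saturation value, with
  multiplicative log-normal noise (scattering noise scales with signal);
* DLS dilution series D(c) = D_0 (1 + k_D c) with Gaussian noise;
* three-Gaussian SEC chromatograms (HMW eluting first, then Monomer,
  then LMW) with areas proportional to the designed composition.

``make_panel`` assembles a full screening design (by default 5 mAbs x
5 pH x 3 NaCl = 75 samples) from per-condition truth tables, so the
pH- and salt-dependence of midpoints and aggregation onsets can be
designed to exercise the case-study workflows.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Callable, Sequence

import numpy as np
from scipy.optimize import brentq

from .conditions import FormulationCondition
from .dsc import Thermogram
from .errors import InvalidInputError, ScanDomainError
from .light_scattering import AggregationTrace, DilutionSeries
from .sec import SECChromatogram
from .thermo import excess_heat_capacity, global_unfolded_fraction, unfolded_fraction

__all__ = [
    "TransitionTruth",
    "AggregationTruth",
    "SampleTruth",
    "PanelDesign",
    "SimulatedSample",
    "default_dsc_grid",
    "default_sls_grid",
    "simulate_thermogram",
    "simulate_aggregation_trace",
    "simulate_dilution_series",
    "simulate_chromatogram",
    "simulate_sample",
    "make_panel",
    "onset_temperature_for_fraction",
]

#: Saturation cap (kcps) keeping aggregation traces bounded.
INTENSITY_CAP = 1.0e6


@dataclass(frozen=True)
class TransitionTruth:
    """Designed two-state transition: midpoint, van't Hoff and calorimetric
    enthalpies (kcal/mol) and the structural domain it represents."""

    tm_true: float  # °C
    dh_vanthoff: float  # kcal/mol
    dh_cal: float  # kcal/mol (peak area)
    domain_label: str = "unassigned"  # Fab | CH2 | CH3

    def __post_init__(self):
        if self.dh_vanthoff <= 0 or self.dh_cal <= 0:
            raise InvalidInputError("enthalpies must be positive")

    @property
    def triple(self):
        return (self.tm_true, self.dh_cal, self.dh_vanthoff)


@dataclass(frozen=True)
class AggregationTruth:
    """Designed aggregation behaviour.

    ``reactivity_fraction`` is the global unfolded fraction at which
    self-assembly begins; intensity then grows exponentially at
    ``growth_rate`` per °C from ``baseline_kcps``.
    """

    reactive_domain: str = "Fab"  # Fab | CH2
    reactivity_fraction: float = 0.2
    growth_rate: float = 2.0  # per °C
    baseline_kcps: float = 200.0

    def __post_init__(self):
        if not (0.0 < self.reactivity_fraction <= 1.0):
            raise InvalidInputError("reactivity_fraction must lie in (0, 1]")
        if self.growth_rate <= 0 or self.baseline_kcps <= 0:
            raise InvalidInputError("growth_rate and baseline_kcps must be positive")


@dataclass(frozen=True)
class SampleTruth:
    condition: FormulationCondition
    transitions: tuple[TransitionTruth, ...]
    aggregation: AggregationTruth
    kd_true: float = 0.0  # mL/mg
    d0_true: float = 4.2e-7  # diffusion units (e.g. cm^2/s)
    sec_fractions_true: tuple[float, float, float] = (2.0, 97.5, 0.5)  # %HMW, %Mono, %LMW
    z_average_nm_true: float = 11.0
    pdi_true: float = 0.05
    qc_flag: bool = False

    def __post_init__(self):
        trs = tuple(sorted(self.transitions, key=lambda tr: tr.tm_true))
        object.__setattr__(self, "transitions", trs)
        if self.d0_true <= 0:
            raise InvalidInputError("d0_true must be positive")
        if abs(sum(self.sec_fractions_true) - 100.0) > 1e-9:
            raise InvalidInputError("sec_fractions_true must sum to 100")
        if any(f < 0 for f in self.sec_fractions_true):
            raise InvalidInputError("sec fractions must be non-negative")

    @property
    def triples(self):
        return [tr.triple for tr in self.transitions]


def default_dsc_grid(step: float = 0.1) -> np.ndarray:
    """Default DSC scan window 20-110 °C."""
    return np.round(np.arange(20.0, 110.0 + step / 2, step), 6)


def default_sls_grid(step: float = 0.1) -> np.ndarray:
    """Default SLS thermal-ramp window 25-90 °C."""
    return np.round(np.arange(25.0, 90.0 + step / 2, step), 6)


def _check_grid(grid):
    grid = np.asarray(grid, dtype=float)
    if grid.ndim != 1 or grid.size < 10:
        raise InvalidInputError("grid must be a 1-D array with >= 10 points")
    if np.any(np.diff(grid) <= 0):
        raise InvalidInputError("grid must be strictly increasing")
    return grid


# ---------------------------------------------------------------------------

def simulate_thermogram(truth: SampleTruth, grid=None, noise_sd: float = 0.0,
                        seed: int | None = None) -> Thermogram:
    """Noisy excess-heat-capacity trace for the designed transitions.

    The noiseless integral over a sufficiently wide grid equals the sum
    of the calorimetric enthalpies.
    """
    grid = _check_grid(default_dsc_grid() if grid is None else grid)
    for tr in truth.transitions:
        if not (grid[0] <= tr.tm_true <= grid[-1]):
            raise ScanDomainError(
                f"transition midpoint {tr.tm_true} °C outside grid "
                f"[{grid[0]}, {grid[-1]}]")
    cp = excess_heat_capacity(grid, truth.triples)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        cp = cp + rng.normal(0.0, noise_sd, size=grid.shape)
    return Thermogram(truth.condition, grid, cp,
                      meta={"truth": truth, "noise_sd": noise_sd})


def _onset_index(truth: SampleTruth, grid: np.ndarray):
    """First grid index where the coupled onset condition holds, or None."""
    f_global = global_unfolded_fraction(grid, truth.triples)
    reactive = [tr for tr in truth.transitions
                if tr.domain_label == truth.aggregation.reactive_domain]
    ok = f_global >= truth.aggregation.reactivity_fraction
    if reactive:
        f_dom = unfolded_fraction(grid, reactive[0].tm_true, reactive[0].dh_vanthoff)
        ok = ok & (f_dom > 0.0)
    idx = np.nonzero(ok)[0]
    return int(idx[0]) if idx.size else None


def simulate_aggregation_trace(truth: SampleTruth, grid=None, noise_cv: float = 0.0,
                               seed: int | None = None) -> AggregationTrace:
    """SLS ramp: flat baseline until the designed unfolded-fraction
    threshold is reached, then exponential growth capped at the
    saturation intensity.  The true onset temperature is annotated in
    ``meta['onset_true']`` (None when unreachable within the grid)."""
    grid = _check_grid(default_sls_grid() if grid is None else grid)
    if not truth.transitions:
        raise InvalidInputError("truth must contain at least one transition")
    agg = truth.aggregation
    i0 = _onset_index(truth, grid)
    intensity = np.full(grid.shape, agg.baseline_kcps, dtype=float)
    onset_true = None
    if i0 is not None:
        onset_true = float(grid[i0])
        growth = agg.baseline_kcps * np.exp(agg.growth_rate * (grid[i0:] - grid[i0]))
        intensity[i0:] = np.minimum(growth, INTENSITY_CAP)
    if noise_cv > 0:
        rng = np.random.default_rng(seed)
        sigma = np.sqrt(np.log1p(noise_cv**2))
        intensity = intensity * rng.lognormal(mean=-sigma**2 / 2, sigma=sigma,
                                              size=grid.shape)
    return AggregationTrace(truth.condition, grid, intensity,
                            meta={"truth": truth, "onset_true": onset_true})


def simulate_dilution_series(truth: SampleTruth, concentrations=(1, 2, 3, 4, 5),
                             noise_sd: float = 0.0,
                             seed: int | None = None) -> DilutionSeries:
    """DLS dilution series: D(c) = D_0 (1 + k_D c) plus Gaussian noise."""
    c = np.asarray(concentrations, dtype=float)
    if np.unique(c).size < 2 or np.any(c <= 0):
        raise InvalidInputError("need >= 2 distinct positive concentrations")
    d = truth.d0_true * (1.0 + truth.kd_true * c)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        d = d + rng.normal(0.0, noise_sd, size=c.shape)
    return DilutionSeries(truth.condition, c, d)


@dataclass(frozen=True)
class SECPeakParams:
    """Elution-peak layout; centers must increase (HMW, Monomer, LMW)."""

    centers_min: tuple[float, float, float] = (7.0, 8.4, 9.8)
    sigma_min: float = 0.12

    def __post_init__(self):
        if not (self.centers_min[0] < self.centers_min[1] < self.centers_min[2]):
            raise InvalidInputError("peak centers must be strictly increasing")


def simulate_chromatogram(truth: SampleTruth, time_grid=None,
                          peaks: SECPeakParams | None = None,
                          noise_sd: float = 0.0,
                          seed: int | None = None) -> SECChromatogram:
    """Three-Gaussian UV-280 chromatogram with areas proportional to the
    designed composition.  Peaks closer than 2 sigma set an 'overlap'
    warning flag in ``meta``."""
    peaks = peaks or SECPeakParams()
    if time_grid is None:
        time_grid = np.round(np.arange(5.0, 12.0 + 0.005, 0.01), 6)
    t = _check_grid(time_grid)
    flags = []
    c = peaks.centers_min
    if min(c[1] - c[0], c[2] - c[1]) < 2.0 * peaks.sigma_min:
        flags.append("overlapping peaks (< 2 sigma apart)")
    y = np.zeros_like(t)
    norm = peaks.sigma_min * np.sqrt(2.0 * np.pi)
    for center, frac in zip(c, truth.sec_fractions_true):
        if frac <= 0:
            continue
        y += (frac / 100.0) / norm * np.exp(-0.5 * ((t - center) / peaks.sigma_min) ** 2)
    if noise_sd > 0:
        rng = np.random.default_rng(seed)
        y = y + rng.normal(0.0, noise_sd, size=t.shape)
    return SECChromatogram(truth.condition, t, y,
                           meta={"truth": truth, "warnings": flags})


# ---------------------------------------------------------------------------
# design helpers

def onset_temperature_for_fraction(truth_transitions: Sequence[TransitionTruth],
                                   fraction: float,
                                   lo: float = 25.0, hi: float = 90.0) -> float:
    """Temperature at which the global unfolded fraction reaches ``fraction``
    (root-finding on the exact two-state model); used when a sample's
    aggregation behaviour is designed in fraction space."""
    triples = [tr.triple for tr in truth_transitions]

    def g(t):
        return float(global_unfolded_fraction(np.array([t]), triples)[0]) - fraction

    if g(lo) >= 0:
        return lo
    if g(hi) <= 0:
        raise ScanDomainError("requested fraction is not reached within the window")
    return float(brentq(g, lo, hi, xtol=1e-6))


@dataclass
class PanelDesign:
    """A screening design: sample conditions plus a truth response function.

    ``truth_fn(mab_id, pH, nacl_mM) -> SampleTruth`` encodes how midpoints,
    aggregation onsets and colloidal parameters respond to formulation;
    monotone responses in pH/salt let panel-level trends be designed.
    """

    mab_ids: Sequence[str]
    ph_values: Sequence[float] = (4.0, 5.0, 6.0, 7.0, 8.0)
    nacl_values: Sequence[float] = (0.0, 50.0, 150.0)
    truth_fn: Callable[[str, float, float], SampleTruth] | None = None

    def conditions(self):
        for mab in self.mab_ids:
            for ph in self.ph_values:
                for nacl in self.nacl_values:
                    yield (mab, ph, nacl)

    @property
    def n_samples(self) -> int:
        return len(list(self.mab_ids)) * len(list(self.ph_values)) * len(list(self.nacl_values))


@dataclass
class SimulatedSample:
    truth: SampleTruth
    thermogram: Thermogram
    aggregation_trace: AggregationTrace
    dilution_series: DilutionSeries
    chromatogram: SECChromatogram

    @property
    def condition(self) -> FormulationCondition:
        return self.truth.condition


@dataclass
class NoiseModel:
    """Per-technique noise defaults for panel simulation."""

    dsc_sd: float = 2.0  # kcal/mol/°C, ~1% of a typical Fab peak
    sls_cv: float = 0.05
    dls_sd_frac: float = 0.005  # fraction of D_0
    sec_sd: float = 0.002  # absorbance units (~0.06% of a typical monomer apex)


def simulate_sample(truth: SampleTruth, noise: NoiseModel | None = None,
                    seed: int | None = None, dsc_step: float = 0.1,
                    sls_step: float = 0.1) -> SimulatedSample:
    noise = noise or NoiseModel()
    ss = np.random.SeedSequence(seed)
    seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(4)]
    return SimulatedSample(
        truth=truth,
        thermogram=simulate_thermogram(truth, default_dsc_grid(dsc_step),
                                       noise.dsc_sd, seeds[0]),
        aggregation_trace=simulate_aggregation_trace(truth, default_sls_grid(sls_step),
                                                     noise.sls_cv, seeds[1]),
        dilution_series=simulate_dilution_series(truth,
                                                 noise_sd=noise.dls_sd_frac * truth.d0_true,
                                                 seed=seeds[2]),
        chromatogram=simulate_chromatogram(truth, noise_sd=noise.sec_sd, seed=seeds[3]),
    )


def make_panel(design: PanelDesign, seed: int = 0,
               noise: NoiseModel | None = None) -> list[SimulatedSample]:
    """Simulate every sample of a design, reproducibly for a fixed seed."""
    if design.truth_fn is None:
        raise InvalidInputError("design must provide a truth_fn")
    conditions = list(design.conditions())
    if not conditions:
        raise InvalidInputError("design is empty")
    ss = np.random.SeedSequence(seed)
    child_seeds = [int(s.generate_state(1)[0] % (2**31)) for s in ss.spawn(len(conditions))]
    panel = []
    for (mab, ph, nacl), s in zip(conditions, child_seeds):
        truth = design.truth_fn(mab, ph, nacl)
        panel.append(simulate_sample(truth, noise=noise, seed=s))
    return panel
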