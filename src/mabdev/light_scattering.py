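"""Light-scattering analysis.

Two measurement modes feed developability screening:

* DLS dilution series -> diffusion interaction parameter k_D.  The model
  is D(c) = D_0 (1 + k_D c); ordinary least squares of D on c gives
  D_0 as the intercept and k_D as slope/intercept.  Positive k_D means
  net repulsive protein-protein interactions.
* SLS thermal ramps -> aggregation onset temperatures.  T_agg_1 is the
  earliest detectable sign of aggregation (a sustained excursion above
  the baseline noise band); T_agg_2 is the temperature at which the
  scattered intensity crosses a fixed fast-aggregation threshold
  (3,000 kcps by default, an instrument-specific convention).
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np

from .conditions import FormulationCondition
from .errors import InvalidInputError

__all__ = [
    "DilutionSeries",
    "KDResult",
    "AggregationTrace",
    "AggregationDetectionParams",
    "AggregationResult",
    "SizeSummary",
    "fit_kd",
    "detect_tagg1",
    "detect_tagg2",
    "detect_aggregation",
]


@dataclass
class DilutionSeries:
    condition: FormulationCondition
    concentration: np.ndarray  # mg/mL
    diffusion: np.ndarray  # same length; any consistent diffusion unit

    def __post_init__(self):
        self.concentration = np.asarray(self.concentration, dtype=float)
        self.diffusion = np.asarray(self.diffusion, dtype=float)
        if self.concentration.shape != self.diffusion.shape:
            raise InvalidInputError("concentration and diffusion must have equal length")
        if np.any(self.concentration <= 0):
            raise InvalidInputError("all concentrations must be positive")
        if np.unique(self.concentration).size < 2:
            raise InvalidInputError("need at least 2 distinct concentrations")


@dataclass
class KDResult:
    kd: float  # mL/mg
    d0: float  # diffusion units (intercept)
    kd_se: float  # standard error of k_D via the delta method


@dataclass
class AggregationTrace:
    condition: FormulationCondition
    temperature: np.ndarray  # °C, increasing
    intensity: np.ndarray  # kcps
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.intensity = np.asarray(self.intensity, dtype=float)
        if self.temperature.shape != self.intensity.shape:
            raise InvalidInputError("temperature and intensity must have equal length")
        if np.any(self.intensity < 0):
            raise InvalidInputError("intensity must be non-negative")


@dataclass
class AggregationDetectionParams:
    tagg2_threshold: float = 3000.0  # kcps; instrument-setup specific
    onset_k_sigma: float = 5.0
    baseline_window: float = 10.0  # °C from scan start
    run_length: int = 10
    backtrack_k_sigma: float = 3.0  # departure band, in smoothed-baseline SDs

    def __post_init__(self):
        if self.tagg2_threshold <= 0:
            raise InvalidInputError("tagg2_threshold must be positive")


@dataclass
class AggregationResult:
    tagg1: float | None
    tagg2: float | None
    tagg2_flag: str = ""  # e.g. "pre-aggregated"


@dataclass
class SizeSummary:
    """Instrument-software DLS summary carried through as input."""

    z_average_nm: float
    pdi: float

    def __post_init__(self):
        if self.z_average_nm <= 0:
            raise InvalidInputError("z_average_nm must be positive")
        if not (0.0 <= self.pdi <= 1.0):
            raise InvalidInputError("pdi must lie in [0, 1]")


# ---------------------------------------------------------------------------

def fit_kd(series: DilutionSeries) -> KDResult:
    """Least-squares fit of D(c) = D_0 (1 + k_D c).

    k_D = slope / intercept; its standard error comes from first-order
    (delta-method) propagation of the OLS covariance of (intercept, slope).
    """
    c, d = series.concentration, series.diffusion
    n = c.size
    X = np.column_stack([np.ones(n), c])
    coef, res_ss, *_ = np.linalg.lstsq(X, d, rcond=None)
    a, b = coef  # intercept, slope
    if a <= 0:
        raise InvalidInputError("nonphysical D_0: intercept <= 0")
    kd = b / a
    if n > 2:
        resid = d - X @ coef
        sigma2 = float(resid @ resid) / (n - 2)
        cov = sigma2 * np.linalg.inv(X.T @ X)
        var_kd = (cov[1, 1] / a**2 + b**2 * cov[0, 0] / a**4
                  - 2.0 * b * cov[0, 1] / a**3)
        kd_se = float(np.sqrt(max(var_kd, 0.0)))
    else:
        warnings.warn("two-point fit: k_D standard error undefined, reported as 0")
        kd_se = 0.0
    return KDResult(kd=float(kd), d0=float(a), kd_se=kd_se)


def _baseline_stats(trace: AggregationTrace, params: AggregationDetectionParams):
    t = trace.temperature
    mask = t <= t[0] + params.baseline_window
    base = trace.intensity[mask]
    mu, sd = float(base.mean()), float(base.std())
    if sd == 0.0:
        if mu == 0.0:
            warnings.warn("flat zero baseline; using 1 kcps as noise stand-in")
            sd = 1.0
        else:
            sd = max(1e-6 * mu, 1e-12)
    return mu, sd, int(mask.sum())


def detect_tagg1(trace: AggregationTrace,
                 params: AggregationDetectionParams | None = None) -> float | None:
    """Earliest detectable sign of aggregation.

    Detection is two-stage: a sustained excursion (smoothed intensity
    above baseline mean + k_sigma * baseline SD for ``run_length``
    consecutive points) confirms that aggregation happened, and the
    onset is then dated by walking back from the confirmed run to the
    start of the contiguous stretch in which the smoothed signal sits
    above the departure band (baseline mean + ``backtrack_k_sigma``
    smoothed-baseline SDs).  The confirm-then-backdate split keeps the
    detector robust to spikes without biasing the onset late.  Returns
    None if the trace never leaves the noise band; the criterion is
    invariant to rescaling the whole trace by a positive constant.
    """
    params = params or AggregationDetectionParams()
    if trace.temperature.size < params.run_length:
        raise InvalidInputError("trace shorter than run_length")
    mu, sd, _ = _baseline_stats(trace, params)
    y = trace.intensity
    if y.size >= 5:  # 5-point moving average knocks down spikes
        kernel = np.ones(5) / 5.0
        smooth = np.convolve(y, kernel, mode="same")
    else:
        smooth = y
    thr = mu + params.onset_k_sigma * sd
    above = smooth > thr
    count = 0
    run_start = None
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= params.run_length:
            run_start = i - params.run_length + 1
            break
    if run_start is None:
        return None
    # backdate to where the smoothed signal first left the baseline band
    base_mask = trace.temperature <= trace.temperature[0] + params.baseline_window
    sd_s = float(smooth[base_mask].std())
    sd_s = sd_s if sd_s > 0 else sd
    depart = mu + params.backtrack_k_sigma * sd_s
    j = run_start
    while j > 0 and smooth[j - 1] > depart:
        j -= 1
    t = trace.temperature
    if 0 < j and smooth[j] > depart > smooth[j - 1]:
        # sub-grid departure by linear interpolation of the smoothed signal
        frac = (depart - smooth[j - 1]) / (smooth[j] - smooth[j - 1])
        return float(t[j - 1] + frac * (t[j] - t[j - 1]))
    return float(t[j])


def detect_tagg2(trace: AggregationTrace,
                 params: AggregationDetectionParams | None = None) -> float | None:
    """Fast-aggregation temperature: first upward crossing of the fixed
    intensity threshold, linearly interpolated between the bracketing
    samples so the answer does not depend on grid resolution."""
    params = params or AggregationDetectionParams()
    t, y = trace.temperature, trace.intensity
    thr = params.tagg2_threshold
    if y[0] >= thr:
        raise InvalidInputError("pre-aggregated sample: trace starts above threshold")
    idx = np.nonzero((y[:-1] < thr) & (y[1:] >= thr))[0]
    if idx.size == 0:
        return None
    i = int(idx[0])
    frac = (thr - y[i]) / (y[i + 1] - y[i])
    return float(t[i] + frac * (t[i + 1] - t[i]))


def detect_aggregation(trace: AggregationTrace,
                       params: AggregationDetectionParams | None = None) -> AggregationResult:
    params = params or AggregationDetectionParams()
    tagg1 = detect_tagg1(trace, params)
    flag = ""
    try:
        tagg2 = detect_tagg2(trace, params)
    except InvalidInputError:
        tagg2, flag = None, "pre-aggregated"
    return AggregationResult(tagg1=tagg1, tagg2=tagg2, tagg2_flag=flag)
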