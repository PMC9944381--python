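"""DSC thermogram analysis.

Baseline handling, multi-transition deconvolution, onset-of-unfolding
(T_onset) extraction, structural domain assignment and the cumulative
fraction-unfolded curve used by the aggregation-overlay workflow.

Domain assignment follows the convention used for IgG thermograms:
the Fab region is the peak with the largest calorimetric area, and of
the remaining peaks the C_H2 domain is the one with the lowest midpoint;
a third peak, where present, is C_H3.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field, replace

import numpy as np
from scipy.integrate import cumulative_trapezoid, trapezoid
from scipy.optimize import least_squares
from scipy.signal import find_peaks, savgol_filter

from .conditions import FormulationCondition
from .constants import dhvh_from_width, width_from_dhvh
from .errors import FitConvergenceError, InvalidInputError, NoSignalError
from .thermo import dfraction_dT, unfolded_fraction

__all__ = [
    "Thermogram",
    "UnfoldingTransition",
    "FractionUnfoldedCurve",
    "DSCResult",
    "subtract_baseline",
    "deconvolve_transitions",
    "choose_n_transitions",
    "compute_tonset",
    "assign_domains",
    "fraction_unfolded_curve",
    "fraction_unfolded_from_fit",
    "analyze_thermogram",
]


@dataclass
class Thermogram:
    """A thermal unfolding profile: excess heat capacity vs temperature."""

    condition: FormulationCondition
    temperature: np.ndarray  # °C, strictly increasing
    cp_excess: np.ndarray  # kcal/mol/°C
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.temperature = np.asarray(self.temperature, dtype=float)
        self.cp_excess = np.asarray(self.cp_excess, dtype=float)
        if self.temperature.shape != self.cp_excess.shape:
            raise InvalidInputError("temperature and cp_excess must have equal length")
        if self.temperature.size < 10:
            raise InvalidInputError("thermogram needs at least 10 points")
        if np.any(np.diff(self.temperature) <= 0):
            raise InvalidInputError("temperature grid must be strictly increasing")


@dataclass
class UnfoldingTransition:
    """A fitted two-state unfolding transition.

    ``width`` is the full width at half maximum of the excess-heat-capacity
    peak; it maps one-to-one onto the van't Hoff enthalpy at fixed ``tm``.
    """

    tm: float  # °C
    area: float  # kcal/mol (calorimetric enthalpy)
    width: float  # °C (FWHM)
    domain: str = "unassigned"  # Fab | CH2 | CH3 | unassigned

    @property
    def dhvh(self) -> float:
        return dhvh_from_width(self.tm, self.width)


class FractionUnfoldedCurve:
    """Tabulated monotone mapping temperature -> fraction unfolded in [0, 1]."""

    def __init__(self, temperature, fraction):
        self.temperature = np.asarray(temperature, dtype=float)
        self.fraction = np.asarray(fraction, dtype=float)

    def __call__(self, t):
        return np.interp(t, self.temperature, self.fraction)


@dataclass
class DSCResult:
    condition: FormulationCondition
    tonset: float
    transitions: list[UnfoldingTransition]
    fraction_unfolded: FractionUnfoldedCurve
    fit_residual: float
    warnings_: list[str] = field(default_factory=list)

    def tm_by_domain(self, domain: str):
        for tr in self.transitions:
            if tr.domain == domain:
                return tr.tm
        return None

    @property
    def tm_fab(self):
        return self.tm_by_domain("Fab")

    def tm_sorted(self):
        return sorted(tr.tm for tr in self.transitions)


# ---------------------------------------------------------------------------
# baseline

def subtract_baseline(raw: Thermogram, window_low: float = 8.0, window_high: float = 8.0) -> Thermogram:
    """Remove an affine baseline anchored in transition-free end windows.

    A straight line fitted by least squares over the first ``window_low``
    °C and the last ``window_high`` °C of the scan jointly is subtracted
    (pooling both windows minimises the slope/offset error that would
    otherwise accumulate through the running integral).  If either window
    shows appreciable slope (signal leaking into the anchor region) a
    warning flag is set on the returned thermogram.
    """
    t, y = raw.temperature, raw.cp_excess
    lo_mask = t <= t[0] + window_low
    hi_mask = t >= t[-1] - window_high
    if lo_mask.sum() < 5 or hi_mask.sum() < 5:
        raise InvalidInputError("baseline windows must contain at least 5 points")

    anchor = lo_mask | hi_mask
    slope, intercept = np.polyfit(t[anchor], y[anchor], 1)
    baseline = intercept + slope * t

    flags = list(raw.meta.get("warnings", []))
    span = np.ptp(y) if np.ptp(y) > 0 else 1.0
    resid = y - baseline
    for name, mask in (("low", lo_mask), ("high", hi_mask)):
        if np.max(np.abs(resid[mask])) > 0.05 * span:
            msg = f"baseline window '{name}' overlaps transition signal"
            warnings.warn(msg)
            flags.append(msg)
    meta = dict(raw.meta)
    meta["warnings"] = flags
    meta["baseline_subtracted"] = True
    return Thermogram(raw.condition, t, y - baseline, meta)


# ---------------------------------------------------------------------------
# deconvolution

def _model_cp(t, params):
    """params: flat array [tm1, area1, dhvh1, tm2, ...]."""
    cp = np.zeros_like(t)
    for i in range(0, len(params), 3):
        tm, area, dhvh = params[i : i + 3]
        cp += area * dfraction_dT(t, tm, dhvh)
    return cp


def _initial_guesses(t, y, n):
    """Peak-pick based starting points; returns a list of parameter vectors."""
    span = max(np.max(y), 1e-12)
    win = max(5, min(31, (len(t) // 20) * 2 + 1))
    smooth = savgol_filter(y, win, 3) if len(y) >= win else y
    peaks, props = find_peaks(smooth, prominence=0.02 * span)
    order = np.argsort(props["prominences"])[::-1] if len(peaks) else np.array([], int)
    picked = sorted(t[peaks[order[:n]]]) if len(peaks) else []
    total_area = max(trapezoid(np.clip(y, 0, None), t), 1e-9)

    def build(tms):
        params = []
        for tm in tms:
            params.extend([tm, total_area / n, 500.0])
        return np.array(params)

    starts = []
    if len(picked) == n:
        starts.append(build(picked))
        starts.append(build([tm + 1.0 for tm in picked]))
        starts.append(build([tm - 1.0 for tm in picked]))
    else:
        # fall back to spreading midpoints over the occupied scan region
        w = np.clip(y, 0, None) + 1e-12
        tbar = np.sum(t * w) / np.sum(w)
        sd = np.sqrt(np.sum((t - tbar) ** 2 * w) / np.sum(w))
        grid = np.linspace(tbar - sd, tbar + sd, n) if n > 1 else np.array([tbar])
        starts.append(build(list(grid)))
        for tm in picked:
            alt = sorted(set(list(grid[: n - len(picked)]) + picked))
            if len(alt) == n:
                starts.append(build(alt))
                break
    return starts


def _resolve_degenerate(t, y, best, lo, hi):
    """Prefer the parsimonious representation when two fitted components
    coincide (midpoints closer than half a peak width): merge them and
    park a near-zero component at the scan edge, keeping the merge only
    if it fits at least as well after a polish."""
    from scipy.optimize import least_squares as _ls

    params = best.x.reshape(-1, 3)
    if len(params) < 2:
        return best
    order = np.argsort(params[:, 0])
    params = params[order]
    merged = False
    for i in range(len(params) - 1):
        tm1, a1, v1 = params[i]
        tm2, a2, v2 = params[i + 1]
        half_width = 0.5 * max(width_from_dhvh(tm1, v1), width_from_dhvh(tm2, v2))
        if a1 > 0 and a2 > 0 and abs(tm2 - tm1) < half_width:
            w = a1 + a2
            params[i] = [(tm1 * a1 + tm2 * a2) / w, w, (v1 * a1 + v2 * a2) / w]
            params[i + 1] = [t[0], 1e-3, 500.0]
            merged = True
    if not merged:
        return best
    x0 = np.clip(params.ravel(), lo, hi)
    res = _ls(lambda p: _model_cp(t, p) - y, x0, bounds=(lo, hi),
              method="trf", xtol=1e-10, ftol=1e-10, max_nfev=800)
    # the parked component cannot reach exactly zero area, so allow a
    # signal-energy-relative slack when comparing fits
    tol = 1e-6 * (0.5 * float(np.sum(y * y)) + 1.0)
    return res if res.cost <= best.cost + tol else best


def deconvolve_transitions(tg: Thermogram, n_transitions: int, init=None):
    """Fit a sum of ``n_transitions`` two-state peaks by bounded least squares.

    Multi-start (peak-pick plus perturbed copies) protects against local
    minima.  Returns ``(transitions_sorted_by_tm, fit_residual_rms)``.
    """
    if n_transitions not in (1, 2, 3):
        raise InvalidInputError("n_transitions must be 1, 2 or 3")
    t, y = tg.temperature, tg.cp_excess

    if init is not None:
        starts = [np.asarray(init, dtype=float)]
    else:
        starts = _initial_guesses(t, y, n_transitions)

    lo = np.tile([t[0], 1e-3, 30.0], n_transitions)
    hi = np.tile([t[-1], 1e5, 5000.0], n_transitions)

    best = None
    for x0 in starts:
        x0 = np.clip(x0, lo, hi)
        try:
            res = least_squares(
                lambda p: _model_cp(t, p) - y, x0, bounds=(lo, hi),
                method="trf", xtol=1e-10, ftol=1e-10, max_nfev=800,
            )
        except Exception:  # pragma: no cover - defensive
            continue
        if best is None or res.cost < best.cost:
            best = res
    if best is None:
        raise FitConvergenceError("deconvolution failed for every start")

    best = _resolve_degenerate(t, y, best, lo, hi)
    rms = float(np.sqrt(np.mean((_model_cp(t, best.x) - y) ** 2)))
    transitions = []
    for i in range(0, len(best.x), 3):
        tm, area, dhvh = best.x[i : i + 3]
        transitions.append(UnfoldingTransition(tm=float(tm), area=float(area),
                                               width=width_from_dhvh(float(tm), float(dhvh))))
    transitions.sort(key=lambda tr: tr.tm)
    # iteration exhaustion (status 0) still yields the best-so-far fit,
    # which is what model selection needs; only invalid runs are fatal
    if best.status < 0:
        raise FitConvergenceError("deconvolution did not converge",
                                  best=transitions, residual=rms)
    return transitions, rms


def choose_n_transitions(tg: Thermogram, max_n: int = 3, improvement: float = 0.10):
    """Fit n = 1..max_n and keep the smallest n beyond which the RMS residual
    improves by less than ``improvement`` (fractional).  Guards against
    fitting shoulders that are only noise."""
    fits = {}
    chosen = 1
    prev_rms = None
    for n in range(1, max_n + 1):
        fits[n] = deconvolve_transitions(tg, n)
        rms = fits[n][1]
        if prev_rms is not None and rms > (1.0 - improvement) * prev_rms:
            break
        chosen = n
        prev_rms = rms
    return fits[chosen]


# ---------------------------------------------------------------------------
# onset, domains, fraction unfolded

def compute_tonset(tg: Thermogram, fit, threshold_frac: float = 0.05,
                   run_length: int = 10) -> float:
    """Onset of unfolding: the lowest temperature at which the smoothed,
    baseline-subtracted signal exceeds ``threshold_frac`` of its global
    maximum for at least ``run_length`` consecutive grid points.

    The definition is monotone in the threshold: lowering ``threshold_frac``
    can only move the onset to lower temperature.
    """
    if not fit:
        raise InvalidInputError("compute_tonset requires a non-empty fit")
    t, y = tg.temperature, tg.cp_excess
    win = max(5, min(21, (len(y) // 30) * 2 + 1))
    smooth = savgol_filter(y, win, 3) if len(y) >= win else y
    thr = threshold_frac * np.max(smooth)
    above = smooth > thr
    # first index opening a run of run_length consecutive True
    count = 0
    for i, a in enumerate(above):
        count = count + 1 if a else 0
        if count >= run_length:
            return float(t[i - run_length + 1])
    raise NoSignalError("no transition detected above threshold")


def assign_domains(transitions) -> list[UnfoldingTransition]:
    """Label transitions with antibody domains.

    Largest calorimetric area -> Fab; of the remaining peaks the lowest
    midpoint -> CH2; a further peak -> CH3.  Ties on area (within 1e-9)
    break toward the lower midpoint with a warning.  Input order is kept.
    """
    trs = list(transitions)
    if not 1 <= len(trs) <= 3:
        raise InvalidInputError("assign_domains expects 1-3 transitions")
    if any(tr.area <= 0 for tr in trs):
        raise InvalidInputError("transition areas must be positive")

    max_area = max(tr.area for tr in trs)
    candidates = [i for i, tr in enumerate(trs) if abs(tr.area - max_area) <= 1e-9]
    if len(candidates) > 1:
        warnings.warn("tie in largest transition area; assigning Fab to the lower midpoint")
        candidates.sort(key=lambda i: trs[i].tm)
    fab_i = candidates[0]

    rest = [i for i in range(len(trs)) if i != fab_i]
    labels = {fab_i: "Fab"}
    if rest:
        ch2_i = min(rest, key=lambda i: trs[i].tm)
        labels[ch2_i] = "CH2"
        for i in rest:
            if i != ch2_i:
                labels[i] = "CH3"
    return [replace(tr, domain=labels[i]) for i, tr in enumerate(trs)]


def fraction_unfolded_curve(tg: Thermogram) -> FractionUnfoldedCurve:
    """Calorimetric fraction-unfolded curve.

    The running integral of the baseline-subtracted excess heat capacity,
    normalised by the total integral; clipped into [0, 1] and forced
    non-decreasing to absorb numerical noise.
    """
    t, y = tg.temperature, tg.cp_excess
    total = trapezoid(y, t)
    if total <= 0:
        raise NoSignalError("no unfolding signal: total integral <= 0")
    cum = cumulative_trapezoid(y, t, initial=0.0) / total
    cum = np.clip(cum, 0.0, 1.0)
    cum = np.maximum.accumulate(cum)
    return FractionUnfoldedCurve(t, cum)


def fraction_unfolded_from_fit(tg: Thermogram, transitions) -> FractionUnfoldedCurve:
    """Alternative population-based curve from the fitted transitions
    (area-weighted sum of two-state populations)."""
    t = tg.temperature
    total = sum(tr.area for tr in transitions)
    f = np.zeros_like(t)
    for tr in transitions:
        f += (tr.area / total) * unfolded_fraction(t, tr.tm, tr.dhvh)
    return FractionUnfoldedCurve(t, np.clip(f, 0.0, 1.0))


# ---------------------------------------------------------------------------
# convenience driver

def analyze_thermogram(raw: Thermogram, n_transitions: int | None = None,
                       threshold_frac: float = 0.05,
                       baseline: bool = True) -> DSCResult:
    """Full single-thermogram analysis used by the batch pipeline."""
    tg = subtract_baseline(raw) if baseline else raw
    if n_transitions is None:
        transitions, rms = choose_n_transitions(tg)
    else:
        transitions, rms = deconvolve_transitions(tg, n_transitions)
    transitions = assign_domains(transitions)
    tonset = compute_tonset(tg, transitions, threshold_frac=threshold_frac)
    curve = fraction_unfolded_curve(tg)
    return DSCResult(
        condition=raw.condition,
        tonset=tonset,
        transitions=transitions,
        fraction_unfolded=curve,
        fit_residual=rms,
        warnings_=list(tg.meta.get("warnings", [])),
    )
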