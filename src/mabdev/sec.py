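"""SEC chromatogram integration.

Computes the percent area of Monomer, High Molecular Weight (HMW,
aggregates, eluting earlier) and Low Molecular Weight (LMW, fragments,
eluting later) species from a UV-280 chromatogram.  Peak boundaries are
drawn at the valley minima between detected apexes (the standard
drop-line convention); the largest-area peak is taken as the Monomer.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
from scipy.integrate import trapezoid
from scipy.signal import find_peaks

from .conditions import FormulationCondition
from .errors import InvalidInputError, NoSignalError

__all__ = ["SECChromatogram", "SECComposition", "integrate_composition"]


@dataclass
class SECChromatogram:
    condition: FormulationCondition
    time: np.ndarray  # minutes, strictly increasing
    a280: np.ndarray  # absorbance units
    meta: dict = field(default_factory=dict)

    def __post_init__(self):
        self.time = np.asarray(self.time, dtype=float)
        self.a280 = np.asarray(self.a280, dtype=float)
        if self.time.shape != self.a280.shape:
            raise InvalidInputError("time and a280 must have equal length")
        if np.any(np.diff(self.time) <= 0):
            raise InvalidInputError("time grid must be strictly increasing")


@dataclass
class SECComposition:
    pct_hmw: float
    pct_monomer: float
    pct_lmw: float

    def as_tuple(self):
        return (self.pct_hmw, self.pct_monomer, self.pct_lmw)


def _subtract_linear_baseline(time, signal, edge_frac=0.05):
    n = len(time)
    k = max(3, int(edge_frac * n))
    x0, y0 = time[:k].mean(), signal[:k].mean()
    x1, y1 = time[-k:].mean(), signal[-k:].mean()
    slope = (y1 - y0) / (x1 - x0)
    return signal - (y0 + slope * (time - x0))


def integrate_composition(ch: SECChromatogram, min_peak_frac: float = 0.005) -> SECComposition:
    """Percent HMW / Monomer / LMW by valley-to-valley trapezoid integration.

    Peaks below ``min_peak_frac`` of the maximum signal are ignored.
    Percentages are taken over the total integrated peak area and sum to
    100; they are invariant to uniform rescaling of the absorbance.
    """
    t = ch.time
    y = _subtract_linear_baseline(t, ch.a280)
    ymax = float(np.max(y))
    if ymax <= 0:
        raise NoSignalError("empty chromatogram")
    apexes, _ = find_peaks(y, height=min_peak_frac * ymax,
                           prominence=min_peak_frac * ymax)
    if apexes.size == 0:
        raise NoSignalError("empty chromatogram: no peak above min_peak_frac")

    # segment boundaries: trace ends plus valley minima between apexes
    bounds = [0]
    for left, right in zip(apexes[:-1], apexes[1:]):
        bounds.append(left + int(np.argmin(y[left:right + 1])))
    bounds.append(len(y) - 1)

    # signed integration lets zero-mean noise cancel; only a net-negative
    # segment area (pathological baseline) is clipped
    areas = np.array([trapezoid(y[b0:b1 + 1], t[b0:b1 + 1])
                      for b0, b1 in zip(bounds[:-1], bounds[1:])])
    if np.any(areas < 0):
        warnings.warn("negative peak area after baseline subtraction; clipping to 0")
        areas = np.clip(areas, 0.0, None)
    total = areas.sum()
    if total <= 0:
        raise NoSignalError("empty chromatogram: zero integrated area")

    monomer_idx = int(np.argmax(areas))
    near_ties = np.nonzero(np.isclose(areas, areas[monomer_idx], rtol=1e-9, atol=0))[0]
    if near_ties.size > 1:
        warnings.warn("tie in largest peak area; choosing the peak nearest the median elution time")
        med = np.median(t[apexes])
        monomer_idx = int(min(near_ties, key=lambda i: abs(t[apexes[i]] - med)))

    pct = 100.0 * areas / total
    hmw = float(pct[:monomer_idx].sum())
    mono = float(pct[monomer_idx])
    lmw = float(pct[monomer_idx + 1:].sum())
    # close the composition exactly
    mono = 100.0 - hmw - lmw
    return SECComposition(pct_hmw=hmw, pct_monomer=mono, pct_lmw=lmw)
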