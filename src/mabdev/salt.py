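"""Salt-effect liability mapping (colloidal vs conformational stability).

For each (mAb, pH) the workflow compares a low-salt and a high-salt
formulation (0 vs 150 mM NaCl by default):

* dT_agg_2 = T_agg_2(low salt) - T_agg_2(high salt).  Negative values
  mean salt *raises* the fast-aggregation temperature, the signature of
  electrostatic attraction screened by ions — a colloidal liability.
* dT_m is the magnitude of the salt-induced midpoint shift (by default
  the maximum absolute shift across matched transitions).  Large shifts
  indicate a flexible structure easily perturbed by its environment — a
  conformational liability above the (arbitrary, configurable) 3 °C
  threshold.

The two axes split samples into a four-quadrant red/amber/green map:
red = both liabilities, amber = exactly one, green = none.  Threshold
comparisons are strict, so a sample sitting exactly on a border counts
as non-liable.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import pandas as pd

from .dsc import DSCResult
from .errors import InvalidInputError
from .light_scattering import AggregationResult

__all__ = [
    "SaltPair",
    "LiabilityThresholds",
    "SaltEffectResult",
    "compute_delta_tagg2",
    "compute_delta_tm",
    "classify_liability",
    "evaluate_salt_pair",
    "build_salt_map",
]


@dataclass
class SaltPair:
    """Matched low/high-salt measurements of one antibody at one pH."""

    mab_id: str
    pH: float
    low: tuple[DSCResult, AggregationResult]  # 0 mM NaCl
    high: tuple[DSCResult, AggregationResult]  # 150 mM NaCl

    def __post_init__(self):
        c_lo, c_hi = self.low[0].condition, self.high[0].condition
        if c_lo.mab_id != c_hi.mab_id or c_lo.pH != c_hi.pH:
            raise InvalidInputError("pair members must share mAb and pH")
        if c_lo.nacl_mM == c_hi.nacl_mM:
            raise InvalidInputError("pair members must differ in NaCl concentration")


@dataclass
class LiabilityThresholds:
    dtm_threshold: float = 3.0  # °C
    dtagg2_threshold: float = 0.0  # °C

    def __post_init__(self):
        if self.dtm_threshold <= 0:
            raise InvalidInputError("dtm_threshold must be positive")


@dataclass
class SaltEffectResult:
    mab_id: str
    pH: float
    dtm: float
    dtagg2: float  # NaN when incomplete
    colloidal_liability: bool
    conformational_liability: bool
    rag: str  # red | amber | green
    incomplete: bool = False


def compute_delta_tagg2(pair: SaltPair) -> float:
    """T_agg_2(low salt) minus T_agg_2(high salt); antisymmetric under
    swapping the pair members.  NaN (flagged) when either condition has
    no detected fast aggregation."""
    t_lo, t_hi = pair.low[1].tagg2, pair.high[1].tagg2
    if t_lo is None or t_hi is None:
        return float("nan")
    return float(t_lo - t_hi)


def _matched_shifts(pair: SaltPair):
    lo, hi = pair.low[0].transitions, pair.high[0].transitions
    by_domain_lo = {tr.domain: tr for tr in lo if tr.domain != "unassigned"}
    by_domain_hi = {tr.domain: tr for tr in hi if tr.domain != "unassigned"}
    common = [d for d in by_domain_lo if d in by_domain_hi]
    if common and len(common) == max(len(lo), len(hi)):
        return {d: by_domain_lo[d].tm - by_domain_hi[d].tm for d in common}
    warnings.warn("transition sets not fully matched by domain; matching by rank")
    n = min(len(lo), len(hi))
    lo_sorted = sorted(lo, key=lambda tr: tr.tm)
    hi_sorted = sorted(hi, key=lambda tr: tr.tm)
    return {f"rank{i+1}": lo_sorted[i].tm - hi_sorted[i].tm for i in range(n)}


def compute_delta_tm(pair: SaltPair, mode: str = "max_abs_shift",
                     domain: str | None = None) -> float:
    """Salt effect on the unfolding midpoints.

    ``max_abs_shift`` (default): maximum absolute shift across matched
    transitions — a 2.4 °C C_H2 shift co-existing with a 4.2 °C shift of
    another domain reads as 4.2 °C.  ``per_domain`` returns the signed
    magnitude for one requested domain; ``first_transition`` uses the
    lowest-midpoint transition.
    """
    if not pair.low[0].transitions or not pair.high[0].transitions:
        raise InvalidInputError("both pair members need at least one transition")
    shifts = _matched_shifts(pair)
    if mode == "max_abs_shift":
        return float(max(abs(v) for v in shifts.values()))
    if mode == "per_domain":
        if domain is None or domain not in shifts:
            raise InvalidInputError(f"domain {domain!r} not present in matched shifts")
        return float(abs(shifts[domain]))
    if mode == "first_transition":
        lo1 = min(pair.low[0].transitions, key=lambda tr: tr.tm)
        hi1 = min(pair.high[0].transitions, key=lambda tr: tr.tm)
        return float(abs(lo1.tm - hi1.tm))
    raise InvalidInputError(f"unknown mode {mode!r}")


def classify_liability(dtm: float, dtagg2: float,
                       thresholds: LiabilityThresholds | None = None,
                       mab_id: str = "", pH: float = 6.0) -> SaltEffectResult:
    """Four-quadrant red/amber/green call from the two salt-effect axes."""
    thresholds = thresholds or LiabilityThresholds()
    incomplete = bool(np.isnan(dtagg2))
    colloidal = bool(dtagg2 < thresholds.dtagg2_threshold) if not incomplete else False
    conformational = bool(dtm > thresholds.dtm_threshold)
    if colloidal and conformational:
        rag = "red"
    elif colloidal or conformational:
        rag = "amber"
    else:
        rag = "green"
    return SaltEffectResult(mab_id=mab_id, pH=pH, dtm=float(dtm), dtagg2=float(dtagg2),
                            colloidal_liability=colloidal,
                            conformational_liability=conformational,
                            rag=rag, incomplete=incomplete)


def evaluate_salt_pair(pair: SaltPair, thresholds: LiabilityThresholds | None = None,
                       dtm_mode: str = "max_abs_shift") -> SaltEffectResult:
    dtm = compute_delta_tm(pair, mode=dtm_mode)
    dtagg2 = compute_delta_tagg2(pair)
    return classify_liability(dtm, dtagg2, thresholds, mab_id=pair.mab_id, pH=pair.pH)


def build_salt_map(results: list[SaltEffectResult]) -> pd.DataFrame:
    """Plot-ready salt-effect table (X = dT_agg_2, Y = dT_m, colour = RAG).

    Incomplete pairs (missing T_agg_2) are excluded from the map and
    flagged in the returned table's attrs, together with quadrant counts.
    """
    if not results:
        raise InvalidInputError("empty result list")
    df = pd.DataFrame([dict(mab_id=r.mab_id, pH=r.pH, dtagg2_C=r.dtagg2,
                            dtm_C=r.dtm, rag=r.rag, incomplete=r.incomplete)
                       for r in results])
    plotted = df[~df["incomplete"]].copy()
    counts = {rag: int((plotted["rag"] == rag).sum()) for rag in ("red", "amber", "green")}
    plotted.attrs["quadrant_counts"] = counts
    plotted.attrs["n_excluded_incomplete"] = int(df["incomplete"].sum())
    return plotted
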