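"""DSC + SLS overlay analysis (site-specific aggregation propensity).

Combines a sample's thermal unfolding profile with its thermal
aggregation profile to extract three developability attributes:

* T_m(Fab) — overall conformational stability;
* the fraction of globally unfolded protein at the temperature where
  aggregation is first detected — small values flag a highly reactive
  aggregation-prone region that is exposed early in unfolding;
* the structural domain whose unfolding coincides with the aggregation
  onset — identifies where the aggregation-prone region sits.

Panel-level summaries reproduce the scatter ("fraction unfolded vs
T_m(Fab)") and the grouped box-plot statistics, including the averaged
midpoint feature transformation that normalises the strongly stratified
per-molecule T_m(Fab) distributions.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd

from .conditions import FormulationCondition
from .dsc import DSCResult
from .errors import InvalidInputError, ScanDomainError
from .light_scattering import AggregationResult
from .thermo import dfraction_dT

__all__ = [
    "OverlayResult",
    "PanelSummary",
    "overlay_sample",
    "average_tm_transform",
    "build_panel_summary",
    "band_share",
]


@dataclass
class OverlayResult:
    condition: FormulationCondition
    tm_fab: float
    frac_unfolded_at_onset: float | None
    coinciding_domain: str  # Fab | CH2 | CH3 | none
    tagg_used: float | None
    used_tagg2_fallback: bool = False


@dataclass
class PanelSummary:
    table: pd.DataFrame  # one row per sample
    group_stats: pd.DataFrame  # quartiles/mean/SD per grouping
    domain_share: pd.DataFrame  # share of onsets per coinciding domain

    def share(self, domain: str) -> float:
        row = self.domain_share[self.domain_share["domain"] == domain]
        return float(row["share_pct"].iloc[0]) if len(row) else 0.0


def _coinciding_domain(dsc: DSCResult, t: float) -> str:
    """Domain of the fitted transition with the largest excess-heat-capacity
    contribution at temperature ``t`` (robust when peaks overlap)."""
    best, best_val = "none", -np.inf
    for tr in dsc.transitions:
        val = tr.area * float(dfraction_dT(np.array([t]), tr.tm, tr.dhvh)[0])
        if val > best_val:
            best, best_val = tr.domain, val
    return best


def overlay_sample(dsc: DSCResult, agg: AggregationResult) -> OverlayResult:
    """Overlay statistic for one sample.

    The onset used is T_agg_1 (the earliest detected aggregation); if only
    T_agg_2 was detected it is used instead and flagged.  With no detected
    aggregation the fraction and domain are undefined.
    """
    tm_fab = dsc.tm_fab
    if tm_fab is None:
        tm_fab = dsc.transitions[0].tm if dsc.transitions else np.nan
    tagg, fallback = agg.tagg1, False
    if tagg is None and agg.tagg2 is not None:
        tagg, fallback = agg.tagg2, True
    if tagg is None:
        return OverlayResult(dsc.condition, tm_fab, None, "none", None)
    t0 = dsc.fraction_unfolded.temperature[0]
    if tagg < t0:
        raise ScanDomainError(
            f"aggregation onset {tagg:.2f} °C precedes DSC scan start {t0:.2f} °C")
    frac = float(dsc.fraction_unfolded(tagg))
    domain = _coinciding_domain(dsc, tagg)
    return OverlayResult(dsc.condition, tm_fab, frac, domain, float(tagg), fallback)


def average_tm_transform(dsc: DSCResult) -> float:
    """Per-sample mean of the fitted midpoints (order-invariant).

    Averaging midpoints across transitions normalises the per-molecule
    stratification of T_m(Fab) and exposes shared pH trends.
    """
    if not dsc.transitions:
        raise InvalidInputError("sample has no fitted transitions")
    return float(np.mean([tr.tm for tr in dsc.transitions]))


def build_panel_summary(results: list[OverlayResult],
                        dsc_results: list[DSCResult]) -> PanelSummary:
    """Plot-ready overlay table plus grouped distribution statistics."""
    if not results:
        raise InvalidInputError("empty result list")
    rows = []
    for ov, dsc in zip(results, dsc_results):
        rows.append(dict(
            sample_id=ov.condition.sample_id,
            mab_id=ov.condition.mab_id,
            pH=ov.condition.pH,
            nacl_mM=ov.condition.nacl_mM,
            tm_fab_C=ov.tm_fab,
            frac_unfolded_at_onset=ov.frac_unfolded_at_onset,
            coinciding_domain=ov.coinciding_domain,
            tagg_used_C=ov.tagg_used,
            average_tm_C=average_tm_transform(dsc),
        ))
    table = pd.DataFrame(rows)

    stats = []
    for key in ("mab_id", "pH"):
        for metric in ("tm_fab_C", "average_tm_C"):
            g = table.groupby(key)[metric]
            s = g.agg(["mean", "std", "median", "count"])
            s["q1"] = g.quantile(0.25)
            s["q3"] = g.quantile(0.75)
            s = s.reset_index().rename(columns={key: "group"})
            s.insert(0, "grouping", key)
            s.insert(1, "metric", metric)
            stats.append(s)
    group_stats = pd.concat(stats, ignore_index=True)

    detected = table[table["coinciding_domain"] != "none"]
    share = (detected["coinciding_domain"].value_counts(normalize=True) * 100.0
             if len(detected) else pd.Series(dtype=float))
    domain_share = share.rename_axis("domain").reset_index(name="share_pct")

    return PanelSummary(table=table, group_stats=group_stats, domain_share=domain_share)


def band_share(table: pd.DataFrame, mab_id: str, lo: float, hi: float,
               column: str = "tm_fab_C") -> float:
    """Share (%) of the datapoints inside [lo, hi] that belong to ``mab_id``.

    Quantifies how strongly a temperature band is dominated by a single
    molecule (stratification of the panel).
    """
    in_band = table[(table[column] >= lo) & (table[column] <= hi)]
    if len(in_band) == 0:
        return 0.0
    return 100.0 * float((in_band["mab_id"] == mab_id).mean())
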