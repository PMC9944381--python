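"""Manifest-driven batch pipeline tying all analysis stages together.

``run_simulate`` writes a synthetic panel to disk; ``run_analyze`` walks a
manifest, runs DSC / light-scattering / SEC analysis per sample, joins
everything into a per-sample results table and derives the case-study
outputs (overlay table, salt-effect map, transition-temperature ML
evaluation); ``run_report`` renders grouped statistics and figures.
Failures are isolated per sample: a broken trace yields an error code in
its row and the batch continues.
"""

from __future__ import annotations

import dataclasses
import logging
from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from . import io as mio
from .conditions import FormulationCondition
from .designs import study_design
from .dsc import analyze_thermogram
from .errors import InvalidInputError
from .light_scattering import AggregationDetectionParams, detect_aggregation, fit_kd
from .mlpredict import (DEFAULT_TARGETS, curate_dataset, feature_importance,
                        train_evaluate)
from .overlay import build_panel_summary, overlay_sample
from .salt import LiabilityThresholds, SaltPair, build_salt_map, evaluate_salt_pair
from .sec import integrate_composition
from .synth import NoiseModel, make_panel

log = logging.getLogger("mabdev")

__all__ = ["RunConfig", "MLSettings", "run_simulate", "run_analyze", "run_report",
           "AnalysisOutputs"]


@dataclass
class MLSettings:
    enabled: bool = True
    folds: int = 5
    repeats: int = 5
    collinearity_r: float = 0.95
    n_search: int = 0


@dataclass
class RunConfig:
    panel_dir: str = "panel"
    output_dir: str = "results"
    seed: int = 0
    n_transitions: int | None = None  # None = automatic model selection
    detection: AggregationDetectionParams = field(default_factory=AggregationDetectionParams)
    thresholds: LiabilityThresholds = field(default_factory=LiabilityThresholds)
    ml: MLSettings = field(default_factory=MLSettings)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        raw = yaml.safe_load(Path(path).read_text()) or {}
        return cls.from_dict(raw)

    @classmethod
    def from_dict(cls, raw: dict) -> "RunConfig":
        def build(klass, data):
            names = {f.name for f in dataclasses.fields(klass)}
            unknown = set(data) - names
            if unknown:
                raise InvalidInputError(f"unknown config keys for "
                                        f"{klass.__name__}: {sorted(unknown)}")
            return data
        data = dict(build(cls, raw))
        for key, klass in (("detection", AggregationDetectionParams),
                           ("thresholds", LiabilityThresholds),
                           ("ml", MLSettings)):
            if key in data:
                data[key] = klass(**build(klass, data[key]))
        return cls(**data)


@dataclass
class AnalysisOutputs:
    results: pd.DataFrame
    overlay_table: pd.DataFrame | None
    overlay_stats: pd.DataFrame | None
    salt_map: pd.DataFrame | None
    salt_results: list = field(default_factory=list)  # includes incomplete pairs
    ml_mae: pd.DataFrame | None = None
    ml_importance: dict | None = None
    curation_log: object | None = None
    n_failed: int = 0


def run_simulate(config: RunConfig, design=None, noise: NoiseModel | None = None):
    """Simulate a panel (the built-in study design by default) and write it
    under ``config.panel_dir``.  Returns the manifest path."""
    design = design or study_design()
    panel = make_panel(design, seed=config.seed, noise=noise)
    manifest = mio.write_panel(panel, config.panel_dir)
    log.info("wrote %d samples to %s", len(panel), config.panel_dir)
    return manifest


def _analyze_sample(row, panel_dir, config):
    cond = FormulationCondition(row["mab_id"], float(row["pH"]), float(row["nacl_mM"]))
    out = dict(sample_id=row["sample_id"], mab_id=cond.mab_id, pH=cond.pH,
               nacl_mM=cond.nacl_mM, error="")
    objects = {}

    dsc_path = panel_dir / row.get("dsc_path", "")
    if dsc_path.is_file():
        dsc_res = analyze_thermogram(mio.read_thermogram(dsc_path, cond),
                                     n_transitions=config.n_transitions)
        tms = dsc_res.tm_sorted()
        out["tonset"] = dsc_res.tonset
        for i in range(3):
            out[f"tm{i+1}"] = tms[i] if i < len(tms) else np.nan
        for dom in ("Fab", "CH2", "CH3"):
            out[f"tm_{dom.lower()}"] = dsc_res.tm_by_domain(dom)
        objects["dsc"] = dsc_res

    sls_path = panel_dir / row.get("sls_path", "")
    if sls_path.is_file():
        agg = detect_aggregation(mio.read_aggregation_trace(sls_path, cond),
                                 config.detection)
        out["tagg1"], out["tagg2"] = agg.tagg1, agg.tagg2
        objects["agg"] = agg

    dls_path = panel_dir / row.get("dls_path", "")
    if dls_path.is_file():
        kd = fit_kd(mio.read_dilution_series(dls_path, cond))
        out.update(kd=kd.kd, d0=kd.d0, kd_se=kd.kd_se)

    sec_path = panel_dir / row.get("sec_path", "")
    if sec_path.is_file():
        comp = integrate_composition(mio.read_chromatogram(sec_path, cond))
        out.update(pct_hmw=comp.pct_hmw, pct_monomer=comp.pct_monomer,
                   pct_lmw=comp.pct_lmw)

    if "dsc" in objects and "agg" in objects:
        ov = overlay_sample(objects["dsc"], objects["agg"])
        out["tm_fab"] = ov.tm_fab
        out["frac_unfolded_at_onset"] = ov.frac_unfolded_at_onset
        out["coinciding_domain"] = ov.coinciding_domain
        objects["overlay"] = ov

    for col in ("z_average_nm", "pdi", "qc_flag"):
        if col in row:
            out[col] = row[col]
    return out, objects


def run_analyze(config: RunConfig, write: bool = True) -> AnalysisOutputs:
    """Analyse every sample of the manifest under ``config.panel_dir``."""
    panel_dir = Path(config.panel_dir)
    manifest = mio.read_manifest(panel_dir / "manifest.csv")
    rows, per_sample = [], {}
    n_failed = 0
    for _, mrow in manifest.iterrows():
        try:
            out, objects = _analyze_sample(mrow, panel_dir, config)
        except Exception as exc:  # isolate per-sample failures
            log.warning("sample %s failed: %s", mrow["sample_id"], exc)
            out = dict(sample_id=mrow["sample_id"], mab_id=mrow["mab_id"],
                       pH=mrow["pH"], nacl_mM=mrow["nacl_mM"],
                       error=f"{type(exc).__name__}: {exc}")
            objects = {}
            n_failed += 1
        rows.append(out)
        per_sample[out["sample_id"]] = objects
    results = pd.DataFrame(rows)

    # --- case study 1: overlay panel summary
    overlay_table = overlay_stats = None
    ov_pairs = [(o["overlay"], o["dsc"]) for o in per_sample.values()
                if "overlay" in o and "dsc" in o]
    if ov_pairs:
        summary = build_panel_summary([p[0] for p in ov_pairs], [p[1] for p in ov_pairs])
        overlay_table, overlay_stats = summary.table, summary.group_stats
    else:
        log.info("overlay stage skipped: no sample had both DSC and SLS data")

    # --- case study 2: salt-effect map
    salt_map = None
    salt_results = []
    for (mab, ph), group in results.groupby(["mab_id", "pH"]):
        ids = {float(r["nacl_mM"]): r["sample_id"] for _, r in group.iterrows()}
        lo, hi = ids.get(0.0), ids.get(150.0)
        if lo is None or hi is None:
            continue
        olo, ohi = per_sample.get(lo, {}), per_sample.get(hi, {})
        if not ({"dsc", "agg"} <= set(olo) and {"dsc", "agg"} <= set(ohi)):
            continue
        pair = SaltPair(mab, float(ph), (olo["dsc"], olo["agg"]),
                        (ohi["dsc"], ohi["agg"]))
        salt_results.append(evaluate_salt_pair(pair, config.thresholds))
    if salt_results:
        salt_map = build_salt_map(salt_results)
    else:
        log.info("salt-effect stage skipped: no complete 0/150 mM pairs")

    # --- case study 3: transition-temperature prediction
    ml_mae = ml_imp = curation_log = None
    ml_cols = set(DEFAULT_TARGETS) | {"tagg1", "tagg2", "kd"}
    if config.ml.enabled and ml_cols <= set(results.columns):
        try:
            curated, curation_log = curate_dataset(
                results.set_index("sample_id"), collinearity_r=config.ml.collinearity_r)
            evaluation = train_evaluate(curated, folds=config.ml.folds,
                                        repeats=config.ml.repeats, seed=config.seed,
                                        predictors=curation_log.kept_predictors,
                                        n_search=config.ml.n_search)
            ml_imp = feature_importance(evaluation)
            ml_mae = pd.DataFrame([
                dict(target=t, mae_mean=ev.mae_mean, mae_sd=float(ev.mae_splits.std()),
                     pearson_r=ev.pearson_r)
                for t, ev in evaluation.per_target.items()])
        except InvalidInputError as exc:
            log.info("ML stage skipped: %s", exc)

    outputs = AnalysisOutputs(results=results, overlay_table=overlay_table,
                              overlay_stats=overlay_stats, salt_map=salt_map,
                              salt_results=salt_results,
                              ml_mae=ml_mae, ml_importance=ml_imp,
                              curation_log=curation_log, n_failed=n_failed)
    if write:
        _write_outputs(outputs, Path(config.output_dir))
    return outputs


def _write_outputs(outputs: AnalysisOutputs, out_dir: Path):
    out_dir.mkdir(parents=True, exist_ok=True)
    outputs.results.to_csv(out_dir / "results_table.csv", index=False)
    if outputs.overlay_table is not None:
        outputs.overlay_table.to_csv(out_dir / "overlay_table.csv", index=False)
        outputs.overlay_stats.to_csv(out_dir / "overlay_group_stats.csv", index=False)
    if outputs.salt_map is not None:
        outputs.salt_map.to_csv(out_dir / "salt_map.csv", index=False)
    if outputs.ml_mae is not None:
        outputs.ml_mae.to_csv(out_dir / "ml_mae.csv", index=False)
        for target, table in outputs.ml_importance.items():
            table.to_csv(out_dir / f"ml_importance_{target}.csv")


def run_report(config: RunConfig) -> Path:
    """Render figures and a short text summary from written analysis outputs."""
    import matplotlib
    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    out_dir = Path(config.output_dir)
    report = ["# Developability panel report", ""]

    overlay_path = out_dir / "overlay_table.csv"
    if overlay_path.is_file():
        df = pd.read_csv(overlay_path)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        for dom, marker in (("Fab", "o"), ("CH2", "D"), ("CH3", "s")):
            sub = df[df["coinciding_domain"] == dom]
            ax.scatter(sub["tm_fab_C"], sub["frac_unfolded_at_onset"],
                       marker=marker, label=dom, alpha=0.7)
        ax.set_xlabel("T_m(Fab) [°C]")
        ax.set_ylabel("fraction unfolded at aggregation onset")
        ax.legend(title="coinciding domain")
        fig.savefig(out_dir / "overlay_plot.svg")
        plt.close(fig)
        report.append(f"Overlay: {len(df)} samples (overlay_plot.svg).")
    else:
        report.append("Overlay: not run.")

    salt_path = out_dir / "salt_map.csv"
    if salt_path.is_file():
        df = pd.read_csv(salt_path)
        fig, ax = plt.subplots(figsize=(6, 4.5))
        colors = {"red": "tab:red", "amber": "orange", "green": "tab:green"}
        ax.scatter(df["dtagg2_C"], df["dtm_C"], c=df["rag"].map(colors))
        ax.axvline(0.0, color="k", lw=0.5)
        ax.axhline(3.0, color="k", lw=0.5)
        ax.set_xlabel("ΔT_agg2 [°C] (negative = colloidal liability)")
        ax.set_ylabel("ΔT_m [°C] (high = conformational liability)")
        ax.invert_yaxis()  # flexible structures plot toward the bottom
        fig.savefig(out_dir / "salt_map.svg")
        plt.close(fig)
        counts = df["rag"].value_counts().to_dict()
        report.append(f"Salt effects: {len(df)} pairs, RAG counts {counts} (salt_map.svg).")
    else:
        report.append("Salt effects: not run.")

    mae_path = out_dir / "ml_mae.csv"
    if mae_path.is_file():
        df = pd.read_csv(mae_path)
        report.append("ML prediction (mean cross-validated MAE, °C):")
        for _, r in df.iterrows():
            report.append(f"  {r['target']}: {r['mae_mean']:.2f} (r = {r['pearson_r']:.2f})")
    else:
        report.append("ML prediction: not run.")

    path = out_dir / "report.md"
    path.write_text("\n".join(report) + "\n")
    return path
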