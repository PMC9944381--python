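"""Reading and writing instrument-export-style delimited files.

Every trace is a two-column CSV with a typed header; a panel is a
directory of per-sample subdirectories plus a manifest table, and each
simulated sample carries a JSON ground-truth sidecar.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path

import numpy as np
import pandas as pd

from .conditions import FormulationCondition
from .dsc import Thermogram
from .errors import InvalidInputError
from .light_scattering import AggregationTrace, DilutionSeries
from .sec import SECChromatogram
from .synth import SimulatedSample

DSC_COLUMNS = ("temperature_C", "cp_excess_kcal_per_mol_C")
SLS_COLUMNS = ("temperature_C", "intensity_kcps")
DLS_COLUMNS = ("conc_mg_per_mL", "D")
SEC_COLUMNS = ("time_min", "a280")


def _write_two_column(path, columns, x, y):
    pd.DataFrame({columns[0]: x, columns[1]: y}).to_csv(path, index=False)


def _read_two_column(path, columns):
    df = pd.read_csv(path)
    missing = [c for c in columns if c not in df.columns]
    if missing:
        raise InvalidInputError(f"{path}: missing columns {missing}")
    return df[columns[0]].to_numpy(float), df[columns[1]].to_numpy(float)


def write_thermogram(path, tg: Thermogram):
    _write_two_column(path, DSC_COLUMNS, tg.temperature, tg.cp_excess)


def read_thermogram(path, condition: FormulationCondition) -> Thermogram:
    t, y = _read_two_column(path, DSC_COLUMNS)
    return Thermogram(condition, t, y)


def write_aggregation_trace(path, trace: AggregationTrace):
    _write_two_column(path, SLS_COLUMNS, trace.temperature, trace.intensity)


def read_aggregation_trace(path, condition: FormulationCondition) -> AggregationTrace:
    t, y = _read_two_column(path, SLS_COLUMNS)
    return AggregationTrace(condition, t, y)


def write_dilution_series(path, series: DilutionSeries):
    _write_two_column(path, DLS_COLUMNS, series.concentration, series.diffusion)


def read_dilution_series(path, condition: FormulationCondition) -> DilutionSeries:
    c, d = _read_two_column(path, DLS_COLUMNS)
    return DilutionSeries(condition, c, d)


def write_chromatogram(path, ch: SECChromatogram):
    _write_two_column(path, SEC_COLUMNS, ch.time, ch.a280)


def read_chromatogram(path, condition: FormulationCondition) -> SECChromatogram:
    t, y = _read_two_column(path, SEC_COLUMNS)
    return SECChromatogram(condition, t, y)


def _jsonable(obj):
    if dataclasses.is_dataclass(obj) and not isinstance(obj, type):
        return {k: _jsonable(v) for k, v in dataclasses.asdict(obj).items()}
    if isinstance(obj, (np.floating, np.integer)):
        return obj.item()
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    if isinstance(obj, (list, tuple)):
        return [_jsonable(v) for v in obj]
    if isinstance(obj, dict):
        return {k: _jsonable(v) for k, v in obj.items()}
    return obj


def write_truth_sidecar(path, sample: SimulatedSample):
    payload = _jsonable(sample.truth)
    payload["onset_true_C"] = sample.aggregation_trace.meta.get("onset_true")
    Path(path).write_text(json.dumps(payload, indent=1))


def write_panel(panel: list[SimulatedSample], out_dir) -> Path:
    """Write a simulated panel as per-sample directories plus manifest.csv."""
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    rows = []
    for sample in panel:
        cond = sample.condition
        sdir = out_dir / cond.sample_id
        sdir.mkdir(exist_ok=True)
        write_thermogram(sdir / "dsc.csv", sample.thermogram)
        write_aggregation_trace(sdir / "sls.csv", sample.aggregation_trace)
        write_dilution_series(sdir / "dls.csv", sample.dilution_series)
        write_chromatogram(sdir / "sec.csv", sample.chromatogram)
        write_truth_sidecar(sdir / "truth.json", sample)
        rows.append(dict(sample_id=cond.sample_id, mab_id=cond.mab_id,
                         pH=cond.pH, nacl_mM=cond.nacl_mM,
                         dsc_path=f"{cond.sample_id}/dsc.csv",
                         sls_path=f"{cond.sample_id}/sls.csv",
                         dls_path=f"{cond.sample_id}/dls.csv",
                         sec_path=f"{cond.sample_id}/sec.csv",
                         qc_flag=sample.truth.qc_flag,
                         z_average_nm=sample.truth.z_average_nm_true,
                         pdi=sample.truth.pdi_true))
    manifest = pd.DataFrame(rows)
    manifest.to_csv(out_dir / "manifest.csv", index=False)
    return out_dir / "manifest.csv"


def read_manifest(manifest_path) -> pd.DataFrame:
    manifest_path = Path(manifest_path)
    if not manifest_path.exists():
        raise InvalidInputError(f"manifest not found: {manifest_path}")
    df = pd.read_csv(manifest_path)
    required = {"sample_id", "mab_id", "pH", "nacl_mM"}
    missing = required - set(df.columns)
    if missing:
        raise InvalidInputError(f"manifest missing columns {sorted(missing)}")
    return df
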