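"""Serialisation of all artifacts (CSV + JSON), with format versioning.

Formats
-------
* angle series CSV: columns ``cell_id, frame, increment_deg``
* direction series CSV: columns ``cell_id, frame, direction``
* trace CSV: columns ``t_start, cw_bias`` (empty cell = MISSING) plus a JSON
  sidecar (``<stem>.meta.json``) carrying bin_width, stimulus_time, n_cells
* vectors CSV: columns ``y1..y15, label, concentration_mM`` (label UNKNOWN
  and empty concentration allowed)
* ModelSet / templates / profiles / reports: JSON with a ``format_version``

CSV dialect: UTF-8, comma-separated, header row, "." decimal.
"""

from __future__ import annotations

import json
from pathlib import Path

import numpy as np
import pandas as pd

from .concentration import ModelFunction, ModelSet, TrainingSet
from .exceptions import MissingInputError, SchemaError
from .synthetic import SyntheticChemicalProfile
from .template import N_INDICES, UNKNOWN, CharacteristicVector, SixLineTemplate
from .traces import CWBiasTrace, DirectionSeries, FrameAngleSeries, label_to_str, str_to_label

FORMAT_VERSION = "1"


def _require(path) -> Path:
    path = Path(path)
    if not path.exists():
        raise MissingInputError(f"file not found: {path}")
    return path


# ---------------------------------------------------------------- angle series

def write_angle_series(cells, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "frame": np.arange(len(c)),
                "increment_deg": c.angle_increments,
            }
        )
        for c in cells
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_angle_series(path, frame_interval: float = 0.01) -> list:
    df = pd.read_csv(_require(path))
    _check_columns(df, ["cell_id", "frame", "increment_deg"], path)
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            FrameAngleSeries(
                cell_id=str(cell_id),
                angle_increments=grp["increment_deg"].to_numpy(),
                frame_interval=frame_interval,
            )
        )
    return out


def write_direction_series(cells, path) -> None:
    frames = [
        pd.DataFrame(
            {
                "cell_id": c.cell_id,
                "frame": np.arange(len(c)),
                "direction": [label_to_str(v) for v in c.labels],
            }
        )
        for c in cells
    ]
    pd.concat(frames, ignore_index=True).to_csv(path, index=False)


def read_direction_series(path, frame_interval: float = 0.01) -> list:
    df = pd.read_csv(_require(path))
    _check_columns(df, ["cell_id", "frame", "direction"], path)
    out = []
    for cell_id, grp in df.groupby("cell_id", sort=False):
        grp = grp.sort_values("frame")
        out.append(
            DirectionSeries(
                cell_id=str(cell_id),
                labels=np.array([str_to_label(s) for s in grp["direction"]], dtype=np.int8),
                frame_interval=frame_interval,
            )
        )
    return out


# --------------------------------------------------------------------- traces

def _sidecar(path) -> Path:
    path = Path(path)
    return path.with_suffix(".meta.json")


def write_trace(trace: CWBiasTrace, path) -> None:
    df = pd.DataFrame({"t_start": trace.bin_starts, "cw_bias": trace.values})
    df.to_csv(path, index=False, na_rep="")
    meta = {
        "format_version": FORMAT_VERSION,
        "bin_width": trace.bin_width,
        "stimulus_time": trace.stimulus_time,
        "n_cells": trace.n_cells,
    }
    _sidecar(path).write_text(json.dumps(meta, indent=1))


def read_trace(path) -> CWBiasTrace:
    df = pd.read_csv(_require(path))
    _check_columns(df, ["t_start", "cw_bias"], path)
    try:
        meta = json.loads(_require(_sidecar(path)).read_text())
        return CWBiasTrace(
            values=df["cw_bias"].to_numpy(dtype=float),
            stimulus_time=float(meta["stimulus_time"]),
            bin_width=float(meta["bin_width"]),
            n_cells=int(meta["n_cells"]),
        )
    except KeyError as e:
        raise SchemaError(f"trace sidecar {_sidecar(path)} missing field {e}") from None


# -------------------------------------------------------------------- vectors

_YCOLS = [f"y{i}" for i in range(1, N_INDICES + 1)]


def write_vectors(records, path) -> None:
    rows = []
    for rec in records:
        row = {c: rec.y[k] for k, c in enumerate(_YCOLS)}
        row["label"] = rec.label
        row["concentration_mM"] = rec.concentration
        rows.append(row)
    pd.DataFrame(rows).to_csv(path, index=False, na_rep="")


def read_vectors(path) -> list:
    df = pd.read_csv(_require(path))
    _check_columns(df, _YCOLS + ["label"], path)
    records = []
    for _, row in df.iterrows():
        conc = row.get("concentration_mM", float("nan"))
        records.append(
            CharacteristicVector(
                y=row[_YCOLS].to_numpy(dtype=float),
                label=str(row["label"]) if pd.notna(row["label"]) else UNKNOWN,
                concentration=float(conc) if pd.notna(conc) else float("nan"),
                fit_rms=float(row[_YCOLS[-1]]),
            )
        )
    return records


def write_training_set(training: TrainingSet, path) -> None:
    write_vectors(training.records, path)


def read_training_set(path) -> TrainingSet:
    return TrainingSet.from_records(read_vectors(path))


# ------------------------------------------------------------------ templates

def template_to_dict(tpl: SixLineTemplate) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "b": tpl.b, "r": tpl.r,
        "t1": tpl.t1, "t2": tpl.t2, "t3": tpl.t3, "t4": tpl.t4, "t5": tpl.t5,
        "v3": tpl.v3, "v4": tpl.v4, "v5": tpl.v5,
    }


def write_template(tpl: SixLineTemplate, path) -> None:
    Path(path).write_text(json.dumps(template_to_dict(tpl), indent=1))


def read_template(path) -> SixLineTemplate:
    d = json.loads(_require(path).read_text())
    d.pop("format_version", None)
    try:
        return SixLineTemplate(**d)
    except TypeError as e:
        raise SchemaError(f"template file {path}: {e}") from None


# ------------------------------------------------------------------ model sets

def model_set_to_dict(models: ModelSet) -> dict:
    return {
        "format_version": FORMAT_VERSION,
        "chemicals": list(models.chemicals),
        "basis": models.basis,
        "sigma_floor_frac": models.sigma_floor_frac,
        "functions": [
            {
                "chemical": f.chemical,
                "index": f.index,
                "coef": list(map(float, f.coef)),
                "sigma": f.sigma,
                "x_lo": f.x_lo,
                "x_hi": f.x_hi,
            }
            for f in models.functions.values()
        ],
    }


def model_set_from_dict(d: dict) -> ModelSet:
    try:
        functions = {
            (f["chemical"], f["index"]): ModelFunction(
                chemical=f["chemical"],
                index=f["index"],
                coef=np.asarray(f["coef"], dtype=float),
                sigma=f["sigma"],
                x_lo=f["x_lo"],
                x_hi=f["x_hi"],
            )
            for f in d["functions"]
        }
        return ModelSet(
            chemicals=list(d["chemicals"]),
            functions=functions,
            basis=d["basis"],
            sigma_floor_frac=d.get("sigma_floor_frac", 0.05),
        )
    except KeyError as e:
        raise SchemaError(f"model set document missing field {e}") from None


def write_model_set(models: ModelSet, path) -> None:
    Path(path).write_text(json.dumps(model_set_to_dict(models), indent=1))


def read_model_set(path) -> ModelSet:
    return model_set_from_dict(json.loads(_require(path).read_text()))


# ------------------------------------------------------------------- profiles

def write_profiles(profiles, path) -> None:
    doc = {
        "format_version": FORMAT_VERSION,
        "profiles": [p.to_dict() for p in profiles],
    }
    Path(path).write_text(json.dumps(doc, indent=1))


def read_profiles(path) -> dict:
    doc = json.loads(_require(path).read_text())
    try:
        profiles = [SyntheticChemicalProfile.from_dict(d) for d in doc["profiles"]]
    except (KeyError, TypeError) as e:
        raise SchemaError(f"profiles file {path}: {e}") from None
    return {p.name: p for p in profiles}


def _check_columns(df: pd.DataFrame, required, path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing columns {missing}")
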