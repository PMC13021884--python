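"""File-format contracts: design CSV, assay CSVs, factor config, model JSON.

All tabular files are UTF-8 CSV with a mandatory header (no positional
guessing) and "." as the decimal separator.  Schemas:

* factor config (JSON): list of ``{"name", "center", "delta", "unit"}``
* design CSV: ``run_id``, one ``<factor>_coded`` column per factor,
  optional ``<factor>_actual`` columns, optional ``response``
* dual-culture CSV: ``control_diameter``, ``treatment_diameter``,
  optional ``plug_diameter``
* spore CSV: ``label``, ``germinated``, ``total``
* disease CSV: ``grade``, ``count``
* grouped CSV: ``group``, ``value``
* model JSON: ``{"factors": [...], "coefficients": {"b0": ..., ...}}``
"""

from __future__ import annotations

import json
from pathlib import Path
from typing import Sequence

import numpy as np
import pandas as pd

from .assay import (
    DiseaseSurvey,
    DualCultureRecord,
    GroupedMeasurements,
    SporeGerminationRecord,
)
from .design import DesignTable, FactorSpec
from .model import QuadraticModel

__all__ = [
    "SchemaError",
    "read_factor_config",
    "write_factor_config",
    "read_design_csv",
    "write_design_csv",
    "read_model_json",
    "write_model_json",
    "read_dual_culture_csv",
    "read_spore_csv",
    "read_disease_csv",
    "read_grouped_csv",
]


class SchemaError(ValueError):
    """A file does not match its documented schema."""


def _require_columns(df: pd.DataFrame, required: Sequence[str], path) -> None:
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise SchemaError(f"{path}: missing required column(s) {missing}; "
                          f"found {list(df.columns)}")


def read_factor_config(path) -> list[FactorSpec]:
    entries = json.loads(Path(path).read_text())
    if not isinstance(entries, list) or not entries:
        raise SchemaError(f"{path}: factor config must be a nonempty JSON list")
    specs = []
    for i, e in enumerate(entries):
        try:
            specs.append(FactorSpec(name=str(e["name"]), center=float(e["center"]),
                                    delta=float(e["delta"]), unit=str(e.get("unit", "g/L"))))
        except (KeyError, TypeError, ValueError) as exc:
            raise SchemaError(f"{path}: bad factor entry {i}: {exc}") from exc
    return specs


def write_factor_config(specs: Sequence[FactorSpec], path) -> None:
    Path(path).write_text(json.dumps(
        [{"name": s.name, "center": s.center, "delta": s.delta, "unit": s.unit}
         for s in specs], indent=2) + "\n")


def read_design_csv(path) -> DesignTable:
    df = pd.read_csv(path)
    coded_cols = [c for c in df.columns if c.endswith("_coded")]
    if not coded_cols:
        raise SchemaError(f"{path}: no <factor>_coded columns found")
    factors = [c[: -len("_coded")] for c in coded_cols]
    response = df["response"].to_numpy(dtype=float) if "response" in df.columns else None
    run_ids = (df["run_id"].astype(int).tolist() if "run_id" in df.columns
               else list(range(1, len(df) + 1)))
    return DesignTable(
        factors=factors,
        coded=df[coded_cols].to_numpy(dtype=float),
        response=response,
        run_ids=run_ids,
    )


def write_design_csv(design: DesignTable, path,
                     factor_specs: Sequence[FactorSpec] | None = None) -> None:
    design.to_frame(factor_specs).to_csv(path, index=False)


def read_model_json(path) -> QuadraticModel:
    d = json.loads(Path(path).read_text())
    try:
        return QuadraticModel.from_dict(d)
    except (KeyError, TypeError) as exc:
        raise SchemaError(f"{path}: bad model JSON: {exc}") from exc


def write_model_json(model: QuadraticModel, path) -> None:
    Path(path).write_text(json.dumps(model.to_dict(), indent=2) + "\n")


def read_dual_culture_csv(path) -> list[DualCultureRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["control_diameter", "treatment_diameter"], path)
    plug = df["plug_diameter"] if "plug_diameter" in df.columns else pd.Series(4.0, index=df.index)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(DualCultureRecord(float(row["control_diameter"]),
                                         float(row["treatment_diameter"]),
                                         float(plug[i])))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc  # +2: header + 1-based
    return out


def read_spore_csv(path) -> list[SporeGerminationRecord]:
    df = pd.read_csv(path)
    _require_columns(df, ["label", "germinated", "total"], path)
    out = []
    for i, row in df.iterrows():
        try:
            out.append(SporeGerminationRecord(int(row["germinated"]), int(row["total"]),
                                              str(row["label"])))
        except ValueError as exc:
            raise SchemaError(f"{path}: row {i + 2}: {exc}") from exc
    return out


def read_disease_csv(path, max_grade: int = 6) -> DiseaseSurvey:
    df = pd.read_csv(path)
    _require_columns(df, ["grade", "count"], path)
    try:
        return DiseaseSurvey(
            {int(g): int(c) for g, c in zip(df["grade"], df["count"])},
            max_grade=max_grade,
        )
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc


def read_grouped_csv(path) -> GroupedMeasurements:
    df = pd.read_csv(path)
    _require_columns(df, ["group", "value"], path)
    groups = {str(g): sub["value"].to_numpy(dtype=float)
              for g, sub in df.groupby("group", sort=False)}
    try:
        return GroupedMeasurements(groups)
    except ValueError as exc:
        raise SchemaError(f"{path}: {exc}") from exc
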