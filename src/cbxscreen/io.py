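"""Readers and writers for plate tables, layouts and result reports.

Plate data use one strict long-format CSV dialect:
``well,time_s,wavelength_nm,absorbance`` (header required, UTF-8, '.'
decimal).  Layouts are CSV or JSON keyed by well, with concentrations in
micromolar at the file interface (converted to molar on ingestion).
Results are written as JSON (canonical, round-trippable) or flat CSV.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Iterable, Optional, Sequence

import numpy as np
import pandas as pd

from .errors import ContractError, IngestionError, LayoutError, PlateFormatError
from .types import (
    RESULT_TYPES,
    PlateWell,
    SpectralTimeSeries,
    WellCondition,
)

PLATE_COLUMNS = ("well", "time_s", "wavelength_nm", "absorbance")

_LAYOUT_COLUMNS = ("compound_id", "compound_conc_uM", "reagent",
                   "reagent_conc_uM", "replicate")


def read_layout(path: str | Path) -> dict[str, WellCondition]:
    """Read a plate layout (CSV or JSON by extension) into conditions.

    A well is a blank when it has a reagent but no compound.
    """
    path = Path(path)
    if path.suffix.lower() == ".json":
        raw = json.loads(path.read_text(encoding="utf-8"))
        rows = [{"well": well, **fields} for well, fields in raw.items()]
    else:
        df = pd.read_csv(path)
        missing = [c for c in ("well",) + _LAYOUT_COLUMNS if c not in df.columns]
        if missing:
            raise PlateFormatError(f"layout is missing column(s) {missing}")
        rows = df.to_dict("records")
    layout: dict[str, WellCondition] = {}
    for row in rows:
        compound = row.get("compound_id")
        if compound is None or (isinstance(compound, float) and np.isnan(compound)) \
                or compound == "":
            compound = None
        reagent = str(row.get("reagent", "none"))
        cond = WellCondition(
            compound_id=compound,
            compound_conc=float(row.get("compound_conc_uM", 0.0)) * 1e-6,
            reagent=reagent,
            reagent_conc=float(row.get("reagent_conc_uM", 0.0)) * 1e-6,
            replicate=int(row.get("replicate", 1)),
            is_blank=(compound is None and reagent != "none"),
        )
        layout[str(row["well"])] = cond
    return layout


def write_layout(layout: dict[str, WellCondition], path: str | Path) -> None:
    rows = []
    for well, cond in layout.items():
        rows.append({
            "well": well,
            "compound_id": cond.compound_id if cond.compound_id else "",
            "compound_conc_uM": cond.compound_conc * 1e6,
            "reagent": cond.reagent,
            "reagent_conc_uM": cond.reagent_conc * 1e6,
            "replicate": cond.replicate,
        })
    pd.DataFrame(rows).to_csv(path, index=False)


def read_plate_table(path: str | Path,
                     layout: str | Path | dict[str, WellCondition],
                     ) -> list[PlateWell]:
    """Read a long-format plate CSV and attach conditions from a layout.

    Raises
    ------
    PlateFormatError
        If a required column is absent.
    IngestionError
        If any well's (time, wavelength) grid has a missing cell: gaps are
        never silently filled.
    LayoutError
        If a well in the data has no layout entry.
    """
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    df = pd.read_csv(path)
    missing = [c for c in PLATE_COLUMNS if c not in df.columns]
    if missing:
        raise PlateFormatError(f"plate table is missing column(s) {missing}")
    if df[list(PLATE_COLUMNS[1:])].isna().any().any():
        bad = df.loc[df[list(PLATE_COLUMNS[1:])].isna().any(axis=1), "well"]
        raise IngestionError(
            f"well {bad.iloc[0]!r} has missing values in the plate table")
    conditions = layout if isinstance(layout, dict) else read_layout(layout)

    wells: list[PlateWell] = []
    for well, group in df.groupby("well", sort=True):
        well = str(well)
        if well not in conditions:
            raise LayoutError(f"well {well!r} is absent from the layout")
        times = np.unique(group["time_s"].to_numpy(dtype=float))
        wavelengths = np.unique(group["wavelength_nm"].to_numpy(dtype=float))
        if len(group) != times.size * wavelengths.size:
            raise IngestionError(
                f"well {well!r} has an incomplete (time, wavelength) grid: "
                f"{len(group)} rows for a {times.size}x{wavelengths.size} grid")
        pivot = group.pivot_table(index="time_s", columns="wavelength_nm",
                                  values="absorbance", aggfunc="first")
        if pivot.isna().any().any():
            raise IngestionError(
                f"well {well!r} has an incomplete (time, wavelength) grid")
        cond = conditions[well]
        series = SpectralTimeSeries(
            well_id=well,
            compound_id=cond.compound_id,
            timepoints=pivot.index.to_numpy(dtype=float),
            wavelengths=pivot.columns.to_numpy(dtype=float),
            absorbance=pivot.to_numpy(dtype=float),
        )
        wells.append(PlateWell(series=series, condition=cond))
    return wells


def write_plate_table(series: Iterable[SpectralTimeSeries],
                      path: str | Path) -> None:
    """Write series to the long-format plate CSV dialect."""
    frames = []
    for s in series:
        tt, ww = np.meshgrid(s.timepoints, s.wavelengths, indexing="ij")
        frames.append(pd.DataFrame({
            "well": s.well_id,
            "time_s": tt.ravel(),
            "wavelength_nm": ww.ravel(),
            "absorbance": s.absorbance.ravel(),
        }))
    pd.concat(frames, ignore_index=True).to_csv(path, index=False,
                                                float_format="%.10g")


def _record_to_jsonable(record) -> dict:
    out = {}
    for f in dataclasses.fields(record):
        v = getattr(record, f.name)
        if isinstance(v, (np.floating, np.integer)):
            v = v.item()
        elif isinstance(v, tuple):
            v = list(v)
        out[f.name] = v
    return out


def write_results(results: Sequence, path: str | Path) -> None:
    """Write a homogeneous collection of result records.

    JSON (``.json``) is the canonical format and round-trips through
    :func:`read_results`; any other extension gets a flat CSV export.
    Mixing result kinds in one call is a type error.
    """
    results = list(results)
    kinds = {type(r).__name__ for r in results}
    if len(kinds) > 1:
        raise TypeError(f"mixed result kinds in one report: {sorted(kinds)}")
    kind = kinds.pop() if kinds else None
    if kind is not None and kind not in RESULT_TYPES:
        raise TypeError(f"{kind} is not a writable result type")
    records = [_record_to_jsonable(r) for r in results]
    for rec in records:
        for key, val in rec.items():
            if isinstance(val, float) and not np.isfinite(val):
                raise ContractError(f"non-finite value in field {key!r}")
    path = Path(path)
    if path.suffix.lower() == ".json":
        payload = {"result_type": kind, "records": records}
        path.write_text(json.dumps(payload, indent=2), encoding="utf-8")
    else:
        pd.DataFrame(records).to_csv(path, index=False)


def read_results(path: str | Path) -> list:
    """Read back a JSON result report written by :func:`write_results`."""
    payload = json.loads(Path(path).read_text(encoding="utf-8"))
    kind = payload["result_type"]
    if kind is None:
        return []
    cls = RESULT_TYPES[kind]
    out = []
    for rec in payload["records"]:
        if "weights" in rec and isinstance(rec["weights"], list):
            rec = {**rec, "weights": tuple(rec["weights"])}
        out.append(cls(**rec))
    return out


def find_blank(wells: Sequence[PlateWell], reagent: str,
               replicate: int) -> Optional[PlateWell]:
    """Locate the reagent-only blank matching (reagent, replicate)."""
    for w in wells:
        if w.condition.is_blank and w.condition.reagent == reagent \
                and w.condition.replicate == replicate:
            return w
    return None
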