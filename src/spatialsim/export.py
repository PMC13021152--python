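"""Per-sample cell tables, CSV dialects, and sample-level summaries.

One pandas DataFrame per simulated sample, one row per cell.  Column names
are fixed so downstream spatial-statistics tools can address them:
``Sample``, ``x``, ``y``, ``Tissue Assignment``, ``Hole Assignment``, then
``Cell i Assignment`` and optionally ``Cell i Value`` per cell type.  Columns
for stages that have not run are simply absent.

The "halo-like" dialect additionally writes XMin/XMax/YMin/YMax columns, each
equal to the point coordinate (a degenerate bounding box — simulated cells
are points), so tools expecting cell bounding boxes from digital-pathology
exports can ingest the files.
"""

from __future__ import annotations

import re
from pathlib import Path

import numpy as np
import pandas as pd

from .core import SimObject

__all__ = [
    "create_spatial_list",
    "summarise_spatial",
    "write_tables",
    "read_tables",
    "write_density_grid",
]

_BBOX_COLS = ("XMin", "XMax", "YMin", "YMax")


def cell_assignment_column(cell_type: int) -> str:
    """Column name for one phenotype's positivity (cell_type is 1-based)."""
    return f"Cell {cell_type} Assignment"


def create_spatial_list(obj: SimObject, drop_holes: bool | None = None) -> list[pd.DataFrame]:
    """Materialize one cell table per sample from the simulation state.

    ``drop_holes=None`` defers to the flag recorded when holes were assigned.
    """
    patterns = obj.require_patterns()
    if drop_holes is None:
        drop_holes = obj.drop_holes
    tables = []
    for i, pat in enumerate(patterns):
        data: dict[str, np.ndarray] = {
            "Sample": np.full(len(pat), pat.sample_id, dtype=int),
            "x": pat.xs,
            "y": pat.ys,
        }
        if obj.tissue is not None:
            data["Tissue Assignment"] = obj.tissue[i]
        if obj.holes is not None:
            data["Hole Assignment"] = obj.holes[i].astype(int)
        if obj.positivity is not None:
            for t in range(obj.n_cell_types):
                data[cell_assignment_column(t + 1)] = obj.positivity[i][:, t]
        if obj.marker_values is not None:
            for t in range(obj.n_cell_types):
                data[f"Cell {t + 1} Value"] = obj.marker_values[i][:, t]
        df = pd.DataFrame(data)
        if drop_holes and "Hole Assignment" in df.columns:
            df = df[df["Hole Assignment"] == 0].reset_index(drop=True)
        df.attrs["sample_id"] = pat.sample_id
        tables.append(df)
    return tables


def summarise_spatial(
    tables: list[pd.DataFrame],
    marker_columns: str | list[str],
) -> pd.DataFrame:
    """Sample-level abundance summary: cell counts and percent positive.

    Returns one row per sample with ``Total Cells`` and, per marker column,
    ``<marker> Positive Cells`` and ``<marker> Percent Positive``
    (100 * positive / total; missing for empty samples rather than 0).
    """
    if isinstance(marker_columns, str):
        marker_columns = [marker_columns]
    for col in marker_columns:
        for j, df in enumerate(tables):
            if col not in df.columns:
                raise ValueError(
                    f"marker column {col!r} missing from table {j}"
                )
    rows = []
    for df in tables:
        total = len(df)
        row: dict[str, object] = {
            "Sample": df["Sample"].iloc[0] if total else pd.NA,
            "Total Cells": total,
        }
        for col in marker_columns:
            npos = int(df[col].sum()) if total else 0
            row[f"{col} Positive Cells"] = npos
            row[f"{col} Percent Positive"] = (
                100.0 * npos / total if total else np.nan
            )
        rows.append(row)
    return pd.DataFrame(rows)


def write_tables(
    tables: list[pd.DataFrame],
    path: str | Path,
    dialect: str = "simple",
) -> list[Path]:
    """Write one CSV per sample; returns the file paths.

    dialect "simple" writes the cell-table columns verbatim; "halo-like"
    appends degenerate bounding-box columns (XMin == XMax == x, likewise y).
    """
    if dialect not in ("simple", "halo-like"):
        raise ValueError(f"unknown dialect {dialect!r}")
    path = Path(path)
    path.mkdir(parents=True, exist_ok=True)
    files = []
    for pos, df in enumerate(tables):
        sample_id = df.attrs.get("sample_id")
        if sample_id is None:
            sample_id = int(df["Sample"].iloc[0]) if len(df) else pos + 1
        out = df
        if dialect == "halo-like":
            out = df.copy()
            out["XMin"] = out["x"]
            out["XMax"] = out["x"]
            out["YMin"] = out["y"]
            out["YMax"] = out["y"]
        f = path / f"sample_{sample_id}.csv"
        out.to_csv(f, index=False)
        files.append(f)
    return files


def read_tables(path: str | Path) -> list[pd.DataFrame]:
    """Read back a directory of exported cell tables, ordered by sample id."""
    path = Path(path)
    files = sorted(
        path.glob("sample_*.csv"),
        key=lambda f: int(re.search(r"sample_(\d+)", f.stem).group(1)),
    )
    if not files:
        raise FileNotFoundError(f"no sample_*.csv files under {path}")
    return [pd.read_csv(f) for f in files]


def write_density_grid(grid: np.ndarray, path: str | Path) -> Path:
    """Write an (n, 3) density grid as an x,y,probability CSV."""
    path = Path(path)
    pd.DataFrame(grid, columns=["x", "y", "probability"]).to_csv(path, index=False)
    return path
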