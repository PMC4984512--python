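"""Readers and writers for island tables and presence-absence matrices.

Island table: delimited text (comma default, tab auto-detected),
header row ``island_id, area_km2, <taxon1>, <taxon2>, ...``; areas are
positive decimals (scientific notation accepted), richness columns
non-negative integers.  Zero-richness islands are retained -- they
carry real information about the small-island regime.

Presence-absence matrix: first column species id, header row of
island ids, cells strictly 0/1.
"""

from __future__ import annotations

import json
import platform
from pathlib import Path
from typing import Any

import numpy as np
import pandas as pd

from .nestedness import PresenceAbsenceMatrix
from .sar_models import SARDataset

__all__ = [
    "read_island_table",
    "write_island_table",
    "read_matrix",
    "write_matrix",
    "write_json",
    "run_manifest",
]


def _sniff_sep(path: Path) -> str:
    with open(path, "r", encoding="utf-8") as fh:
        header = fh.readline()
    return "\t" if "\t" in header else ","


def read_island_table(path: str | Path) -> dict[str, SARDataset]:
    """Parse an island table into one dataset per richness column."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, dtype={0: str})
    if df.shape[1] < 3:
        raise ValueError(
            f"{path}: expected columns island_id, area_km2, <taxon...>, got {list(df.columns)}"
        )
    id_col, area_col = df.columns[0], df.columns[1]
    if df[id_col].isna().any() or df[id_col].duplicated().any():
        dupes = df[id_col][df[id_col].duplicated()].tolist()
        raise ValueError(f"{path}: duplicate or missing island ids {dupes[:5]}")
    areas = pd.to_numeric(df[area_col], errors="coerce")
    if areas.isna().any():
        row = int(areas.index[areas.isna()][0]) + 2  # +2: header + 1-based
        raise ValueError(f"{path}: unparseable area at row {row}")
    bad = areas <= 0
    if bad.any():
        row = int(areas.index[bad][0]) + 2
        raise ValueError(f"{path}: non-positive area at row {row}")
    datasets: dict[str, SARDataset] = {}
    for taxon in df.columns[2:]:
        col = pd.to_numeric(df[taxon], errors="coerce")
        if col.isna().any():
            row = int(col.index[col.isna()][0]) + 2
            raise ValueError(f"{path}: missing/unparseable richness '{taxon}' row {row}")
        if not (col == col.round()).all() or (col < 0).any():
            raise ValueError(f"{path}: richness column '{taxon}' must hold non-negative integers")
        datasets[taxon] = SARDataset.from_areas_richness(
            areas.to_numpy(float),
            col.to_numpy(int),
            island_ids=df[id_col].tolist(),
            taxon=str(taxon),
        )
    return datasets


def write_island_table(path: str | Path, datasets: dict[str, SARDataset], sep: str = ",") -> None:
    """Write one or more taxa sharing the same islands to delimited text."""
    first = next(iter(datasets.values()))
    out = pd.DataFrame({"island_id": first.island_ids, "area_km2": first.area_km2})
    for taxon, ds in datasets.items():
        if list(ds.island_ids) != list(first.island_ids):
            raise ValueError("all taxa must share the same island list")
        out[taxon] = ds.richness.astype(int)
    out.to_csv(path, sep=sep, index=False)


def read_matrix(path: str | Path) -> PresenceAbsenceMatrix:
    """Parse a binary species x island matrix from delimited text."""
    path = Path(path)
    sep = _sniff_sep(path)
    df = pd.read_csv(path, sep=sep, index_col=0)
    if df.index.duplicated().any() or pd.Index(df.columns).duplicated().any():
        raise ValueError(f"{path}: duplicate species or island labels")
    values = df.to_numpy()
    try:
        values = values.astype(float)
    except (TypeError, ValueError) as exc:
        raise ValueError(f"{path}: non-numeric cell: {exc}") from None
    if np.isnan(values).any():
        raise ValueError(f"{path}: missing cells (ragged rows?)")
    if not np.isin(values, (0.0, 1.0)).all():
        raise ValueError(f"{path}: cells must be 0/1")
    return PresenceAbsenceMatrix(
        species_ids=[str(s) for s in df.index],
        island_ids=[str(c) for c in df.columns],
        cells=values.astype(np.int8),
    )


def write_matrix(path: str | Path, matrix: PresenceAbsenceMatrix, sep: str = ",") -> None:
    df = pd.DataFrame(matrix.cells, index=matrix.species_ids, columns=matrix.island_ids)
    df.to_csv(path, sep=sep)


def write_json(path: str | Path, payload: dict[str, Any]) -> None:
    with open(path, "w", encoding="utf-8") as fh:
        json.dump(payload, fh, indent=2, sort_keys=True, default=_json_default)
        fh.write("\n")


def _json_default(obj):
    if isinstance(obj, (np.integer,)):
        return int(obj)
    if isinstance(obj, (np.floating,)):
        return float(obj)
    if isinstance(obj, np.ndarray):
        return obj.tolist()
    raise TypeError(f"not JSON serialisable: {type(obj)}")


def run_manifest(seed: int | None, settings: dict[str, Any]) -> dict[str, Any]:
    """Provenance record written next to every command's outputs."""
    from . import __version__

    return {
        "islesar_version": __version__,
        "python_version": platform.python_version(),
        "numpy_version": np.__version__,
        "pandas_version": pd.__version__,
        "seed": seed,
        "settings": settings,
    }
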