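"""Delimited-text readers and writers for cell tables, partitions and configs.

Cell tables are CSV/TSV with a header and columns
``cell_id,x,y,cell_type[,sample_id,condition]``.  Partition files append a
``tcn_label`` column (and optionally a vote-share QC column) to the cell
table and round-trip losslessly.
"""

from __future__ import annotations

import dataclasses
import json
from pathlib import Path
from typing import Optional

import numpy as np
import pandas as pd
import yaml

from .datatypes import CellMap, RunConfig, TCNPartition, warn_unknown_keys

__all__ = [
    "read_cell_table",
    "write_cell_table",
    "read_partition",
    "write_partition",
    "load_config",
    "write_enrichment",
    "write_manifest",
]

_REQUIRED = ["cell_id", "x", "y", "cell_type"]


def _sniff_sep(path: str | Path, dialect: Optional[str]) -> str:
    if dialect is not None:
        return {"csv": ",", "tsv": "\t"}.get(dialect, dialect)
    return "\t" if str(path).endswith((".tsv", ".txt")) else ","


def read_cell_table(path: str | Path, dialect: Optional[str] = None) -> CellMap:
    """Read one sample's cell table into a :class:`CellMap`.

    Row order is preserved; the phenotype vocabulary is built from this
    file alone and widened later when maps are pooled into a cohort.
    """
    sep = _sniff_sep(path, dialect)
    try:
        df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "cell_type": str})
    except pd.errors.EmptyDataError:
        raise ValueError(f"no cells: {path} is empty") from None
    missing = [c for c in _REQUIRED if c not in df.columns]
    if missing:
        raise ValueError(f"missing required column(s) {missing} in {path}")
    if len(df) == 0:
        raise ValueError(f"no cells in {path}")
    for col in ("x", "y"):
        vals = pd.to_numeric(df[col], errors="coerce")
        bad = np.nonzero(vals.isna().to_numpy() & df[col].notna().to_numpy())[0]
        if bad.size:
            raise ValueError(
                f"non-numeric coordinate in column {col!r} at row {int(bad[0])}"
            )
        df[col] = vals
    condition = None
    if "condition" in df.columns and df["condition"].notna().all():
        uniq = df["condition"].unique()
        if len(uniq) != 1:
            raise ValueError("a single cell table must carry one condition label")
        condition = int(uniq[0])
    sample_id = str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else Path(path).stem
    return CellMap(
        cell_ids=df["cell_id"].tolist(),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        cell_types=df["cell_type"].tolist(),
        sample_id=sample_id,
        condition=condition,
    )


def _base_frame(cell_map: CellMap) -> pd.DataFrame:
    df = pd.DataFrame(
        {
            "cell_id": cell_map.cell_ids,
            "x": cell_map.coords[:, 0],
            "y": cell_map.coords[:, 1],
            "cell_type": cell_map.cell_types,
            "sample_id": cell_map.sample_id,
        }
    )
    if cell_map.condition is not None:
        df["condition"] = cell_map.condition
    return df


def write_cell_table(cell_map: CellMap, path: str | Path, dialect: Optional[str] = None) -> None:
    _base_frame(cell_map).to_csv(path, sep=_sniff_sep(path, dialect), index=False)


def write_partition(
    partition: TCNPartition,
    cell_map: CellMap,
    path: str | Path,
    vote_share: Optional[np.ndarray] = None,
    one_based: bool = False,
    dialect: Optional[str] = None,
) -> None:
    """Write per-cell TCN labels next to the cell table columns."""
    if partition.n_cells != cell_map.n_cells:
        raise ValueError(
            f"partition length {partition.n_cells} does not match "
            f"map size {cell_map.n_cells}"
        )
    df = _base_frame(cell_map)
    df["tcn_label"] = partition.labels + (1 if one_based else 0)
    if vote_share is not None:
        df["vote_share"] = np.asarray(vote_share, dtype=float)
    df.to_csv(path, sep=_sniff_sep(path, dialect), index=False)


def read_partition(path: str | Path, dialect: Optional[str] = None) -> tuple[CellMap, TCNPartition]:
    sep = _sniff_sep(path, dialect)
    df = pd.read_csv(path, sep=sep, dtype={"cell_id": str, "cell_type": str})
    if "tcn_label" not in df.columns:
        raise ValueError(f"missing tcn_label column in {path}")
    labels = df["tcn_label"].to_numpy(dtype=int)
    cell_map = CellMap(
        cell_ids=df["cell_id"].tolist(),
        coords=df[["x", "y"]].to_numpy(dtype=float),
        cell_types=df["cell_type"].tolist(),
        sample_id=str(df["sample_id"].iloc[0]) if "sample_id" in df.columns else Path(path).stem,
    )
    return cell_map, TCNPartition(labels)


_CONFIG_FIELDS = {f.name for f in dataclasses.fields(RunConfig)}


def load_config(path: str | Path) -> RunConfig:
    """Load a flat key-value (YAML subset) run configuration.

    Unset fields take mode defaults; unknown keys warn rather than fail;
    out-of-range values raise naming the offending field.
    """
    with open(path) as fh:
        raw = yaml.safe_load(fh) or {}
    if not isinstance(raw, dict):
        raise ValueError(f"config {path} must be flat key-value pairs")
    known = {k: v for k, v in raw.items() if k in _CONFIG_FIELDS}
    warn_unknown_keys([k for k in raw if k not in _CONFIG_FIELDS])
    return RunConfig(**known)


def write_enrichment(scores: pd.DataFrame, path: str | Path) -> None:
    """Enrichment CSV: rows = TCNs, columns = cell types."""
    scores.to_csv(path, index=True, index_label="tcn")


def write_manifest(path: str | Path, config: RunConfig, **extra) -> None:
    """JSON run manifest recording the configuration, seeds and traces."""
    payload = {"config": dataclasses.asdict(config)}
    payload.update(extra)

    def _default(obj):
        if isinstance(obj, np.ndarray):
            return obj.tolist()
        if isinstance(obj, (np.integer, np.floating)):
            return obj.item()
        raise TypeError(f"not JSON serializable: {type(obj)}")

    with open(path, "w") as fh:
        json.dump(payload, fh, indent=2, default=_default)
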