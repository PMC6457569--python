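"""CSV schemas of the pipeline.

All files are UTF-8 comma-separated with a header row; times are HH:MM,
dates ISO-8601. Internally, samples additionally carry ``time_min`` (minutes
since midnight) and ``date_days`` (days since the earliest collection date);
both are derived, never stored.

Input tables
------------
sites.csv        site_id, pair_id, island_type, area_m2
samples.csv      sample_id, site_id, date, time, water_temp_c, depth_cm
                 (water_temp_c may be empty -> imputed downstream)
replicates.csv   sample_id, replicate_id, run_id, m_total, m_pos, ipc_conc
neg_controls.csv control_id, control_type, m_total, m_pos
"""

from __future__ import annotations

from pathlib import Path

import numpy as np
import pandas as pd

from .ddpcr import ReplicateRun

__all__ = [
    "read_sites",
    "read_samples",
    "read_replicates",
    "read_neg_controls",
    "write_dataset",
    "read_detections",
    "minutes_to_hhmm",
    "hhmm_to_minutes",
]


def minutes_to_hhmm(m: int) -> str:
    m = int(m)
    return f"{m // 60:02d}:{m % 60:02d}"


def hhmm_to_minutes(s: str) -> int:
    h, m = str(s).split(":")
    return int(h) * 60 + int(m)


def _require(df: pd.DataFrame, cols: list[str], path) -> None:
    missing = [c for c in cols if c not in df.columns]
    if missing:
        raise ValueError(f"{path}: missing required columns {missing}")


def read_sites(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"site_id": str, "pair_id": str})
    _require(df, ["site_id", "pair_id", "island_type"], path)
    bad = set(df["island_type"]) - {"colony", "control"}
    if bad:
        raise ValueError(f"{path}: unknown island types {sorted(bad)}")
    if df["site_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate site_id")
    return df


def read_samples(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str, "site_id": str})
    _require(df, ["sample_id", "site_id", "date", "time", "depth_cm"], path)
    if df["sample_id"].duplicated().any():
        raise ValueError(f"{path}: duplicate sample_id")
    df["time_min"] = df["time"].map(hhmm_to_minutes)
    if "water_temp_c" not in df.columns:
        df["water_temp_c"] = np.nan
    df["water_temp_c"] = pd.to_numeric(df["water_temp_c"], errors="coerce")
    if "temp_imputed" in df.columns:
        df["temp_imputed"] = df["temp_imputed"].astype(bool)
    else:
        df["temp_imputed"] = False
    dates = pd.to_datetime(df["date"], format="ISO8601")
    df["date_days"] = (dates - dates.min()).dt.days.astype(float)
    return df


def read_replicates(path) -> list[ReplicateRun]:
    df = pd.read_csv(path, dtype={"sample_id": str})
    _require(df, ["sample_id", "replicate_id", "run_id", "m_total", "m_pos"], path)
    runs = []
    for row in df.itertuples(index=False):
        ipc = getattr(row, "ipc_conc", None)
        runs.append(
            ReplicateRun(
                sample_id=row.sample_id,
                replicate_id=int(row.replicate_id),
                run_id=int(row.run_id),
                m_total=int(row.m_total),
                m_pos=int(row.m_pos),
                ipc_conc=None if ipc is None or pd.isna(ipc) else float(ipc),
            )
        )
    return runs


def read_neg_controls(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"control_id": str})
    _require(df, ["control_id", "control_type", "m_total", "m_pos"], path)
    return df


def read_detections(path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"sample_id": str}).set_index("sample_id")
    det_cols = [c for c in df.columns if c.startswith("det_")]
    if not det_cols:
        raise ValueError(f"{path}: no det_* columns")
    return df


def write_dataset(dataset, out_dir) -> dict[str, Path]:
    """Write the four raw input CSVs of an (attached-tables) dataset.

    Returns a mapping of table name to path. Re-reading the files with the
    ``read_*`` functions reproduces every field, including flags.
    """
    out_dir = Path(out_dir)
    out_dir.mkdir(parents=True, exist_ok=True)
    t = dataset.tables
    paths = {}

    sites = t["sites"][["site_id", "pair_id", "island_type", "area_m2"]]
    paths["sites"] = out_dir / "sites.csv"
    sites.to_csv(paths["sites"], index=False)

    samples = t["samples"].copy()
    samples["time"] = samples["time_min"].map(minutes_to_hhmm)
    samples = samples[
        ["sample_id", "site_id", "date", "time", "water_temp_c", "depth_cm", "temp_imputed"]
    ]
    paths["samples"] = out_dir / "samples.csv"
    samples.to_csv(paths["samples"], index=False)

    paths["replicates"] = out_dir / "replicates.csv"
    t["replicates"].to_csv(paths["replicates"], index=False)
    paths["neg_controls"] = out_dir / "neg_controls.csv"
    t["neg_controls"].to_csv(paths["neg_controls"], index=False)
    return paths
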