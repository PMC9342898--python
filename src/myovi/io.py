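"""CSV/JSON readers and writers for the pipeline's file interfaces."""

from __future__ import annotations

import json
from pathlib import Path
from typing import Optional

import pandas as pd
from shapely.geometry import Polygon, shape

from .smlm_cluster import LocalizationTable
from .transient_fit import FluorescenceTrace

__all__ = [
    "read_trace",
    "write_trace",
    "read_localizations",
    "read_tracks",
    "read_roi",
]


def read_trace(path) -> FluorescenceTrace:
    """Read a stopped-flow trace CSV (time_s, signal) with a JSON sidecar."""
    path = Path(path)
    df = pd.read_csv(path)
    meta = {}
    sidecar = path.with_suffix(".json")
    if sidecar.exists():
        meta = json.loads(sidecar.read_text())
    return FluorescenceTrace(
        time=df["time_s"].to_numpy(),
        signal=df["signal"].to_numpy(),
        probe=meta.get("probe", ""),
        partner_conc=meta.get("partner_conc_uM", float("nan")),
        dead_time=meta.get("dead_time_s", 0.002),
    )


def write_trace(trace: FluorescenceTrace, path) -> None:
    path = Path(path)
    path.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame({"time_s": trace.time, "signal": trace.signal}).to_csv(path, index=False)
    path.with_suffix(".json").write_text(
        json.dumps(
            {
                "probe": trace.probe,
                "partner_conc_uM": trace.partner_conc,
                "dead_time_s": trace.dead_time,
            },
            indent=2,
        )
    )


def read_roi(path) -> Polygon:
    """ROI polygon from GeoJSON-style {"type": "Polygon", "coordinates": ...}."""
    return shape(json.loads(Path(path).read_text()))


def read_localizations(path, roi: Optional[Polygon] = None) -> LocalizationTable:
    """ThunderSTORM-style localization CSV -> LocalizationTable.

    Accepts either the pipeline's native columns (x, y, precision,
    channel, frame) or ThunderSTORM headers like ``x [nm]``.
    """
    df = pd.read_csv(path)
    rename = {}
    for col in df.columns:
        base = col.split("[")[0].strip().lower()
        if base in ("x", "y", "precision", "channel", "frame", "uncertainty"):
            rename[col] = "precision" if base == "uncertainty" else base
    df = df.rename(columns=rename)
    if "channel" not in df.columns:
        df["channel"] = 1
    return LocalizationTable(df, roi=roi)


def read_tracks(path) -> pd.DataFrame:
    """Trajectory CSV with columns track_id, frame, t_s, x_um, y_um, z_um."""
    df = pd.read_csv(path)
    required = {"track_id", "frame", "t_s", "x_um", "y_um", "z_um"}
    missing = required - set(df.columns)
    if missing:
        raise ValueError(f"trajectory table missing columns: {sorted(missing)}")
    return df
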