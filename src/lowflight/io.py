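"""Delimited-text I/O for tracks, bird metadata, feature tables and models.

External fix schema (CSV, header required): ``bird_id, timestamp
(ISO-8601 UTC), x, y, altitude, altitude_datum {msl|ellipsoid},
ground_speed_ms, hdop, position_error_m``; hdop / position_error may be
empty. Bird metadata: ``bird_id, fledge_date``.
"""

from __future__ import annotations

import json
from pathlib import Path

import pandas as pd

from .nnmodel import NetworkModel, model_from_dict, model_to_dict
from .terrain import NormStats

__all__ = [
    "write_tracks",
    "read_tracks",
    "write_birds",
    "read_birds",
    "write_norm_stats",
    "read_norm_stats",
    "save_model",
    "load_model",
]

_EXTERNAL_COLUMNS = {
    "altitude_raw": "altitude",
    "ground_speed": "ground_speed_ms",
    "position_error": "position_error_m",
}
_INTERNAL_COLUMNS = {v: k for k, v in _EXTERNAL_COLUMNS.items()}
_FIX_FIELDS = [
    "bird_id", "timestamp", "x", "y", "altitude", "altitude_datum",
    "ground_speed_ms", "hdop", "position_error_m",
]


def write_tracks(fixes: pd.DataFrame, path: str | Path) -> None:
    out = fixes.rename(columns=_EXTERNAL_COLUMNS)
    out = out[_FIX_FIELDS].copy()
    out["timestamp"] = pd.to_datetime(out["timestamp"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_tracks(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str, "altitude_datum": str})
    df["timestamp"] = pd.to_datetime(df["timestamp"], utc=True).dt.tz_localize(None)
    return df.rename(columns=_INTERNAL_COLUMNS)


def write_birds(birds: pd.DataFrame, path: str | Path) -> None:
    out = birds.copy()
    out["fledge_date"] = pd.to_datetime(out["fledge_date"]).dt.strftime("%Y-%m-%dT%H:%M:%SZ")
    out.to_csv(path, index=False)


def read_birds(path: str | Path) -> pd.DataFrame:
    df = pd.read_csv(path, dtype={"bird_id": str})
    df["fledge_date"] = pd.to_datetime(df["fledge_date"], utc=True).dt.tz_localize(None)
    return df


def write_norm_stats(stats: NormStats, path: str | Path) -> None:
    stats.to_frame().to_csv(path, index_label="variable")


def read_norm_stats(path: str | Path) -> NormStats:
    return NormStats.from_frame(pd.read_csv(path, index_col="variable"))


def save_model(model: NetworkModel, path: str | Path) -> None:
    Path(path).write_text(json.dumps(model_to_dict(model)))


def load_model(path: str | Path) -> NetworkModel:
    return model_from_dict(json.loads(Path(path).read_text()))
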