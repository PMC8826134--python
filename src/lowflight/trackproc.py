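"""GPS track cleaning: from raw fixes to the modelling dataset.

The pipeline turns heterogeneous raw telemetry into a set of daylight,
in-flight, in-region fixes with a well-defined altitude above ground level
(AGL), applying, in order:

1. completeness — drop fixes missing altitude or instantaneous ground speed;
2. datum conversion — ellipsoidal heights to sea-level heights via the
   geoid-undulation raster, then AGL = height minus terrain elevation;
3. quality — drop HDOP >= 10 (when HDOP is provided) or position error
   >= 30 m (otherwise);
4. AGL range — keep -50 m <= AGL <= 4000 m (both ends inclusive);
5. daylight — keep fixes between sunrise and sunset (geometric sun
   elevation >= 0);
6. flight — drop fixes that are simultaneously slow (< 2 m/s) and low
   (< 100 m AGL), i.e. perched birds;
7. region — keep fixes inside the study-region mask;
8. post-release — drop fixes within eight weeks (exactly 56 days) of
   fledging; the boundary instant is retained;
9. subsampling — at most one fix per bird per calendar UTC minute (the
   earliest in each minute), so 1 Hz bursts do not dominate;
10. minimum sample — drop birds with fewer than 100 surviving fixes.

All functions take and return pandas DataFrames in the fix schema
(`bird_id, timestamp, x, y, altitude_raw, altitude_datum, ground_speed,
hdop, position_error` plus derived `altitude_msl`, `agl`); every filter is
idempotent and only ever removes rows.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .raster import Raster
from .solar import is_daylight

__all__ = [
    "CleaningReport",
    "require_complete",
    "to_msl",
    "compute_agl",
    "quality_filter",
    "agl_range_filter",
    "daylight_filter",
    "flight_filter",
    "region_filter",
    "post_release_filter",
    "subsample_per_minute",
    "min_fix_filter",
    "clean_tracks",
    "MIN_FIXES",
    "POST_RELEASE_DAYS",
]

MIN_FIXES = 100
POST_RELEASE_DAYS = 56  # eight weeks
HDOP_MAX = 10.0
POSITION_ERROR_MAX = 30.0
AGL_MIN, AGL_MAX = -50.0, 4000.0
FLIGHT_SPEED = 2.0
FLIGHT_AGL = 100.0


@dataclass
class CleaningReport:
    """Per-stage audit of the cleaning pipeline.

    ``stages`` chain: the output count of each stage is the input count of
    the next.
    """

    stages: list[tuple[str, int, int]] = field(default_factory=list)
    birds_retained: list[str] = field(default_factory=list)

    def record(self, name: str, n_in: int, n_out: int) -> None:
        if n_out > n_in:
            raise ValueError(f"stage {name!r} gained rows")
        self.stages.append((name, n_in, n_out))

    def removed(self, name: str) -> int:
        for stage, n_in, n_out in self.stages:
            if stage == name:
                return n_in - n_out
        raise KeyError(name)

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame(self.stages, columns=["stage", "n_in", "n_out"])


def _as_utc_naive(ts: pd.Series) -> pd.Series:
    ts = pd.to_datetime(ts)
    if getattr(ts.dt, "tz", None) is not None:
        ts = ts.dt.tz_convert("UTC").dt.tz_localize(None)
    return ts


def require_complete(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep fixes that carry both an altitude and an instantaneous speed."""
    keep = fixes["altitude_raw"].notna() & fixes["ground_speed"].notna()
    return fixes.loc[keep]


def to_msl(fixes: pd.DataFrame, undulation: Raster | None = None) -> pd.DataFrame:
    """Convert raw altitudes to heights above mean sea level.

    Sea-level datum fixes pass through; ellipsoidal heights have the local
    geoid undulation subtracted (requires the undulation raster to cover
    every ellipsoid-datum fix).
    """
    out = fixes.copy()
    alt = out["altitude_raw"].to_numpy(dtype=float).copy()
    ell = (out["altitude_datum"] == "ellipsoid").to_numpy()
    if ell.any():
        if undulation is None:
            raise ValueError("ellipsoid-datum fixes present but no undulation raster given")
        u = undulation.sample(out.loc[ell, "x"].to_numpy(), out.loc[ell, "y"].to_numpy())
        if np.isnan(u).any():
            raise ValueError("fix outside undulation raster coverage")
        alt[ell] = alt[ell] - u
    out["altitude_msl"] = alt
    return out


def compute_agl(fixes: pd.DataFrame, dem: Raster) -> pd.DataFrame:
    """Altitude above ground: sea-level height minus terrain elevation at
    the containing DEM cell. Negative values are allowed at this stage."""
    out = fixes.copy()
    ground = dem.sample(out["x"].to_numpy(), out["y"].to_numpy())
    if np.isnan(ground).any():
        raise ValueError("fix outside DEM coverage")
    out["agl"] = out["altitude_msl"].to_numpy() - ground
    return out


def quality_filter(fixes: pd.DataFrame) -> pd.DataFrame:
    """Positional-quality cull. HDOP governs when provided (drop >= 10);
    otherwise the manufacturer position error (drop >= 30 m); fixes with
    neither field are retained."""
    hdop = fixes["hdop"].to_numpy(dtype=float)
    perr = fixes["position_error"].to_numpy(dtype=float)
    has_hdop = ~np.isnan(hdop)
    has_perr = ~np.isnan(perr)
    keep = np.ones(len(fixes), dtype=bool)
    keep[has_hdop] = hdop[has_hdop] < HDOP_MAX
    only_perr = ~has_hdop & has_perr
    keep[only_perr] = perr[only_perr] < POSITION_ERROR_MAX
    return fixes.loc[keep]


def agl_range_filter(fixes: pd.DataFrame) -> pd.DataFrame:
    """Keep fixes with AGL within [-50, 4000] m (inclusive); values outside
    are treated as altitude measurement failures."""
    agl = fixes["agl"].to_numpy(dtype=float)
    return fixes.loc[(agl >= AGL_MIN) & (agl <= AGL_MAX)]


def daylight_filter(fixes: pd.DataFrame, lat_deg: float, lon_deg: float) -> pd.DataFrame:
    """Keep fixes recorded between sunrise and sunset (geometric solar
    elevation >= 0 at the fix time)."""
    times = _as_utc_naive(fixes["timestamp"])
    keep = is_daylight(pd.DatetimeIndex(times), lat_deg, lon_deg)
    return fixes.loc[keep]


def flight_filter(fixes: pd.DataFrame) -> pd.DataFrame:
    """Drop fixes that are both slow (< 2 m/s) and low (< 100 m AGL):
    almost certainly a perched bird."""
    speed = fixes["ground_speed"].to_numpy(dtype=float)
    agl = fixes["agl"].to_numpy(dtype=float)
    return fixes.loc[~((speed < FLIGHT_SPEED) & (agl < FLIGHT_AGL))]


def region_filter(fixes: pd.DataFrame, region_mask: Raster) -> pd.DataFrame:
    """Keep fixes whose containing cell has mask value 1."""
    vals = region_mask.sample(fixes["x"].to_numpy(), fixes["y"].to_numpy())
    return fixes.loc[vals == 1]


def post_release_filter(fixes: pd.DataFrame, birds: pd.DataFrame) -> pd.DataFrame:
    """Drop fixes within eight weeks of the bird's fledging (or release)
    date; the fix exactly at fledge + 56 days is retained."""
    meta = birds.set_index("bird_id")["fledge_date"]
    present = fixes["bird_id"].unique()
    missing = [b for b in present if b not in meta.index or pd.isna(meta[b])]
    if missing:
        raise ValueError(f"missing fledge_date for bird(s): {missing}")
    cutoff = pd.to_datetime(meta.loc[fixes["bird_id"]]).to_numpy() + pd.Timedelta(
        days=POST_RELEASE_DAYS
    ).to_numpy()
    times = _as_utc_naive(fixes["timestamp"]).to_numpy()
    return fixes.loc[times >= cutoff]


def subsample_per_minute(fixes: pd.DataFrame) -> pd.DataFrame:
    """At most one fix per bird per calendar UTC minute, keeping the
    earliest fix of each minute. Run after all removal filters so that 1 Hz
    bursts do not dominate the modelling dataset."""
    if len(fixes) == 0:
        return fixes
    times = _as_utc_naive(fixes["timestamp"])
    order = np.lexsort((times.to_numpy(), fixes["bird_id"].to_numpy()))
    sorted_fixes = fixes.iloc[order]
    minute = _as_utc_naive(sorted_fixes["timestamp"]).dt.floor("min")
    first = ~pd.DataFrame(
        {"b": sorted_fixes["bird_id"].to_numpy(), "m": minute.to_numpy()}
    ).duplicated().to_numpy()
    return sorted_fixes.loc[first]


def min_fix_filter(fixes: pd.DataFrame, min_fixes: int = MIN_FIXES) -> pd.DataFrame:
    """Keep only birds with at least ``min_fixes`` surviving locations."""
    counts = fixes.groupby("bird_id").size()
    keep_birds = counts[counts >= min_fixes].index
    if len(keep_birds) == 0 and len(fixes) > 0:
        warnings.warn("no bird reaches the minimum fix count; dataset is empty")
    return fixes.loc[fixes["bird_id"].isin(keep_birds)]


def clean_tracks(
    fixes: pd.DataFrame,
    birds: pd.DataFrame,
    dem: Raster,
    undulation: Raster | None,
    region_mask: Raster,
    lat_deg: float,
    lon_deg: float,
    min_fixes: int = MIN_FIXES,
) -> tuple[pd.DataFrame, CleaningReport]:
    """Run the full cleaning pipeline and return the surviving fixes plus a
    per-stage audit report."""
    report = CleaningReport()
    df = fixes

    n = len(df)
    df = require_complete(df)
    report.record("completeness", n, len(df))

    n = len(df)
    df = to_msl(df, undulation)
    df = compute_agl(df, dem)
    report.record("datum_conversion", n, len(df))

    for name, step in (
        ("quality", quality_filter),
        ("agl_range", agl_range_filter),
        ("daylight", lambda d: daylight_filter(d, lat_deg, lon_deg)),
        ("flight", flight_filter),
        ("region", lambda d: region_filter(d, region_mask)),
        ("post_release", lambda d: post_release_filter(d, birds)),
        ("subsample", subsample_per_minute),
        ("min_fixes", lambda d: min_fix_filter(d, min_fixes)),
    ):
        n = len(df)
        df = step(df)
        report.record(name, n, len(df))

    df = df.reset_index(drop=True)
    report.birds_retained = sorted(df["bird_id"].unique().tolist())
    return df, report
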