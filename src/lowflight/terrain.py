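"""Terrain predictors, feature encoding and the collinearity screen.

Derives the topographic predictor bands from the elevation model (slope,
eastness/northness, topographic position index, slope unevenness), resamples
the coarse wind band onto the native grid, joins GPS fixes to the band stack
and encodes them into the classifier's feature space: 10 land-cover
indicators + 4 geology indicators + 8 z-scored continuous variables.

Feature column order is a contract (generating coefficient vectors and
permutation groups rely on it): see :data:`FEATURE_COLUMNS`.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import pandas as pd
from scipy.interpolate import RegularGridInterpolator
from scipy.stats import spearmanr

from .raster import Raster, RasterError

__all__ = [
    "LANDCOVER_CLASSES",
    "GEOLOGY_CLASSES",
    "CONTINUOUS_VARS",
    "FEATURE_COLUMNS",
    "EnvStack",
    "NormStats",
    "slope_aspect",
    "tpi",
    "slope_unevenness",
    "resample_wind",
    "complete_stack",
    "encode_features",
    "extract_features",
    "stack_features",
    "fit_normalizer",
    "apply_normalizer",
    "collinearity_screen",
]

# Land cover: 1 orchards, 2 forest, 3 bush, 4 scree, 5 anthropic, 6 marshland,
# 7 water, 8 rock, 9 glacier, 10 other. Geology: 1 limestone, 2 granite,
# 3 gneiss, 4 other substrates.
LANDCOVER_CLASSES = tuple(range(1, 11))
GEOLOGY_CLASSES = tuple(range(1, 5))
CONTINUOUS_VARS = (
    "eastness",
    "northness",
    "slope",
    "slope_unev",
    "tpi",
    "ibex",
    "chamois",
    "windspeed",
)
FEATURE_COLUMNS = (
    tuple(f"landcover_{c}" for c in LANDCOVER_CLASSES)
    + tuple(f"geology_{c}" for c in GEOLOGY_CLASSES)
    + CONTINUOUS_VARS
)

#: altitude (m above ground) below which a fix counts as within the
#: rotor-swept band; "below" is read strictly, so agl == CRITICAL_AGL is class 0.
CRITICAL_AGL = 200.0


@dataclass
class EnvStack:
    """Named, co-registered predictor bands on one grid.

    ``wind_100m`` (the coarse native-resolution wind band) is the only band
    allowed on a different grid; :func:`resample_wind` brings it onto the
    stack grid as ``windspeed``.
    """

    bands: dict[str, Raster]

    def __post_init__(self) -> None:
        ref = self.reference
        for name, band in self.bands.items():
            if name == "wind_100m":
                continue
            if not band.same_grid(ref):
                raise RasterError(f"band {name!r} is not co-registered with the stack")

    @property
    def reference(self) -> Raster:
        for name, band in self.bands.items():
            if name != "wind_100m":
                return band
        raise RasterError("empty stack")

    def __getitem__(self, name: str) -> Raster:
        return self.bands[name]

    def __contains__(self, name: str) -> bool:
        return name in self.bands


# ---------------------------------------------------------------------------
# derived topographic bands
# ---------------------------------------------------------------------------

def _neighbour_views(z: np.ndarray):
    """The eight 3x3-neighbour views of the interior of ``z``."""
    return {
        "nw": z[:-2, :-2], "n": z[:-2, 1:-1], "ne": z[:-2, 2:],
        "w": z[1:-1, :-2], "e": z[1:-1, 2:],
        "sw": z[2:, :-2], "s": z[2:, 1:-1], "se": z[2:, 2:],
    }


def slope_aspect(dem: Raster) -> tuple[Raster, Raster, Raster]:
    """Slope (degrees) and aspect encoded as eastness/northness.

    Uses Horn's 3x3 weighted finite differences. Aspect is the downslope
    direction measured clockwise from north; eastness = sin(aspect),
    northness = cos(aspect). Flat cells get eastness = northness = 0;
    border cells and cells touching nodata are nodata.
    """
    if dem.nrows < 3 or dem.ncols < 3:
        raise RasterError("slope/aspect need at least a 3x3 grid")
    z = dem.data
    v = _neighbour_views(z)
    # x: easting; y: northing (row 0 is north, so northward is decreasing row)
    dzdx = ((v["ne"] + 2 * v["e"] + v["se"]) - (v["nw"] + 2 * v["w"] + v["sw"])) / (8 * dem.cell)
    dzdy = ((v["nw"] + 2 * v["n"] + v["ne"]) - (v["sw"] + 2 * v["s"] + v["se"])) / (8 * dem.cell)

    slope_deg = np.degrees(np.arctan(np.hypot(dzdx, dzdy)))
    flat = (dzdx == 0) & (dzdy == 0)
    with np.errstate(invalid="ignore"):
        aspect = np.arctan2(-dzdx, -dzdy)  # direction of steepest descent
    east = np.where(flat, 0.0, np.sin(aspect))
    north = np.where(flat, 0.0, np.cos(aspect))
    nanmask = np.isnan(dzdx) | np.isnan(dzdy)
    east = np.where(nanmask, np.nan, east)
    north = np.where(nanmask, np.nan, north)

    def pad(interior: np.ndarray) -> np.ndarray:
        out = np.full(z.shape, np.nan)
        out[1:-1, 1:-1] = interior
        return out

    return dem.copy_with(pad(slope_deg)), dem.copy_with(pad(east)), dem.copy_with(pad(north))


def tpi(dem: Raster) -> Raster:
    """Topographic position index: cell value minus the mean of its eight
    neighbours (nine-pixel moving window, centre excluded)."""
    if dem.nrows < 3 or dem.ncols < 3:
        raise RasterError("tpi needs at least a 3x3 grid")
    z = dem.data
    v = _neighbour_views(z)
    neigh_mean = sum(v.values()) / 8.0
    out = np.full(z.shape, np.nan)
    out[1:-1, 1:-1] = z[1:-1, 1:-1] - neigh_mean
    return dem.copy_with(out)


def slope_unevenness(slope_raster: Raster) -> Raster:
    """Local slope relative to surrounding slope: the TPI operator applied
    to the slope band."""
    return tpi(slope_raster)


def resample_wind(wind: Raster, target: Raster) -> Raster:
    """Bilinearly resample the coarse wind band onto ``target``'s grid.

    Values are interpolated between coarse cell centres (clamped at the
    edges), so the output range never exceeds the input range.
    """
    if wind.cell <= target.cell:
        raise RasterError("wind grid must be coarser than the target grid")
    txmin, tymin, txmax, tymax = target.bounds
    wxmin, wymin, wxmax, wymax = wind.bounds
    tol = wind.cell  # allow edge clamping within one coarse cell
    if txmin < wxmin - tol or txmax > wxmax + tol or tymin < wymin - tol or tymax > wymax + tol:
        raise RasterError("wind band does not cover the target grid")

    # coarse cell-centre axes, increasing
    yc = wind.y0 - (np.arange(wind.nrows) + 0.5) * wind.cell  # decreasing
    xc = wind.x0 + (np.arange(wind.ncols) + 0.5) * wind.cell
    interp = RegularGridInterpolator(
        (yc[::-1], xc), wind.data[::-1, :], method="linear", bounds_error=False
    )
    ty = target.y0 - (np.arange(target.nrows) + 0.5) * target.cell
    tx = target.x0 + (np.arange(target.ncols) + 0.5) * target.cell
    ty_clamped = np.clip(ty, yc[-1], yc[0])
    tx_clamped = np.clip(tx, xc[0], xc[-1])
    yy, xx = np.meshgrid(ty_clamped, tx_clamped, indexing="ij")
    out = interp(np.column_stack([yy.ravel(), xx.ravel()])).reshape(target.data.shape)
    return target.copy_with(out)


def complete_stack(stack: EnvStack) -> EnvStack:
    """Add the derived topographic bands and the resampled wind band to a
    stack holding elevation, landcover, geology, ibex, chamois, wind_100m."""
    bands = dict(stack.bands)
    slope, east, north = slope_aspect(stack["elevation"])
    bands["slope"] = slope
    bands["eastness"] = east
    bands["northness"] = north
    bands["tpi"] = tpi(stack["elevation"])
    bands["slope_unev"] = slope_unevenness(slope)
    if "windspeed" not in bands and "wind_100m" in bands:
        bands["windspeed"] = resample_wind(stack["wind_100m"], stack.reference)
    return EnvStack(bands)


# ---------------------------------------------------------------------------
# feature encoding
# ---------------------------------------------------------------------------

def encode_features(band_values: pd.DataFrame) -> pd.DataFrame:
    """One-hot encode landcover/geology and assemble the 22 feature columns.

    ``band_values`` must hold columns ``landcover``, ``geology`` and the
    eight continuous variables; the result has exactly the columns of
    :data:`FEATURE_COLUMNS`, in that order, unnormalized.
    """
    n = len(band_values)
    out = pd.DataFrame(index=band_values.index)
    lc = band_values["landcover"].to_numpy()
    geo = band_values["geology"].to_numpy()
    if not np.all(np.isin(lc, LANDCOVER_CLASSES)):
        raise ValueError("landcover codes outside 1..10")
    if not np.all(np.isin(geo, GEOLOGY_CLASSES)):
        raise ValueError("geology codes outside 1..4")
    for c in LANDCOVER_CLASSES:
        out[f"landcover_{c}"] = (lc == c).astype(float)
    for c in GEOLOGY_CLASSES:
        out[f"geology_{c}"] = (geo == c).astype(float)
    for name in CONTINUOUS_VARS:
        out[name] = band_values[name].to_numpy(dtype=float)
    assert out.shape == (n, len(FEATURE_COLUMNS))
    return out


_BAND_ORDER = ("landcover", "geology") + CONTINUOUS_VARS


def _sample_bands(env: EnvStack, x: np.ndarray, y: np.ndarray) -> pd.DataFrame:
    return pd.DataFrame({name: env[name].sample(x, y) for name in _BAND_ORDER})


def extract_features(fixes: pd.DataFrame, env: EnvStack) -> pd.DataFrame:
    """Join cleaned fixes to the band stack and encode them.

    Returns a frame with the 22 feature columns plus ``label`` (1 if
    ``agl`` < 200 m, else 0) and carried-through ``bird_id``, ``x``, ``y``
    (and ``fix_id`` when present). Rows landing on any nodata cell are
    dropped; the count is recorded in ``result.attrs['n_dropped']``.
    """
    x = fixes["x"].to_numpy(dtype=float)
    y = fixes["y"].to_numpy(dtype=float)
    raw = _sample_bands(env, x, y)
    valid = ~raw.isna().any(axis=1).to_numpy()
    feats = encode_features(raw.loc[valid].reset_index(drop=True))
    kept = fixes.loc[fixes.index[valid]].reset_index(drop=True)
    feats["label"] = (kept["agl"].to_numpy(dtype=float) < CRITICAL_AGL).astype(int)
    for col in ("bird_id", "fix_id", "x", "y"):
        if col in kept.columns:
            feats[col] = kept[col].to_numpy()
    feats.attrs["n_dropped"] = int((~valid).sum())
    return feats


def stack_features(env: EnvStack) -> tuple[pd.DataFrame, np.ndarray, np.ndarray]:
    """Encode every cell of the stack with at least one valid value in all
    bands. Returns (features, rows, cols) with rows/cols indexing the grid
    cells each feature row came from."""
    ref = env.reference
    arrays = {name: env[name].data.ravel() for name in _BAND_ORDER}
    raw = pd.DataFrame(arrays)
    valid = ~raw.isna().any(axis=1).to_numpy()
    feats = encode_features(raw.loc[valid].reset_index(drop=True))
    idx = np.flatnonzero(valid)
    rows, cols = np.divmod(idx, ref.ncols)
    return feats, rows, cols


@dataclass
class NormStats:
    """Training-split mean/sd of the continuous feature columns."""

    mean: pd.Series
    sd: pd.Series

    def to_frame(self) -> pd.DataFrame:
        return pd.DataFrame({"mean": self.mean, "sd": self.sd})

    @classmethod
    def from_frame(cls, frame: pd.DataFrame) -> "NormStats":
        return cls(mean=frame["mean"], sd=frame["sd"])


def fit_normalizer(train_rows: pd.DataFrame) -> NormStats:
    """Mean/sd of the 8 continuous columns, from the training split only."""
    if len(train_rows) == 0:
        raise ValueError("empty training split")
    cols = list(CONTINUOUS_VARS)
    mean = train_rows[cols].mean()
    sd = train_rows[cols].std(ddof=0)
    zero = sd[sd == 0]
    if len(zero):
        raise ValueError(f"zero-variance continuous column(s): {list(zero.index)}")
    return NormStats(mean=mean, sd=sd)


def apply_normalizer(rows: pd.DataFrame, stats: NormStats) -> pd.DataFrame:
    """z-score the continuous columns with the stored training statistics;
    indicator columns pass through unchanged."""
    out = rows.copy()
    cols = list(CONTINUOUS_VARS)
    out[cols] = (out[cols] - stats.mean[cols]) / stats.sd[cols]
    return out


def collinearity_screen(
    env: EnvStack, n_samples: int = 10_000, threshold: float = 0.6, seed: int = 0
) -> pd.DataFrame:
    """Pairwise Spearman correlations of the continuous bands at random cells.

    Samples ``n_samples`` non-nodata cells (with replacement if the grid is
    small) and reports |r_s| for every pair; pairs at or above ``threshold``
    are flagged in the ``flagged`` column.
    """
    names = [v for v in CONTINUOUS_VARS if v in env]
    if len(names) < 2:
        raise ValueError("need at least two continuous bands to screen")
    frame = pd.DataFrame({name: env[name].data.ravel() for name in names}).dropna()
    rng = np.random.default_rng(seed)
    idx = rng.choice(len(frame), size=min(n_samples, len(frame)), replace=len(frame) < n_samples)
    sample = frame.iloc[idx]
    records = []
    for i, a in enumerate(names):
        for b in names[i + 1:]:
            rs = spearmanr(sample[a], sample[b]).statistic
            records.append({"var_a": a, "var_b": b, "r_s": rs, "flagged": abs(rs) >= threshold})
    return pd.DataFrame.from_records(records)
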