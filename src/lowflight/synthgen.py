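"""Synthetic world generator: terrain, predictor bands and GPS tracks.

Every downstream stage of the pipeline — cleaning, feature extraction,
network training, cross-validation and risk mapping — is exercised against
data produced here, with a *known* generating process: the probability that
a fix lies below the 200 m rotor-swept band is an exact logistic function of
the encoded environmental features at the fix location.

The generator emulates the heterogeneity of real raptor telemetry: mixed
fix schedules (1 Hz bursts vs. sparse sampling), two altitude datums
(sea-level vs. ellipsoidal heights plus a smooth geoid-undulation field),
vertical GPS noise, and contamination with night fixes, perched fixes,
poor-quality fixes, fixes within eight weeks of fledging and out-of-region
fixes, each at a configurable rate. All outputs are pure functions of the
configuration (including its seed).
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.ndimage import gaussian_filter
from scipy.special import expit

from .raster import Raster
from .terrain import (
    CONTINUOUS_VARS,
    FEATURE_COLUMNS,
    EnvStack,
    complete_stack,
    encode_features,
    stack_features,
)

__all__ = [
    "InvalidConfigError",
    "WorldConfig",
    "SyntheticTruth",
    "default_beta",
    "generate_dem",
    "generate_env_stack",
    "generate_tracks",
    "generate_world",
    "bayes_auc",
]


class InvalidConfigError(ValueError):
    pass


def default_beta() -> np.ndarray:
    """Default generating coefficients, one per encoded feature column.

    Slope carries by far the largest continuous coefficient so that it is
    the dominant driver of low flight (steep terrain means orographic
    updraught and low ground clearance); ibex occurrence and wind speed
    contribute positively, northness negatively (south-facing aspect
    favours thermals). Land-cover effects favour rock and scree over
    forest and water.
    """
    lc = [0.0, -0.8, -0.3, 0.6, -0.5, -0.3, -0.8, 0.7, 0.2, 0.0]
    geo = [0.2, 0.1, -0.1, 0.0]
    cont = {
        "eastness": 0.2,
        "northness": -0.5,
        "slope": 1.3,
        "slope_unev": 0.2,
        "tpi": 0.2,
        "ibex": 0.8,
        "chamois": 0.2,
        "windspeed": 0.6,
    }
    return np.array(lc + geo + [cont[v] for v in CONTINUOUS_VARS], dtype=float)


@dataclass
class WorldConfig:
    """Configuration of the synthetic world.

    Contamination rates are fractions of each bird's fixes; the disjoint
    contaminated subsets are injected so that each kind is removed by
    exactly one cleaning stage, which makes the cleaning audit exact.
    """

    grid_rows: int = 200
    grid_cols: int = 200
    cell_size: float = 25.0
    relief_amplitude: float = 1500.0
    smoothing_scale: float = 500.0
    base_elevation: float = 1200.0
    n_birds: int = 25
    fixes_per_bird: int = 2000
    burst_fraction: float = 0.4
    night_fraction: float = 0.12
    perched_fraction: float = 0.08
    bad_quality_fraction: float = 0.05
    early_fraction: float = 0.03
    offregion_fraction: float = 0.03
    vertical_noise_sd: float = 10.0
    ibex_elev_coupling: float = 1.0
    beta: np.ndarray = field(default_factory=default_beta)
    # default intercept puts ~74% of clean fixes below the critical
    # altitude, the share observed in Alpine bearded vulture telemetry
    intercept: float = 1.8
    region_margin_cells: int = 8
    lat0: float = 46.5
    lon0: float = 8.0
    start_date: str = "2024-06-01"
    seed: int = 0

    def validate(self) -> None:
        if self.grid_rows <= 0 or self.grid_cols <= 0:
            raise InvalidConfigError("grid dimensions must be positive")
        if self.cell_size <= 0:
            raise InvalidConfigError("cell_size must be positive")
        if self.n_birds <= 0 or self.fixes_per_bird <= 0:
            raise InvalidConfigError("n_birds and fixes_per_bird must be positive")
        for name in (
            "burst_fraction",
            "night_fraction",
            "perched_fraction",
            "bad_quality_fraction",
            "early_fraction",
            "offregion_fraction",
        ):
            v = getattr(self, name)
            if not 0.0 <= v <= 1.0:
                raise InvalidConfigError(f"{name} must be in [0, 1], got {v}")
        total = (
            self.night_fraction
            + self.perched_fraction
            + self.bad_quality_fraction
            + self.early_fraction
            + self.offregion_fraction
        )
        if total > 1.0:
            raise InvalidConfigError("contamination fractions sum to more than 1")
        beta = np.asarray(self.beta, dtype=float)
        if beta.shape != (len(FEATURE_COLUMNS),):
            raise InvalidConfigError(
                f"beta must have {len(FEATURE_COLUMNS)} entries, got {beta.shape}"
            )

    def with_seed(self, seed: int) -> "WorldConfig":
        return replace(self, seed=seed)


@dataclass
class SyntheticTruth:
    """Ground truth of the generating process.

    ``frame`` has one row per generated fix: the true low-flight
    probability (NaN where the fix sits on cells without full predictor
    coverage), the sampled binary label, and the contamination tag.
    ``bayes_auc`` is the Monte-Carlo achievable discrimination: the AUC of
    the true probabilities against labels re-drawn from them, averaged over
    draws, computed on the clean fixes.
    """

    frame: pd.DataFrame
    beta: np.ndarray
    intercept: float
    bayes_auc: float
    feature_mean: pd.Series
    feature_sd: pd.Series


# ---------------------------------------------------------------------------
# rasters
# ---------------------------------------------------------------------------

_STREAMS = {
    "dem": 1, "undulation": 2, "landcover": 3, "geology": 4,
    "ibex": 5, "chamois": 6, "wind": 7, "tracks": 8, "bayes": 9,
}


def _rng(cfg: WorldConfig, stream: str) -> np.random.Generator:
    return np.random.default_rng([_STREAMS[stream], cfg.seed])


def _smooth_field(rng: np.random.Generator, rows: int, cols: int, sigma_cells: float) -> np.ndarray:
    """Autocorrelated standard field: Gaussian-filtered white noise,
    re-standardized to zero mean, unit sd."""
    noise = rng.standard_normal((rows, cols))
    if sigma_cells > 0:
        noise = gaussian_filter(noise, sigma=sigma_cells, mode="reflect")
    sd = noise.std()
    if sd > 0:
        noise = (noise - noise.mean()) / sd
    return noise


def generate_dem(cfg: WorldConfig) -> Raster:
    """Smoothed random elevation field scaled to the configured relief."""
    cfg.validate()
    rng = _rng(cfg, "dem")
    sigma = cfg.smoothing_scale / cfg.cell_size
    f = _smooth_field(rng, cfg.grid_rows, cfg.grid_cols, sigma)
    lo, hi = f.min(), f.max()
    if cfg.relief_amplitude == 0 or hi == lo:
        data = np.full((cfg.grid_rows, cfg.grid_cols), cfg.base_elevation)
    else:
        data = cfg.base_elevation + (f - lo) / (hi - lo) * cfg.relief_amplitude
    return Raster(data, x0=0.0, y0=cfg.grid_rows * cfg.cell_size, cell=cfg.cell_size)


def _classify(field_: np.ndarray, n_classes: int) -> np.ndarray:
    """Quantile-bin a continuous field into codes 1..n_classes."""
    qs = np.quantile(field_, np.linspace(0, 1, n_classes + 1)[1:-1])
    return np.digitize(field_, qs) + 1


def generate_env_stack(cfg: WorldConfig, dem: Raster) -> EnvStack:
    """Generate the predictor bands on the DEM grid.

    Land cover (10 codes) and geology (4 codes) are quantile-binned smooth
    fields (land cover partly driven by elevation); ibex and chamois are
    logistic transforms of elevation plus smooth noise, with ibex coupled
    to elevation by ``cfg.ibex_elev_coupling``; wind speed is generated on
    a 4x coarser grid (``wind_100m``) and left for resampling. The region
    mask (1 inside the study region) and the geoid undulation field ride
    along as extra bands.
    """
    cfg.validate()
    rows, cols, cell = cfg.grid_rows, cfg.grid_cols, cfg.cell_size
    sigma = cfg.smoothing_scale / cell
    z = dem.data
    zsd = z.std()
    z_std = (z - z.mean()) / zsd if zsd > 0 else np.zeros_like(z)

    lc_field = 0.6 * z_std + _smooth_field(_rng(cfg, "landcover"), rows, cols, sigma / 2)
    landcover = dem.copy_with(_classify(lc_field, 10).astype(float))
    geo_field = _smooth_field(_rng(cfg, "geology"), rows, cols, sigma)
    geology = dem.copy_with(_classify(geo_field, 4).astype(float))

    ibex = dem.copy_with(
        expit(cfg.ibex_elev_coupling * z_std + 0.8 * _smooth_field(_rng(cfg, "ibex"), rows, cols, sigma))
    )
    chamois = dem.copy_with(
        expit(0.3 * z_std + _smooth_field(_rng(cfg, "chamois"), rows, cols, sigma))
    )

    coarse = 4
    crows, ccols = -(-rows // coarse), -(-cols // coarse)
    wfield = _smooth_field(_rng(cfg, "wind"), crows, ccols, sigma / coarse)
    wind = Raster(
        np.clip(5.0 + 2.0 * wfield, 0.0, None),
        x0=dem.x0, y0=dem.y0, cell=cell * coarse,
    )

    ufield = _smooth_field(_rng(cfg, "undulation"), rows, cols, sigma)
    undul = dem.copy_with(60.0 * ufield / max(np.abs(ufield).max(), 1e-12))

    mask = np.zeros((rows, cols))
    m = cfg.region_margin_cells
    if rows > 2 * m and cols > 2 * m:
        mask[m:rows - m, m:cols - m] = 1.0
    else:
        mask[:] = 1.0
    region = dem.copy_with(mask)

    return EnvStack({
        "elevation": dem,
        "landcover": landcover,
        "geology": geology,
        "ibex": ibex,
        "chamois": chamois,
        "wind_100m": wind,
        "undulation": undul,
        "region_mask": region,
    })


# ---------------------------------------------------------------------------
# tracks
# ---------------------------------------------------------------------------

_DAY_START, _DAY_END = 9.5, 15.5  # UTC hours of the base fix window

CONTAMINATION_KINDS = ("none", "night", "perched", "quality", "early", "offregion")


def _bird_times(rng: np.random.Generator, n: int, burst: bool, day0: pd.Timestamp) -> pd.DatetimeIndex:
    """Chronological fix times within daily 09:30-15:30 UTC windows."""
    seconds: list[float] = []
    t = _DAY_START * 3600.0
    day = 0
    i = 0
    while i < n:
        if burst and rng.random() < 0.5:
            length = int(rng.integers(30, 61))
            for _ in range(min(length, n - i)):
                seconds.append(day * 86400 + t)
                t += 1.0
                i += 1
                if t > _DAY_END * 3600:
                    day += 1
                    t = _DAY_START * 3600.0
            t += rng.uniform(120, 600)
        else:
            seconds.append(day * 86400 + t)
            i += 1
            t += rng.uniform(60, 300) if burst else rng.uniform(60, 900)
        if t > _DAY_END * 3600:
            day += 1
            t = _DAY_START * 3600.0
    return day0 + pd.to_timedelta(np.round(seconds, 0), unit="s")


def generate_tracks(
    cfg: WorldConfig, env: EnvStack
) -> tuple[pd.DataFrame, pd.DataFrame, SyntheticTruth]:
    """Generate per-bird GPS fixes with a known low-flight process.

    Returns ``(fixes, birds, truth)``: the fix table (one row per generated
    fix, in the external delimited-text schema plus ``fix_id`` and
    ``contamination`` bookkeeping columns), the bird metadata table
    (``bird_id``, ``fledge_date``) and the :class:`SyntheticTruth`.

    Clean fixes sit on in-region cells with full predictor coverage, in
    daylight, with flying speeds; their true altitude above ground is drawn
    uniformly on [0, 200) m when the sampled label is 1 and on [200, 1500) m
    otherwise. Contaminated subsets (disjoint, per bird) are altered so that
    each is caught by exactly one cleaning stage.
    """
    cfg.validate()
    if "slope" not in env:
        env = complete_stack(env)
    for required in ("undulation", "region_mask"):
        if required not in env:
            raise InvalidConfigError(f"env stack lacks the {required!r} band")

    rng = _rng(cfg, "tracks")
    ref = env.reference

    feats_all, rows_all, cols_all = stack_features(env)
    in_region = env["region_mask"].data[rows_all, cols_all] == 1
    feats_region = feats_all.loc[np.flatnonzero(in_region)].reset_index(drop=True)
    if len(feats_region) == 0:
        raise InvalidConfigError("no in-region cells with full predictor coverage")
    rows_region, cols_region = rows_all[in_region], cols_all[in_region]
    mean = feats_region[list(CONTINUOUS_VARS)].mean()
    sd = feats_region[list(CONTINUOUS_VARS)].std(ddof=0).replace(0.0, 1.0)

    z = feats_region.copy()
    z[list(CONTINUOUS_VARS)] = (z[list(CONTINUOUS_VARS)] - mean) / sd
    beta = np.asarray(cfg.beta, dtype=float)
    cell_logit = z[list(FEATURE_COLUMNS)].to_numpy() @ beta + cfg.intercept
    cell_p = expit(cell_logit)

    offmask = env["region_mask"].data == 0
    off_rows, off_cols = np.nonzero(offmask)

    n = cfg.fixes_per_bird
    day0 = pd.Timestamp(cfg.start_date)
    n_burst_birds = int(round(cfg.burst_fraction * cfg.n_birds))

    fix_frames = []
    bird_records = []
    fid0 = 0
    for b in range(cfg.n_birds):
        bird_id = f"SB{b + 1:03d}"
        burst = b < n_burst_birds
        uses_hdop = bool(rng.random() < 0.5)
        datum = "msl" if rng.random() < 0.5 else "ellipsoid"
        times = _bird_times(rng, n, burst, day0 + pd.Timedelta(days=int(rng.integers(0, 15))))

        # contamination bookkeeping: disjoint subsets; the first k_early
        # chronological fixes are the pre-fledging ones so that a single
        # time threshold removes exactly them.
        k_early = int(np.floor(cfg.early_fraction * n))
        kinds = np.array(["none"] * n, dtype=object)
        kinds[:k_early] = "early"
        rest = rng.permutation(np.arange(k_early, n))
        k_night = int(np.floor(cfg.night_fraction * n))
        k_perch = int(np.floor(cfg.perched_fraction * n))
        k_qual = int(np.floor(cfg.bad_quality_fraction * n))
        k_off = int(np.floor(cfg.offregion_fraction * n))
        pos = 0
        for kind, k in (("night", k_night), ("perched", k_perch),
                        ("quality", k_qual), ("offregion", k_off)):
            kinds[rest[pos:pos + k]] = kind
            pos += k

        cells = rng.integers(0, len(feats_region), size=n)
        p_true = cell_p[cells].copy()
        labels = (rng.random(n) < p_true).astype(int)
        agl = np.where(labels == 1, rng.uniform(0, 200, n), rng.uniform(200, 1500, n))
        speed = rng.uniform(2.0, 25.0, n)
        r_idx, c_idx = rows_region[cells], cols_region[cells]

        # perched: stationary on the ground, caught by the flight filter
        perched = kinds == "perched"
        speed[perched] = rng.uniform(0.0, 1.9, perched.sum())
        agl[perched] = rng.uniform(5.0, 60.0, perched.sum())
        labels[perched] = 1

        # night: same clean location, timestamp moved to local night
        night = kinds == "night"
        if night.any():
            night_hours = rng.uniform(23.0, 26.0, night.sum())
            base_days = times[night].normalize()
            times = times.to_numpy()
            times[night] = base_days.to_numpy() + (night_hours * 3600).astype("timedelta64[s]")
            times = pd.DatetimeIndex(times)

        # offregion: relocate to masked-out cells
        off = kinds == "offregion"
        if off.any():
            if len(off_rows) == 0:
                raise InvalidConfigError("offregion_fraction > 0 but the region mask has no zero cells")
            pick = rng.integers(0, len(off_rows), size=off.sum())
            r_idx = r_idx.copy(); c_idx = c_idx.copy()
            r_idx[off] = off_rows[pick]
            c_idx[off] = off_cols[pick]
            p_true[off] = np.nan

        xc, yc = ref.cell_center(r_idx, c_idx)
        x = xc + rng.uniform(-0.49, 0.49, n) * ref.cell
        y = yc + rng.uniform(-0.49, 0.49, n) * ref.cell

        ground = env["elevation"].data[r_idx, c_idx]
        alt_msl = ground + agl + rng.normal(0.0, cfg.vertical_noise_sd, n)
        undul = env["undulation"].data[r_idx, c_idx]
        alt_raw = alt_msl if datum == "msl" else alt_msl + undul

        hdop = np.full(n, np.nan)
        perr = np.full(n, np.nan)
        qual = kinds == "quality"
        if uses_hdop:
            hdop[:] = rng.uniform(0.5, 5.0, n)
            hdop[qual] = rng.uniform(10.0, 25.0, qual.sum())
        else:
            perr[:] = rng.uniform(3.0, 20.0, n)
            perr[qual] = rng.uniform(30.0, 120.0, qual.sum())

        # exact instant so that the eight-week cut removes precisely the
        # designated pre-fledging fixes (synthetic fledge "dates" carry a
        # time of day for this reason)
        fledge = (times[k_early] - pd.Timedelta(days=56)) if k_early > 0 \
            else (times[0] - pd.Timedelta(days=70))
        bird_records.append({"bird_id": bird_id, "fledge_date": fledge})

        fix_frames.append(pd.DataFrame({
            "fix_id": np.arange(fid0, fid0 + n),
            "bird_id": bird_id,
            "timestamp": times,
            "x": x, "y": y,
            "altitude_raw": alt_raw,
            "altitude_datum": datum,
            "ground_speed": speed,
            "hdop": hdop,
            "position_error": perr,
            "contamination": kinds,
            "p_true": p_true,
            "label": labels,
        }))
        fid0 += n

    fixes = pd.concat(fix_frames, ignore_index=True)
    birds = pd.DataFrame.from_records(bird_records)
    truth_frame = fixes[["fix_id", "bird_id", "p_true", "label", "contamination"]].copy()
    fixes = fixes.drop(columns=["p_true", "label"])

    clean = truth_frame["contamination"] == "none"
    bauc = bayes_auc(truth_frame.loc[clean, "p_true"].to_numpy(), seed=cfg.seed)
    truth = SyntheticTruth(
        frame=truth_frame,
        beta=beta,
        intercept=cfg.intercept,
        bayes_auc=bauc,
        feature_mean=mean,
        feature_sd=sd,
    )
    return fixes, birds, truth


def bayes_auc(p_true: np.ndarray, seed: int, n_draws: int = 10) -> float:
    """Monte-Carlo achievable AUC: score = true probability, labels re-drawn
    from it ``n_draws`` times; the mean AUC over draws."""
    from .evalsuite import auc

    p_true = np.asarray(p_true, dtype=float)
    p_true = p_true[~np.isnan(p_true)]
    rng = np.random.default_rng([_STREAMS["bayes"], seed])
    vals = []
    for _ in range(n_draws):
        labels = (rng.random(p_true.shape) < p_true).astype(int)
        if labels.min() == labels.max():
            continue
        vals.append(auc(labels, p_true))
    if not vals:
        raise ValueError("degenerate generating probabilities: single-class draws")
    return float(np.mean(vals))


def generate_world(cfg: WorldConfig):
    """Convenience: DEM -> completed env stack -> tracks.

    Returns ``(env, fixes, birds, truth)`` with the stack completed
    (derived topographic bands and resampled wind included).
    """
    dem = generate_dem(cfg)
    env = complete_stack(generate_env_stack(cfg, dem))
    fixes, birds, truth = generate_tracks(cfg, env)
    return env, fixes, birds, truth
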