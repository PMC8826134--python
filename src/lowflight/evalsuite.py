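"""Model evaluation: AUC, architecture grid search, cross-validation,
permutation importance and ICE/PD effect curves.

Two complementary cross-validation designs probe generalization: leave-one-
bird-out (one fold per individual, testing transfer across animals) and
spatial block CV (square blocks randomly assigned to five folds, testing
transfer across space). Both train for a fixed 20 epochs without early
stopping, so no per-fold validation split is needed.

Permutation importance is the drop in AUC when a variable's columns are
jointly shuffled (one-hot groups move intact); reported as a relative
percentage drop by default, absolute percentage points on request.
"""

from __future__ import annotations

import itertools
import warnings
from dataclasses import dataclass, field, replace

import numpy as np
import pandas as pd
from scipy.optimize import curve_fit
from scipy.stats import rankdata

from . import nnmodel
from .nnmodel import ModelConfig, NetworkModel
from .raster import Raster
from .terrain import (
    CONTINUOUS_VARS,
    FEATURE_COLUMNS,
    GEOLOGY_CLASSES,
    LANDCOVER_CLASSES,
    EnvStack,
    NormStats,
    apply_normalizer,
    fit_normalizer,
)

__all__ = [
    "auc",
    "GridSpec",
    "enumerate_grid",
    "grid_search",
    "train_val_split",
    "CvResult",
    "loo_bird_cv",
    "estimate_block_size",
    "BlockGrid",
    "make_blocks",
    "block_cv",
    "permutation_importance",
    "VARIABLE_GROUPS",
    "HEADLINE_GROUPS",
    "EffectCurves",
    "ice_pd",
]


def auc(labels, scores) -> float:
    """Rank-based (Mann-Whitney) area under the ROC curve; ties count 1/2.

    Equals the probability that a uniformly drawn positive outscores a
    uniformly drawn negative.
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    n_pos = int((y == 1).sum())
    n_neg = int((y == 0).sum())
    if n_pos == 0 or n_neg == 0:
        raise ValueError("AUC needs both classes present")
    ranks = rankdata(s)
    return float((ranks[y == 1].sum() - n_pos * (n_pos + 1) / 2) / (n_pos * n_neg))


# ---------------------------------------------------------------------------
# splits and feature-table helpers
# ---------------------------------------------------------------------------

def train_val_split(n: int, val_fraction: float = 0.3, seed: int = 0):
    """Seeded random split over rows; returns boolean (train, val) masks."""
    rng = np.random.default_rng([2, seed])
    val = np.zeros(n, dtype=bool)
    n_val = int(round(val_fraction * n))
    val[rng.choice(n, size=n_val, replace=False)] = True
    return ~val, val


def prepare_xy(table: pd.DataFrame, stats: NormStats):
    """Normalized feature matrix and label vector from a feature table."""
    normed = apply_normalizer(table, stats)
    X = normed[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    y = table["label"].to_numpy(dtype=float)
    return X, y


# ---------------------------------------------------------------------------
# grid search
# ---------------------------------------------------------------------------

@dataclass
class GridSpec:
    """Hyperparameter grid: hidden-layer widths doubling from 16 to 512,
    dropout rate 0.2-0.7 in steps of 0.1 (216 configurations by default)."""

    units1_values: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    units2_values: tuple[int, ...] = (16, 32, 64, 128, 256, 512)
    dropout_values: tuple[float, ...] = (0.2, 0.3, 0.4, 0.5, 0.6, 0.7)

    @property
    def size(self) -> int:
        return len(self.units1_values) * len(self.units2_values) * len(self.dropout_values)


def enumerate_grid(grid: GridSpec, base_cfg: ModelConfig | None = None) -> list[ModelConfig]:
    """All configurations of the grid, in deterministic lexicographic order."""
    base = base_cfg or ModelConfig()
    return [
        replace(base, units1=u1, units2=u2, dropout_rate=d)
        for u1, u2, d in itertools.product(
            grid.units1_values, grid.units2_values, grid.dropout_values
        )
    ]


def grid_search(
    table: pd.DataFrame,
    grid: GridSpec,
    base_cfg: ModelConfig | None = None,
    seed: int = 0,
) -> tuple[pd.DataFrame, ModelConfig]:
    """Train every grid configuration on one fixed 70/30 split.

    Each configuration trains with early stopping on the shared validation
    split; results are returned sorted by validation AUC (best first),
    together with the best configuration.
    """
    configs = enumerate_grid(grid, base_cfg)
    train_mask, val_mask = train_val_split(len(table), seed=seed)
    stats = fit_normalizer(table.loc[train_mask])
    Xtr, ytr = prepare_xy(table.loc[train_mask], stats)
    Xva, yva = prepare_xy(table.loc[val_mask], stats)

    records = []
    for cfg in configs:
        model = nnmodel.init_network(cfg)
        model.norm_stats = stats
        model, log = nnmodel.train(model, Xtr, ytr, Xva, yva, cfg)
        records.append({
            "units1": cfg.units1,
            "units2": cfg.units2,
            "dropout_rate": cfg.dropout_rate,
            "train_auc": auc(ytr, nnmodel.predict(model, Xtr)),
            "val_auc": log.best_val_auc,
            "best_epoch": log.best_epoch,
        })
    results = pd.DataFrame.from_records(records).sort_values(
        "val_auc", ascending=False, kind="stable"
    ).reset_index(drop=True)
    top = results.iloc[0]
    best = replace(
        configs[0], units1=int(top["units1"]), units2=int(top["units2"]),
        dropout_rate=float(top["dropout_rate"]),
    )
    return results, best


# ---------------------------------------------------------------------------
# cross-validation
# ---------------------------------------------------------------------------

@dataclass
class CvResult:
    """Per-fold (or per-bird) train/test AUC with summary statistics."""

    frame: pd.DataFrame

    @property
    def mean_train(self) -> float:
        return float(self.frame["train_auc"].mean())

    @property
    def sd_train(self) -> float:
        return float(self.frame["train_auc"].std())

    @property
    def mean_test(self) -> float:
        return float(self.frame["test_auc"].mean())

    @property
    def sd_test(self) -> float:
        return float(self.frame["test_auc"].std())


CV_EPOCHS = 20


def _cv_fold(table, test_mask, cfg, unit_label, unit_value, n_epochs):
    train_rows = table.loc[~test_mask]
    test_rows = table.loc[test_mask]
    stats = fit_normalizer(train_rows)
    Xtr, ytr = prepare_xy(train_rows, stats)
    Xte, yte = prepare_xy(test_rows, stats)
    model = nnmodel.init_network(cfg)
    model.norm_stats = stats
    model, _ = nnmodel.train_fixed_epochs(model, Xtr, ytr, n_epochs, cfg)
    train_auc = auc(ytr, nnmodel.predict(model, Xtr))
    if yte.size == 0 or yte.min() == yte.max():
        warnings.warn(f"{unit_label} {unit_value!r}: held-out split single-class; AUC undefined")
        test_auc = np.nan
    else:
        test_auc = auc(yte, nnmodel.predict(model, Xte))
    return {
        unit_label: unit_value,
        "n_train": len(train_rows),
        "n_test": len(test_rows),
        "train_auc": train_auc,
        "test_auc": test_auc,
    }


def loo_bird_cv(table: pd.DataFrame, best_cfg: ModelConfig, n_epochs: int = CV_EPOCHS) -> CvResult:
    """Leave-one-bird-out: one model per bird, trained on all other birds
    for a fixed number of epochs, evaluated on the held-out bird."""
    birds = sorted(table["bird_id"].unique())
    if len(birds) < 2:
        raise ValueError("leave-one-bird-out needs at least two birds")
    records = []
    for bird in birds:
        test_mask = (table["bird_id"] == bird).to_numpy()
        records.append(_cv_fold(table, test_mask, best_cfg, "bird_id", bird, n_epochs))
    return CvResult(pd.DataFrame.from_records(records))


@dataclass
class BlockGrid:
    """Square spatial blocks tiling the region bounding box, each randomly
    assigned to one of ``n_folds`` cross-validation folds (balanced to
    within one block per fold)."""

    side_m: float
    block_raster: Raster
    fold_of_block: dict[int, int]
    n_folds: int

    def fold_of_points(self, x, y) -> np.ndarray:
        blocks = self.block_raster.sample(x, y).astype(int)
        return np.array([self.fold_of_block[b] for b in blocks])


def make_blocks(region_mask: Raster, side_m: float = 10_000.0, n_folds: int = 5,
                seed: int = 0) -> BlockGrid:
    """Tile the mask's bounding box with axis-aligned square blocks from its
    north-west origin (partial edge blocks kept) and assign blocks to folds
    by a seeded shuffled round-robin."""
    if side_m < region_mask.cell:
        raise ValueError("block side must be at least one cell")
    cells_per_block = side_m / region_mask.cell
    rows = np.arange(region_mask.nrows)
    cols = np.arange(region_mask.ncols)
    brow = np.floor(rows / cells_per_block).astype(int)
    bcol = np.floor(cols / cells_per_block).astype(int)
    nbx = bcol.max() + 1
    block_ids = brow[:, None] * nbx + bcol[None, :]
    n_blocks = int(block_ids.max()) + 1
    if n_blocks < n_folds:
        raise ValueError(f"only {n_blocks} blocks for {n_folds} folds; shrink the block side")
    rng = np.random.default_rng([3, seed])
    order = rng.permutation(n_blocks)
    fold_of = {int(b): int(i % n_folds) + 1 for i, b in enumerate(order)}
    raster = region_mask.copy_with(block_ids.astype(float))
    return BlockGrid(side_m, raster, fold_of, n_folds)


def block_cv(table: pd.DataFrame, blocks: BlockGrid, best_cfg: ModelConfig,
             n_epochs: int = CV_EPOCHS) -> CvResult:
    """Spatial block cross-validation: each fold's fixes held out in turn,
    models trained for a fixed number of epochs on the remaining folds."""
    folds = blocks.fold_of_points(table["x"].to_numpy(), table["y"].to_numpy())
    records = []
    for fold in range(1, blocks.n_folds + 1):
        test_mask = folds == fold
        if not test_mask.any():
            warnings.warn(f"fold {fold} holds no fixes; skipped")
            continue
        records.append(_cv_fold(table, test_mask, best_cfg, "fold", fold, n_epochs))
    return CvResult(pd.DataFrame.from_records(records))


# ---------------------------------------------------------------------------
# spatial autocorrelation range (block-size recommendation)
# ---------------------------------------------------------------------------

def estimate_block_size(env: EnvStack, n_pairs: int = 20_000, seed: int = 0):
    """Recommend a block side from the spatial autocorrelation of the
    continuous bands.

    Per band: an empirical semivariogram from randomly sampled cell pairs
    (15 log-spaced lag bins), a weighted least-squares fit of the
    exponential model ``gamma(h) = c0 + c1 (1 - exp(-h/a))``, and the
    practical range 3a. The recommendation is the median of the per-band
    ranges. Degenerate (constant) bands are skipped with a warning.
    """
    records = []
    for name in CONTINUOUS_VARS:
        if name not in env:
            continue
        band = env[name]
        vals = band.data
        if np.count_nonzero(~np.isnan(vals)) < 10 or np.nanstd(vals) == 0:
            warnings.warn(f"band {name!r} degenerate; skipped in block-size estimate")
            continue
        # the sample depends only on the grid and seed (identical bands get
        # identical pair samples); lags are drawn log-uniformly so short
        # distances are as well populated as long ones, and capped at half
        # the grid extent as standard for empirical variograms
        rng = np.random.default_rng([4, seed])
        nr, nc, cell = band.nrows, band.ncols, band.cell
        hmax = 0.5 * np.hypot(nr, nc) * cell
        r1 = rng.integers(0, nr, n_pairs)
        c1_ = rng.integers(0, nc, n_pairs)
        lag = np.exp(rng.uniform(np.log(cell), np.log(hmax), n_pairs))
        ang = rng.uniform(0, 2 * np.pi, n_pairs)
        r2 = r1 + np.rint(lag * np.sin(ang) / cell).astype(int)
        c2 = c1_ + np.rint(lag * np.cos(ang) / cell).astype(int)
        ok = (r2 >= 0) & (r2 < nr) & (c2 >= 0) & (c2 < nc) & ((r2 != r1) | (c2 != c1_))
        z1, z2 = vals[r1[ok], c1_[ok]], vals[r2[ok], c2[ok]]
        finite = ~(np.isnan(z1) | np.isnan(z2))
        h = (np.hypot(r1[ok] - r2[ok], c1_[ok] - c2[ok]) * cell)[finite]
        gamma = (0.5 * (z1 - z2) ** 2)[finite]

        edges = np.geomspace(cell, hmax + cell, 16)
        which = np.digitize(h, edges) - 1
        lags, semis, counts = [], [], []
        for b in range(15):
            m = which == b
            if m.sum() >= 10:
                lags.append(h[m].mean())
                semis.append(gamma[m].mean())
                counts.append(m.sum())
        lags, semis, counts = map(np.asarray, (lags, semis, counts))

        def model(hh, c0, c1, a):
            return c0 + c1 * (1.0 - np.exp(-hh / a))

        sill0 = semis.max()
        # initial scale: first lag where the semivariance nears its sill
        near = np.flatnonzero(semis >= 0.95 * sill0)
        a0 = max(lags[near[0]] / 3.0 if len(near) else lags.mean() / 3.0, cell / 3.0)
        try:
            popt, _ = curve_fit(
                model, lags, semis,
                p0=[semis[0] * 0.5, sill0, a0],
                sigma=1.0 / np.sqrt(counts),
                bounds=([0, 1e-12, cell / 100.0], [np.inf, np.inf, 10 * lags.max()]),
                maxfev=20_000,
            )
            c0, c1, a = popt
            sse_exp = np.sum(counts * (semis - model(lags, *popt)) ** 2)
            cbar = np.sum(counts * semis) / np.sum(counts)
            sse_const = np.sum(counts * (semis - cbar) ** 2)
            # pure nugget: the exponential model explains essentially
            # nothing beyond a constant, or its sill share is negligible
            if sse_exp > 0.95 * sse_const or c1 < 0.05 * (c0 + c1):
                practical_range = cell
            else:
                practical_range = 3.0 * a
        except RuntimeError:
            warnings.warn(f"variogram fit failed for {name!r}; skipped")
            continue
        records.append({"band": name, "range_m": float(practical_range)})
    per_band = pd.DataFrame.from_records(records)
    if len(per_band) == 0:
        raise ValueError("no band yielded a variogram range")
    return float(per_band["range_m"].median()), per_band


# ---------------------------------------------------------------------------
# permutation importance
# ---------------------------------------------------------------------------

#: one group per predictor of the band stack
VARIABLE_GROUPS: dict[str, tuple[str, ...]] = {
    "landcover": tuple(f"landcover_{c}" for c in LANDCOVER_CLASSES),
    "geology": tuple(f"geology_{c}" for c in GEOLOGY_CLASSES),
    **{v: (v,) for v in CONTINUOUS_VARS},
}

#: merged grouping used for headline rankings: aspect = eastness + northness,
#: food = ibex + chamois
HEADLINE_GROUPS: dict[str, tuple[str, ...]] = {
    "landcover": VARIABLE_GROUPS["landcover"],
    "geology": VARIABLE_GROUPS["geology"],
    "aspect": ("eastness", "northness"),
    "slope": ("slope",),
    "slope_unev": ("slope_unev",),
    "tpi": ("tpi",),
    "food": ("ibex", "chamois"),
    "windspeed": ("windspeed",),
}


def permutation_importance(
    model: NetworkModel,
    rows: np.ndarray | pd.DataFrame,
    labels: np.ndarray,
    groups: dict[str, tuple[str, ...]] | None = None,
    n_reps: int = 10,
    seed: int = 0,
    relative: bool = True,
) -> pd.DataFrame:
    """AUC drop when each variable group's columns are jointly permuted.

    ``rows`` must be normalized model inputs (a DataFrame with the feature
    columns or a bare 22-column array in :data:`FEATURE_COLUMNS` order).
    For each group and repetition one seeded row permutation is applied to
    all of the group's columns simultaneously (one-hot rows move intact);
    the reported drop is the mean over repetitions of
    ``100 * (AUC0 - AUCp) / AUC0`` (relative, default) or
    ``100 * (AUC0 - AUCp)`` percentage points (``relative=False``).
    """
    groups = groups or VARIABLE_GROUPS
    if isinstance(rows, pd.DataFrame):
        X = rows[list(FEATURE_COLUMNS)].to_numpy(dtype=float)
    else:
        X = np.asarray(rows, dtype=float)
    y = np.asarray(labels)
    col_index = {name: k for k, name in enumerate(FEATURE_COLUMNS)}
    for gname, cols in groups.items():
        unknown = [c for c in cols if c not in col_index]
        if unknown:
            raise ValueError(f"group {gname!r} names unknown column(s) {unknown}")

    auc0 = auc(y, nnmodel.predict(model, X))
    rng = np.random.default_rng([5, seed])
    records = []
    for gname, cols in groups.items():
        idx = [col_index[c] for c in cols]
        drops = []
        for _ in range(n_reps):
            perm = rng.permutation(len(X))
            Xp = X.copy()
            Xp[:, idx] = X[perm][:, idx]
            auc_p = auc(y, nnmodel.predict(model, Xp))
            drop = 100.0 * (auc0 - auc_p)
            drops.append(drop / auc0 if relative else drop)
        records.append({
            "group": gname,
            "importance": float(np.mean(drops)),
            "sd": float(np.std(drops, ddof=1)) if n_reps > 1 else 0.0,
        })
    out = pd.DataFrame.from_records(records).sort_values(
        "importance", ascending=False, kind="stable"
    ).reset_index(drop=True)
    out.attrs["auc0"] = auc0
    return out


# ---------------------------------------------------------------------------
# ICE / PD effect curves
# ---------------------------------------------------------------------------

@dataclass
class EffectCurves:
    """ICE matrix (one curve per observation) and its average, the PD curve,
    for one focal variable; grid values are on the variable's natural scale."""

    variable: str
    grid: np.ndarray
    ice: np.ndarray  # n_obs x n_grid
    pd: np.ndarray  # length n_grid

    def __post_init__(self):
        assert self.ice.shape == (self.ice.shape[0], len(self.grid))
        assert len(self.pd) == len(self.grid)


def ice_pd(
    model: NetworkModel,
    rows: pd.DataFrame,
    variable: str,
    n_grid: int = 20,
    norm_stats: NormStats | None = None,
) -> EffectCurves:
    """Individual conditional expectation and partial dependence.

    ``rows`` is a feature table on the *natural* scale (unnormalized).
    For a continuous variable the grid spans its observed range with
    ``n_grid`` equally spaced values; for ``landcover``/``geology`` the grid
    is the class code set and the whole one-hot group is switched. Each
    observation is predicted at every grid value with its other variables
    fixed; the PD curve is the exact column mean of the ICE matrix.
    """
    stats = norm_stats or model.norm_stats
    if stats is None:
        raise ValueError("normalization statistics required (pass norm_stats)")

    categorical = variable in ("landcover", "geology")
    if categorical:
        classes = LANDCOVER_CLASSES if variable == "landcover" else GEOLOGY_CLASSES
        grid = np.asarray(classes, dtype=float)
    else:
        if variable not in CONTINUOUS_VARS:
            raise ValueError(f"unknown variable {variable!r}")
        if n_grid < 2:
            raise ValueError("n_grid must be >= 2 for a continuous variable")
        lo, hi = rows[variable].min(), rows[variable].max()
        grid = np.linspace(lo, hi, n_grid)

    n_obs = len(rows)
    ice = np.empty((n_obs, len(grid)))
    for k, g in enumerate(grid):
        mod = rows.copy()
        if categorical:
            for c in (LANDCOVER_CLASSES if variable == "landcover" else GEOLOGY_CLASSES):
                mod[f"{variable}_{c}"] = float(c == g)
        else:
            mod[variable] = g
        X, _ = _rows_to_x(mod, stats)
        ice[:, k] = nnmodel.predict(model, X)
    return EffectCurves(variable, grid, ice, ice.mean(axis=0))


def _rows_to_x(rows: pd.DataFrame, stats: NormStats):
    normed = apply_normalizer(rows, stats)
    return normed[list(FEATURE_COLUMNS)].to_numpy(dtype=float), None
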