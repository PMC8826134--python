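"""Bagged probability maps, sensitivity-constrained binarization and the
conflict products.

The mapping stage projects the trained classifier to every cell of the
study area, quantifies prediction uncertainty by bootstrap aggregation
(bagging: models retrained on resamples of the training split, cellwise
mean plus a 95% percentile interval), converts the probability surface to a
binary critical-flight map with the threshold that retains a 95% true
positive rate, and intersects the result with externally supplied
species-occurrence and potential-conflict rasters to produce the joint
probability map, the high-risk conflict map and the area-share table.
"""

from __future__ import annotations

from dataclasses import dataclass, replace

import numpy as np
import pandas as pd

from . import nnmodel
from .evalsuite import train_val_split, prepare_xy
from .nnmodel import ModelConfig, NetworkModel
from .raster import Raster, RasterError
from .terrain import EnvStack, NormStats, fit_normalizer, stack_features

__all__ = [
    "BaggedPrediction",
    "bagging_train",
    "predict_raster",
    "aggregate_bagged",
    "threshold_at_sensitivity",
    "binarize",
    "joint_probability",
    "high_risk_intersect",
]

CONFLICT_LEVELS = (0, 1, 2, 3, 4)
DEFAULT_B = 30
DEFAULT_SENSITIVITY = 0.95


@dataclass
class BaggedPrediction:
    """Cellwise mean and 2.5/97.5 percentile rasters of a model ensemble."""

    mean: Raster
    lower: Raster
    upper: Raster
    B: int


def bagging_train(
    table: pd.DataFrame,
    best_cfg: ModelConfig,
    B: int = DEFAULT_B,
    seed: int = 0,
) -> tuple[list[NetworkModel], NormStats]:
    """Train a bagged ensemble.

    The 70/30 split is fixed once; each of the ``B`` members trains on a
    seeded bootstrap resample of the training split (same size, with
    replacement) with early stopping on the shared validation split.
    """
    if B < 2:
        raise ValueError("bagging needs at least two members")
    train_mask, val_mask = train_val_split(len(table), seed=seed)
    train_rows = table.loc[train_mask].reset_index(drop=True)
    stats = fit_normalizer(train_rows)
    Xtr, ytr = prepare_xy(train_rows, stats)
    Xva, yva = prepare_xy(table.loc[val_mask], stats)

    members = []
    for b in range(B):
        rng = np.random.default_rng([6, seed, b])
        resample = rng.integers(0, len(Xtr), size=len(Xtr))
        cfg = replace(best_cfg, seed=best_cfg.seed + b)
        model = nnmodel.init_network(cfg)
        model.norm_stats = stats
        model, _ = nnmodel.train(model, Xtr[resample], ytr[resample], Xva, yva, cfg)
        members.append(model)
    return members, stats


def predict_raster(model_or_ensemble, env: EnvStack, norm_stats: NormStats):
    """Probability raster(s) over the stack's grid.

    Cells are encoded exactly like observation rows (same one-hot layout,
    same training normalization statistics); cells without full band
    coverage stay nodata. An ensemble yields one raster per member.
    """
    models = model_or_ensemble if isinstance(model_or_ensemble, (list, tuple)) \
        else [model_or_ensemble]
    feats, rows, cols = stack_features(env)
    X, _ = prepare_xy(feats.assign(label=0), norm_stats)
    ref = env.reference
    out = []
    for model in models:
        p = nnmodel.predict(model, X)
        grid = np.full(ref.data.shape, np.nan)
        grid[rows, cols] = p
        out.append(ref.copy_with(grid))
    if isinstance(model_or_ensemble, (list, tuple)):
        return out
    return out[0]


def aggregate_bagged(member_maps: list[Raster]) -> BaggedPrediction:
    """Cellwise mean and empirical 2.5%/97.5% percentiles (linear
    interpolation between order statistics) of co-registered member maps."""
    if len(member_maps) < 2:
        raise ValueError("need at least two member maps")
    ref = member_maps[0]
    for m in member_maps[1:]:
        if not m.same_grid(ref):
            raise RasterError("member maps are not co-registered")
    stack = np.stack([m.data for m in member_maps])
    return BaggedPrediction(
        mean=ref.copy_with(stack.mean(axis=0)),
        lower=ref.copy_with(np.percentile(stack, 2.5, axis=0)),
        upper=ref.copy_with(np.percentile(stack, 97.5, axis=0)),
        B=len(member_maps),
    )


def threshold_at_sensitivity(labels, scores, target: float = DEFAULT_SENSITIVITY):
    """The largest threshold retaining at least the target true-positive rate.

    Scans the unique score values; returns ``(threshold, achieved_tpr)``
    where ``achieved_tpr`` is the fraction of positives scoring at or above
    the threshold. For ``target = 0`` the rule degenerates to the maximum
    score (TPR >= 0 always holds).
    """
    y = np.asarray(labels)
    s = np.asarray(scores, dtype=float)
    pos = np.sort(s[y == 1])
    if pos.size == 0:
        raise ValueError("no positive observations; sensitivity undefined")
    candidates = np.unique(s)[::-1]  # descending
    n_pos = pos.size
    # TPR(t) = #(pos >= t) / n_pos, non-decreasing as t decreases
    tpr = (n_pos - np.searchsorted(pos, candidates, side="left")) / n_pos
    ok = np.flatnonzero(tpr >= target)
    k = ok[0]  # largest threshold meeting the target
    return float(candidates[k]), float(tpr[k])


def binarize(prob_raster: Raster, threshold: float) -> Raster:
    """1 where probability >= threshold, else 0; nodata preserved. The >=
    convention makes the achieved sensitivity match the selection TPR."""
    if not np.isfinite(threshold):
        raise ValueError("threshold must be finite")
    data = prob_raster.data
    out = np.where(np.isnan(data), np.nan, (data >= threshold).astype(float))
    return prob_raster.copy_with(out)


def joint_probability(low_flight_map: Raster, occurrence_map: Raster) -> Raster:
    """Cellwise product: probability of occurring AND flying in the
    rotor-swept band."""
    if not low_flight_map.same_grid(occurrence_map):
        raise RasterError("maps are not co-registered")
    for r in (low_flight_map, occurrence_map):
        v = r.data[~np.isnan(r.data)]
        if v.size and (v.min() < 0 or v.max() > 1):
            raise ValueError("joint_probability expects probability rasters in [0, 1]")
    return low_flight_map.copy_with(low_flight_map.data * occurrence_map.data)


def high_risk_intersect(
    binary_low_flight: Raster,
    conflict_levels: Raster,
    region_mask: Raster | None = None,
) -> tuple[Raster, pd.DataFrame]:
    """Restrict the potential-conflict levels to predicted low-flight cells.

    The output raster keeps the conflict level (1-4) where low flight is
    predicted and is 0 elsewhere. The area-share table reports, per level,
    the percentage of region cells in the potential map, in the high-risk
    map, and the remainder (potential minus high-risk), plus totals.
    """
    if not binary_low_flight.same_grid(conflict_levels):
        raise RasterError("maps are not co-registered")
    lv = conflict_levels.data
    known = np.isnan(lv) | np.isin(lv, CONFLICT_LEVELS)
    if not known.all():
        bad = np.unique(lv[~known])
        raise ValueError(f"unknown conflict level code(s): {bad}")

    binary = binary_low_flight.data
    out = np.where(np.isnan(binary) | np.isnan(lv), np.nan, np.where(binary == 1, lv, 0.0))

    if region_mask is not None:
        if not region_mask.same_grid(conflict_levels):
            raise RasterError("region mask is not co-registered")
        region = region_mask.data == 1
    else:
        region = ~np.isnan(lv)
    n_region = int(region.sum())
    if n_region == 0:
        raise ValueError("empty region")

    records = []
    for level in (1, 2, 3, 4):
        potential = float(100.0 * np.sum(region & (lv == level)) / n_region)
        high = float(100.0 * np.sum(region & (out == level)) / n_region)
        records.append({
            "level": level,
            "potential": potential,
            "high_risk": high,
            "remaining": potential - high,
        })
    table = pd.DataFrame.from_records(records)
    total = table[["potential", "high_risk", "remaining"]].sum()
    table.loc[len(table)] = {"level": "total", **total.to_dict()}
    return conflict_levels.copy_with(out), table
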