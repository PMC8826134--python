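#!/usr/bin/env python
"""Risk mapping: bagged probability surface with a 95% credible interval,
sensitivity-constrained binary critical-flight map, joint-probability map
and high-risk conflict map with the area-share table.

The species-occurrence probability raster and the 4-level potential-conflict
raster are external inputs in the real workflow (outputs of a separate
habitat-suitability model); here SYNTHETIC stand-ins are derived from the
food-availability bands so the products can be demonstrated end to end.

Reads results/world, results/features and results/model; writes
results/maps/.
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from lowflight import io, nnmodel, terrain
from lowflight.evalsuite import prepare_xy
from lowflight.raster import read_ascii_grid
from lowflight.riskmap import (
    aggregate_bagged,
    bagging_train,
    binarize,
    high_risk_intersect,
    joint_probability,
    predict_raster,
    threshold_at_sensitivity,
)

_spec = importlib.util.spec_from_file_location(
    "features_step", Path(__file__).parent / "03_features.py")
_features_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_features_step)


def synthetic_conflict_inputs(env, mask):
    """SYNTHETIC stand-ins for the external habitat model outputs:
    occurrence = mean of the food bands; conflict levels = quartiles of
    occurrence over the top 40% of in-region cells (0 elsewhere)."""
    occ = env.reference.copy_with((env["ibex"].data + env["chamois"].data) / 2.0)
    region = mask.data == 1
    vals = occ.data[region]
    q60 = np.quantile(vals, 0.6)
    edges = np.quantile(vals[vals >= q60], [0.25, 0.5, 0.75])
    levels = np.zeros_like(occ.data)
    suitable = region & (occ.data >= q60)
    levels[suitable] = np.digitize(occ.data[suitable], edges) + 1
    return occ, occ.copy_with(levels)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--features", type=Path, default=Path("results/features/features.csv"))
    ap.add_argument("--model", type=Path, default=Path("results/model/model.json"))
    ap.add_argument("--out", type=Path, default=Path("results/maps"))
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--bags", type=int, default=30)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.features)
    model = io.load_model(args.model)
    env = _features_step.load_env(args.world)
    mask = read_ascii_grid(args.world / "region_mask.asc")

    print(f"training {args.bags} bagged members ...")
    members, stats = bagging_train(table, model.config, B=args.bags, seed=args.seed)
    maps = predict_raster(members, env, stats)
    bag = aggregate_bagged(maps)
    bag.mean.write(args.out / "prob_mean.asc")
    bag.lower.write(args.out / "prob_lower.asc")
    bag.upper.write(args.out / "prob_upper.asc")
    width = np.nanmean(bag.upper.data - bag.lower.data)
    print(f"bagged mean map written; mean 95% interval width {width:.3f}")

    X, y = prepare_xy(table, stats)
    scores = np.mean([nnmodel.predict(m, X) for m in members], axis=0)
    threshold, tpr = threshold_at_sensitivity(y, scores, target=0.95)
    print(f"95%-sensitivity threshold {threshold:.4f} "
          f"(achieved TPR {100 * tpr:.2f}% on the selection data)")
    binary = binarize(bag.mean, threshold)
    binary.write(args.out / "binary_low_flight.asc")

    occ, conflict = synthetic_conflict_inputs(env, mask)
    occ.write(args.out / "synthetic_occurrence.asc")
    conflict.write(args.out / "synthetic_conflict.asc")
    joint = joint_probability(bag.mean, occ)
    joint.write(args.out / "joint_probability.asc")
    high, shares = high_risk_intersect(binary, conflict, region_mask=mask)
    high.write(args.out / "high_risk.asc")
    shares.to_csv(args.out / "area_shares.csv", index=False)
    print("area shares (% of region cells) by sensitivity level:")
    print(shares.to_string(index=False))

    region = mask.data == 1
    flagged = np.nansum(binary.data[region] == 1) / region.sum()
    print(f"share of the region flagged as critical flight altitude: {100 * flagged:.1f}%")


if __name__ == "__main__":
    main()
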