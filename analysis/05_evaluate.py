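#!/usr/bin/env python
"""Generalization and variable-effect diagnostics for the trained model:

- leave-one-bird-out cross-validation (transfer across individuals);
- spatial-block cross-validation with the variogram-recommended block
  size rounded up (transfer across space);
- grouped permutation importance (per-variable and headline groupings);
- ICE / partial-dependence curves for the five most important variables.

Reads results/world, results/features and results/model; writes
results/evaluation/.
"""

import argparse
import importlib.util
from pathlib import Path

import numpy as np
import pandas as pd

from lowflight import io, nnmodel, terrain
from lowflight.evalsuite import (
    HEADLINE_GROUPS,
    block_cv,
    estimate_block_size,
    ice_pd,
    loo_bird_cv,
    make_blocks,
    permutation_importance,
)
from lowflight.raster import read_ascii_grid

_spec = importlib.util.spec_from_file_location(
    "features_step", Path(__file__).parent / "03_features.py")
_features_step = importlib.util.module_from_spec(_spec)
_spec.loader.exec_module(_features_step)


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--features", type=Path, default=Path("results/features/features.csv"))
    ap.add_argument("--model", type=Path, default=Path("results/model/model.json"))
    ap.add_argument("--out", type=Path, default=Path("results/evaluation"))
    ap.add_argument("--seed", type=int, default=42)
    args = ap.parse_args()
    args.out.mkdir(parents=True, exist_ok=True)

    table = pd.read_csv(args.features)
    model = io.load_model(args.model)
    env = _features_step.load_env(args.world)
    mask = read_ascii_grid(args.world / "region_mask.asc")

    # cross-validation across birds
    res_bird = loo_bird_cv(table, model.config)
    res_bird.frame.to_csv(args.out / "cv_bird.csv", index=False)
    print(f"leave-one-bird-out: mean train AUC {res_bird.mean_train:.3f} "
          f"(sd {res_bird.sd_train:.3f}), mean test AUC {res_bird.mean_test:.3f} "
          f"(sd {res_bird.sd_test:.3f})")

    # spatial autocorrelation and block CV
    recommended, per_band = estimate_block_size(env, n_pairs=20_000, seed=args.seed)
    per_band.to_csv(args.out / "variogram_ranges.csv", index=False)
    side = max(float(np.ceil(recommended / 500.0) * 500.0), 500.0)
    # the domain must still tile into enough blocks for five folds
    xmin, ymin, xmax, ymax = mask.bounds
    cap = np.floor(min(xmax - xmin, ymax - ymin) / 4.0 / 500.0) * 500.0
    side = min(side, max(cap, 500.0))
    print(f"variogram-recommended minimum block side: {recommended:.0f} m; using {side:.0f} m")
    blocks = make_blocks(mask, side_m=side, n_folds=5, seed=args.seed)
    res_block = block_cv(table, blocks, model.config)
    res_block.frame.to_csv(args.out / "cv_block.csv", index=False)
    print(f"spatial-block CV: mean train AUC {res_block.mean_train:.3f} "
          f"(sd {res_block.sd_train:.3f}), mean test AUC {res_block.mean_test:.3f} "
          f"(sd {res_block.sd_test:.3f})")

    # permutation importance
    rows = terrain.apply_normalizer(table, model.norm_stats)
    labels = table["label"].to_numpy()
    imp = permutation_importance(model, rows, labels, n_reps=10, seed=args.seed)
    imp.to_csv(args.out / "importance_by_variable.csv", index=False)
    imp_headline = permutation_importance(
        model, rows, labels, groups=HEADLINE_GROUPS, n_reps=10, seed=args.seed)
    imp_headline.to_csv(args.out / "importance_headline.csv", index=False)
    print("headline importance (relative AUC drop, %):")
    print(imp_headline.to_string(index=False))

    # effect curves for the five most important variables
    sample = table.sample(n=min(2000, len(table)), random_state=args.seed)
    top = [g for g in imp["group"] if g not in ("landcover", "geology")][:5]
    for var in top:
        curves = ice_pd(model, sample, var, n_grid=20, norm_stats=model.norm_stats)
        pd.DataFrame({"grid": curves.grid, "pd": curves.pd}).to_csv(
            args.out / f"pd_{var}.csv", index=False)
    print(f"wrote PD curves for: {', '.join(top)}")


if __name__ == "__main__":
    main()
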