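#!/usr/bin/env python
"""Architecture search and final training.

By default a reduced grid (2x2x2 around the study's best architecture) is
searched on the fixed 70/30 split; --full runs the complete 216-point grid
(6 widths x 6 widths x 6 dropout rates), which takes much longer. The best
configuration is then retrained and saved with its training log.

Reads results/features/, writes results/model/.
"""

import argparse
from dataclasses import replace
from pathlib import Path

import pandas as pd

from lowflight import io, nnmodel, terrain
from lowflight.evalsuite import GridSpec, grid_search, prepare_xy, train_val_split
from lowflight.nnmodel import ModelConfig


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--features", type=Path, default=Path("results/features/features.csv"))
    ap.add_argument("--out", type=Path, default=Path("results/model"))
    ap.add_argument("--seed", type=int, default=42)
    ap.add_argument("--full", action="store_true", help="search the complete 216-point grid")
    args = ap.parse_args()

    table = pd.read_csv(args.features)
    base = ModelConfig(seed=args.seed, max_epochs=60)
    if args.full:
        grid = GridSpec()
    else:
        grid = GridSpec((128, 256), (16, 32), (0.3, 0.4))
    print(f"searching {grid.size} configurations ...")
    results, best_cfg = grid_search(table, grid, base, seed=args.seed)
    print(results.head(10).to_string(index=False))
    print(f"best architecture: {best_cfg.units1}/{best_cfg.units2}, "
          f"dropout {best_cfg.dropout_rate}")

    train_mask, val_mask = train_val_split(len(table), seed=args.seed)
    stats = terrain.fit_normalizer(table.loc[train_mask])
    Xtr, ytr = prepare_xy(table.loc[train_mask], stats)
    Xva, yva = prepare_xy(table.loc[val_mask], stats)
    model = nnmodel.init_network(best_cfg)
    model.norm_stats = stats
    model, log = nnmodel.train(model, Xtr, ytr, Xva, yva, best_cfg)

    args.out.mkdir(parents=True, exist_ok=True)
    results.to_csv(args.out / "grid_search.csv", index=False)
    io.save_model(model, args.out / "model.json")
    pd.DataFrame({
        "epoch": range(len(log.train_loss)),
        "train_loss": log.train_loss,
        "val_auc": log.val_auc,
    }).to_csv(args.out / "train_log.csv", index=False)

    from lowflight.evalsuite import auc
    print(f"final model: train AUC {auc(ytr, nnmodel.predict(model, Xtr)):.3f}, "
          f"validation AUC {log.best_val_auc:.3f} "
          f"(best epoch {log.best_epoch}, stopped at {log.stopped_epoch})")


if __name__ == "__main__":
    main()
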