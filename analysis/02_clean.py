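#!/usr/bin/env python
"""Clean the raw telemetry: datum conversion, AGL, quality/daylight/flight
culling, region and post-release filters, per-minute subsampling and the
minimum-sample rule, with a per-stage audit table.

Reads results/world/, writes results/clean/.
"""

import argparse
from pathlib import Path

from lowflight import io, trackproc
from lowflight.raster import read_ascii_grid


def main():
    ap = argparse.ArgumentParser()
    ap.add_argument("--world", type=Path, default=Path("results/world"))
    ap.add_argument("--out", type=Path, default=Path("results/clean"))
    ap.add_argument("--lat", type=float, default=46.5)
    ap.add_argument("--lon", type=float, default=8.0)
    args = ap.parse_args()

    fixes = io.read_tracks(args.world / "fixes.csv")
    birds = io.read_birds(args.world / "birds.csv")
    dem = read_ascii_grid(args.world / "elevation.asc")
    und = read_ascii_grid(args.world / "undulation.asc")
    mask = read_ascii_grid(args.world / "region_mask.asc")

    cleaned, report = trackproc.clean_tracks(fixes, birds, dem, und, mask,
                                             args.lat, args.lon)
    args.out.mkdir(parents=True, exist_ok=True)
    cleaned.to_csv(args.out / "clean_fixes.csv", index=False)
    report.to_frame().to_csv(args.out / "cleaning_report.csv", index=False)

    print(report.to_frame().to_string(index=False))
    print(f"retained {len(report.birds_retained)} birds, {len(cleaned)} fixes")


if __name__ == "__main__":
    main()
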