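#!/usr/bin/env python
"""Slope-calculator outputs: the period x viral-load prediction grid and the
per-period viral-load limits that keep the predicted slope at or above
+20 cells/uL/yr.

Uses the published final-model coefficients by default; pass --fitted to use
the model fitted by 03_fit_model.py instead.  Writes results/grid.tsv and
results/thresholds.tsv.
"""

import argparse
import json
from pathlib import Path

from cd4slope import (
    PatientProfile,
    build_grid,
    published_coefficients,
    solve_vl_threshold,
)
from cd4slope.mixedlm import ModelFit


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--results", type=Path, default=Path("results"))
    parser.add_argument("--fitted", action="store_true",
                        help="use results/fit.json instead of the published model")
    args = parser.parse_args()

    if args.fitted:
        model = ModelFit.from_dict(json.loads((args.results / "fit.json").read_text()))
        label = "fitted"
    else:
        model = published_coefficients()
        label = "published"

    profile = PatientProfile(female=0, age_years=30.0, stage="REF", cd4=200.0)
    grid = build_grid(profile, model)
    (args.results / "grid.tsv").write_text(grid.to_tsv())
    thresholds = solve_vl_threshold(profile, model, target_slope=20.0, mode="GRID")
    thresholds.to_csv(args.results / "thresholds.tsv", sep="\t", index=False)

    print(f"{label} model; reference profile: male, 30 y, CDC-A, CD4 200, no hepatitis")
    print(grid.to_tsv())
    print("largest VL (copies/mL) keeping slope >= +20 cells/uL/yr:")
    for _, row in thresholds.iterrows():
        print(f"  {row['period']}: {row['vl_copies_per_ml']:.0f} ({row['status']})")


if __name__ == "__main__":
    main()
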