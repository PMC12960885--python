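#!/usr/bin/env python
"""Score every habitat patch with the three-component landscape pressure index.

Each patch gets 0-4 values for proximity to agriculture, proximity to urban
areas and the modified-land proportion of its linked drainage basin; the
cumulative value (0-12, >= 6 = higher-level pressure) is compared against the
scene's constructed per-patch truth, and exact recovery is demonstrated on
noise-free scenes built at known high-pressure fractions.
"""

import argparse
from pathlib import Path

from bcmap import PipelineConfig, SimulationConfig, recovery_config, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--out", type=Path, default=Path("results"))
args = parser.parse_args()

result = run_pipeline(PipelineConfig(simulation=SimulationConfig(seed=args.seed)))
args.out.mkdir(parents=True, exist_ok=True)
result.scores_frame().to_csv(args.out / "pressure_scores.csv", index=False)

print("high-pressure area fraction per class (standard scene):")
for cls, value in result.high_pressure_fraction.items():
    truth = result.scene.truth.true_high_pressure_fraction.get(cls)
    print(f"  {cls:28s} {value:.3f}  (constructed truth {truth:.3f})")

print("\nexact recovery on noise-free scenes:")
for fraction in (0.0, 0.25, 0.5, 1.0):
    rec = run_pipeline(PipelineConfig(simulation=recovery_config(fraction, seed=args.seed)))
    print(f"  target {fraction:.2f} -> recovered {rec.high_pressure_fraction['all']:.2f}")
print(f"\npatch table written to {args.out / 'pressure_scores.csv'}")
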