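#!/usr/bin/env python
"""Generate the multi-study dataset the rest of the analysis screens.

Seven simulated studies on a shared probeset universe, each contrasting
3 pluripotent vs 3 differentiated samples; 2000 genes interrogated by 1-3
probesets; 20 planted markers carry a +3.0 log2 effect in the pluripotent
group of every study. Matrices, designs, annotation and ground truth are
written as TSVs under scratch/sim/ (large, regenerable) for the next step.
"""

import argparse
from pathlib import Path

from stemscreen import SimConfig, simulate_studies
from stemscreen.synthetic import write_dataset

ROOT = Path(__file__).resolve().parents[1]


def main() -> None:
    parser = argparse.ArgumentParser(description=__doc__)
    parser.add_argument("--seed", type=int, default=1)
    parser.add_argument("--outdir", type=Path, default=ROOT / "scratch" / "sim")
    args = parser.parse_args()

    config = SimConfig(seed=args.seed)
    studies, annotation, truth = simulate_studies(config)
    write_dataset(studies, annotation, truth, args.outdir)

    n_probesets = len(studies[0].probeset_ids)
    print(f"simulated {config.n_studies} studies, seed={args.seed}")
    print(f"  {config.n_genes} genes -> {n_probesets} probesets")
    print(f"  {config.n_planted} planted markers, effect +{config.effect_size} log2")
    print(f"  wrote TSVs to {args.outdir}")


if __name__ == "__main__":
    main()
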