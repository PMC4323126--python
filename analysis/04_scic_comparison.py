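#!/usr/bin/env python
"""Compare the three correction arms on uniform-flow phantoms.

Replicates the healthy-cohort comparison: MBF spatial heterogeneity and
corrected-reference signal CoV per arm across seeded replicates, and how
often the arms fall in the expected order (no correction worst, PD best).
Writes results/scic_comparison.json.
"""

import argparse
import json
from pathlib import Path

from perfquant.experiments import heterogeneity_ordering_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=100)
    ap.add_argument("--grid", type=int, default=48)
    ap.add_argument("--out", type=Path, default=Path("results/scic_comparison.json"))
    args = ap.parse_args()

    result = heterogeneity_ordering_experiment(
        n_replicates=args.replicates, seed=args.seed, grid=args.grid, snr=20.0
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(result, indent=1, sort_keys=True) + "\n")

    het = result["heterogeneity_pct"]
    print(
        f"MBF heterogeneity over {result['n_replicates']} replicates "
        f"(mean +/- SD): no correction {het['none'][0]:.1f} +/- "
        f"{het['none'][1]:.1f}%, SSFP {het['ssfp'][0]:.1f} +/- "
        f"{het['ssfp'][1]:.1f}%, PD {het['pd'][0]:.1f} +/- {het['pd'][1]:.1f}%"
    )
    print(
        f"ordering none > ssfp >= pd held in "
        f"{100 * result['ordering_fraction']:.0f}% of replicates; "
        f"corrected-PD CoV beat uncorrected in "
        f"{100 * result['cov_improved_fraction']:.0f}%"
    )


if __name__ == "__main__":
    main()
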