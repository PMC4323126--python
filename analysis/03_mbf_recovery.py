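#!/usr/bin/env python
"""Quantify flow-recovery accuracy of the Fermi deconvolution.

Fermi-generated curves are recovered essentially exactly (the fit is in
its own model class).  Kety-generated curves probe the deliberate
generator/quantifier mismatch: the initial-height read-out carries a
flow-dependent bias of a few percent, and concentration noise equivalent
to SNR 20 adds pixel-level scatter.  Writes results/mbf_recovery.csv.
"""

import argparse
from pathlib import Path

import pandas as pd

from perfquant.experiments import mbf_recovery_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--out", type=Path, default=Path("results/mbf_recovery.csv"))
    args = ap.parse_args()

    result = mbf_recovery_experiment(snr=20.0, n_pixels=100, seed=args.seed)
    rows = [
        {
            "flow_ml_min_g": f,
            "noise_free_err_pct": result["kety_noise_free_err_pct"][f],
            "snr20_mae_pct": result["kety_noisy_mae_pct"][f],
        }
        for f in sorted(result["kety_noise_free_err_pct"])
    ]
    args.out.parent.mkdir(parents=True, exist_ok=True)
    pd.DataFrame(rows).to_csv(args.out, index=False)

    worst_fermi = max(result["fermi_self_consistency_err_pct"].values())
    print(f"Fermi self-consistency worst error: {worst_fermi:.2e}%")
    for row in rows:
        print(
            f"  f={row['flow_ml_min_g']:.1f} mL/min/g: noise-free "
            f"{row['noise_free_err_pct']:+.1f}%, SNR-20 MAE "
            f"{row['snr20_mae_pct']:.1f}%"
        )


if __name__ == "__main__":
    main()
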