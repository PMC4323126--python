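#!/usr/bin/env python
"""Check that the third-order surface fit recovers a known gain field.

On a uniform-tissue reference whose gain is itself a cubic polynomial the
fit is exact; under Rician noise at SNR 20 the relative RMS error stays a
fraction of a percent because thousands of myocardial and body pixels
anchor ten coefficients.  Writes results/bias_recovery.json.
"""

import argparse
import json
from pathlib import Path

from perfquant.experiments import bias_recovery_experiment


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--replicates", type=int, default=100)
    ap.add_argument("--out", type=Path, default=Path("results/bias_recovery.json"))
    args = ap.parse_args()

    result = bias_recovery_experiment(
        n_replicates=args.replicates, snr=20.0, seed=args.seed
    )
    args.out.parent.mkdir(parents=True, exist_ok=True)
    args.out.write_text(json.dumps(result, indent=1, sort_keys=True) + "\n")
    print(
        f"in-class gain recovery: noise-free rel RMS "
        f"{result['noise_free_rel_rms']:.2e}; at SNR 20 "
        f"{100 * result['noisy_rel_rms_mean']:.2f}% mean over "
        f"{result['n_replicates']} replicates"
    )


if __name__ == "__main__":
    main()
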