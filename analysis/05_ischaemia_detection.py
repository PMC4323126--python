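#!/usr/bin/env python
"""Reproduce the cohort comparison: can MBF maps find the diseased vessel?

Runs a healthy cohort (uniform flow) and a single-vessel-disease cohort
(30% LAD flow deficit) through all three correction arms and tabulates
remote and ischaemic territory MBF, their difference, and the paired
contrasts — the in-silico analogue of comparing correction methods in
patients.  Without correction the anterior coil gain inflates apparent
LAD flow enough to reverse the sign of the remote-ischaemic difference.
Writes results/study_reproduction.json and a territory table CSV.
"""

import argparse
import json
from pathlib import Path

import pandas as pd

from perfquant.experiments import study_reproduction


def main() -> None:
    ap = argparse.ArgumentParser(description=__doc__)
    ap.add_argument("--seed", type=int, default=1)
    ap.add_argument("--n-healthy", type=int, default=8)
    ap.add_argument("--n-cad", type=int, default=12)
    ap.add_argument("--grid", type=int, default=64)
    ap.add_argument("--out-dir", type=Path, default=Path("results"))
    args = ap.parse_args()

    study = study_reproduction(seed=args.seed, n_healthy=args.n_healthy,
                               n_cad=args.n_cad, grid=args.grid, snr=20.0)
    args.out_dir.mkdir(parents=True, exist_ok=True)
    (args.out_dir / "study_reproduction.json").write_text(
        json.dumps(study, indent=1, sort_keys=True) + "\n"
    )

    rows = []
    for mode, label in (("pd", "PD-SCIC"), ("ssfp", "SSFP-SCIC"),
                        ("none", "No-SCIC")):
        c = study["cad"][mode]
        rows.append({
            "mode": label,
            "remote_mbf_ml_min_g": round(c["remote_mbf"], 3),
            "ischaemic_mbf_ml_min_g": round(c["ischaemic_mbf"], 3),
            "difference_ml_min_g": round(c["difference_mean"], 3),
            "difference_sd": round(c["difference_sd"], 3),
        })
    table = pd.DataFrame(rows)
    table.to_csv(args.out_dir / "territory_mbf_table.csv", index=False)

    print(f"ground-truth remote-ischaemic difference: "
          f"{study['cad_truth_diff']:.2f} mL/min/g")
    print(table.to_string(index=False))
    print(
        f"{study['n_cad_reversed_without_scic']}/{study['n_cad']} disease "
        f"phantoms show a reversed (negative) difference without correction"
    )
    for name, t in study["healthy_paired_tests"].items():
        print(f"paired t ({name}): t={t['t']:.2f}, df={t['df']}, p={t['p']:.3g}")


if __name__ == "__main__":
    main()
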