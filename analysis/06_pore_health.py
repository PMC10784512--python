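"""Pore health under adaptive sampling vs bulk sequencing.

Simulates a 68 h run in which both flow-cell halves lose pores at the
same constant hazard (calibrated so half survive), fits the per-half
decay, and tests whether the halves are statistically distinguishable.
Writes results/pore_health.tsv.
"""

import argparse
import math
from pathlib import Path

import pandas as pd

from poresift import quantify, simulate

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run(seed: int = 0):
    hz = simulate.DEFAULT_PORE_HAZARD
    scans = simulate.simulate_pore_scans(256, hz, 68 * 3600.0, seed=seed)
    scans += simulate.simulate_pore_scans(256, hz, 68 * 3600.0,
                                          seed=seed + 1,
                                          first_channel=257)
    fits = quantify.pore_decay(scans, {"bulk": (1, 256),
                                       "as": (257, 512)})
    mles = {name: quantify.pore_hazard_mle(scans, half)
            for name, half in (("bulk", (1, 256)), ("as", (257, 512)))}
    return hz * 3600.0, fits, mles


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    true_rate, fits, mles = run(args.seed)
    rows = []
    for name in ("bulk", "as"):
        rate, se = mles[name]
        rows.append({
            "half": name,
            "loglinear_rate_per_h": round(fits[name].rate_per_hour, 5),
            "survival_mle_rate_per_h": round(rate, 5),
            "mle_se": round(se, 5),
            "pores_start": fits[name].counts[0],
            "pores_end": fits[name].counts[-1],
        })
    df = pd.DataFrame(rows)
    df.to_csv(RESULTS / "pore_health.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    (r1, s1), (r2, s2) = mles["bulk"], mles["as"]
    z = abs(r1 - r2) / math.sqrt(s1 ** 2 + s2 ** 2)
    print(f"\nTrue hazard {true_rate:.5f}/h; halves differ by "
          f"z = {z:.2f} (|z| <= 3 means the adaptive-sampling half decays "
          f"at the same rate as the bulk half).")


if __name__ == "__main__":
    main()
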