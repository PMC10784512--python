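"""Length dependence of depletion efficiency.

Runs the length-ladder depletion benchmark (targets in each of the four
length bins over a uniform background), tabulating per-bin bulk and
accepted read shares and the reference-normalized depletion ratio.  The
minimum-sequence-length rule (600 bases) spares the two short bins while
transcripts above it are ejected.  Writes results/length_effects.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from poresift import quantify, simulate, synthesize
from poresift.quantify import LENGTH_EDGES

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run(seed: int = 0) -> pd.DataFrame:
    ts, targets = synthesize.make_length_ladder()
    cfg = simulate.RunConfig(mode="deplete", targets=targets,
                             duration=3 * 3600.0, n_channels=64, seed=seed)
    out = simulate.run_simulation(ts, cfg)
    assignment = {r.read_id: (r.true_transcript, r.sequenced_length)
                  for r in out.reads}
    passing = quantify.qc_filter(out.summary)
    bulk_ids, as_ids = quantify.split_by_channel(
        [r for r in out.summary if r.read_id in passing],
        cfg.as_channels, cfg.n_channels)
    accepted, _ = quantify.pool_by_decision(as_ids, out.decisions)
    bulk_ct = quantify.count_reads_bases(bulk_ids, assignment, "bulk")
    acc_ct = quantify.count_reads_bases(accepted, assignment,
                                        "as_accepted")
    attr = {t.id: t.length for t in ts}
    df = quantify.binned_efficiency(bulk_ct, acc_ct, attr,
                                    restrict=set(targets))
    reference = set(ts.ids) - set(targets)
    df["ref_normalized_ratio"] = [
        quantify.reference_normalized_ratio(
            bulk_ct, acc_ct,
            {t for t in targets if lo <= attr[t] < hi}, reference)
        for lo, hi in zip(LENGTH_EDGES, LENGTH_EDGES[1:])
    ]
    return df


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    df = run(args.seed)
    cols = ["bin", "n_transcripts", "bulk_pct", "as_pct",
            "ref_normalized_ratio"]
    df[cols].to_csv(RESULTS / "length_effects.tsv", sep="\t", index=False)
    print(df[cols].round(3).to_string(index=False))
    short = df["ref_normalized_ratio"][:2].mean()
    long = df["ref_normalized_ratio"].iloc[3]
    print(f"\nTargets under 600 bases keep their bulk share "
          f"(ratio ~{short:.2f}); >1000-base targets are depleted "
          f"{long:.0f}-fold — the minimum-sequence-length rule in action.")


if __name__ == "__main__":
    main()
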