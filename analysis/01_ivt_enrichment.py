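"""Decision-time sweep for enriching GAPDH from the 4-transcript IVT pool.

Simulates split-flow-cell runs at 1, 3.5 and 6.5 s decision times with
polyA-driven ambiguity at short decision windows, and reports the GAPDH
read gain of the adaptive half over the bulk half, the rejected-pool
false-rejection rate, and the median rejected-read length.  Alongside, the
published per-half count table is re-derived into its percent-increase
claims.  Writes results/ivt_enrichment.tsv.
"""

import argparse
from pathlib import Path

import pandas as pd

from poresift import datasets, quantify, simulate, synthesize

RESULTS = Path(__file__).resolve().parent.parent / "results"


def run(seed: int = 0) -> pd.DataFrame:
    pool = synthesize.make_ivt_pool()
    rows = []
    for bt in (1.0, 3.5, 6.5):
        base = simulate.RunConfig(
            mode="enrich", targets=frozenset({"GAPDH"}), break_time=bt,
            duration=3 * 3600.0, n_channels=64, seed=seed)
        cfg = simulate.RunConfig(**{
            **base.__dict__,
            "p_ambiguous": simulate.polya_ambiguity(pool, base)})
        out = simulate.run_simulation(pool, cfg)
        assignment = {r.read_id: (r.true_transcript, r.sequenced_length)
                      for r in out.reads}
        rep = quantify.build_report(
            out.summary, out.decisions, assignment, mode="enrich",
            targets={"GAPDH"}, as_channels=cfg.as_channels,
            n_channels=cfg.n_channels)
        rows.append({
            "break_time_s": bt,
            "p_ambiguous": round(cfg.p_ambiguous, 3),
            "gapdh_bulk_reads": rep.counts["bulk"].get("GAPDH", (0, 0))[0],
            "gapdh_as_reads": rep.counts["as_accepted"].get(
                "GAPDH", (0, 0))[0],
            "gapdh_pct_increase": rep.target_percent_increase,
            "false_rejection_pct": (
                round(100 * rep.false_rejection_rate, 2)
                if rep.false_rejection_rate is not None else None),
            "median_reject_len": rep.median_reject_len,
        })
    return pd.DataFrame(rows)


def main():
    parser = argparse.ArgumentParser()
    parser.add_argument("--seed", type=int, default=0)
    args = parser.parse_args()
    RESULTS.mkdir(exist_ok=True)

    df = run(args.seed)
    df.to_csv(RESULTS / "ivt_enrichment.tsv", sep="\t", index=False)
    print(df.to_string(index=False))
    best = df.loc[df["gapdh_pct_increase"].idxmax()]
    print(f"\nGAPDH gain peaks at {best.break_time_s} s decision time "
          f"({best.gapdh_pct_increase:+.1f}% reads vs bulk); at 1 s the "
          f"polyA tail fills the decision window and the gain collapses.")

    pub = datasets.ivt_split_counts()
    pub = pub[pub["mode"] == "enrich"].copy()
    pub["pct_increase"] = [
        quantify.percent_increase(b, a)
        for b, a in zip(pub["bulk"], pub["adaptive"])
    ]
    print("\nPublished enrichment counts re-derived:")
    print(pub[["name", "bulk", "adaptive", "pct_increase"]]
          .to_string(index=False))


if __name__ == "__main__":
    main()
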