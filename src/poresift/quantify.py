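"""From run artifacts to enrichment statistics.

The pipeline follows the split-flow-cell accounting used in adaptive-
sampling experiments: Q-filter reads, assign them to the bulk or the
adaptive-sampling half by channel, group the adaptive-sampling half into
accepted (``stop_receiving`` + ``no_decision``) and rejected (``unblock``)
pools, count reads and bases per transcript in each pool, and derive the
comparison statistics — percent increases, fold reductions, rejected-pool
purity, pool compositions, top-N read shares, length/abundance/polyA
binned efficiencies, and pore-decay rates for each flow-cell half.

Counting runs in either *truth* mode (the simulator's read->transcript
labels, bases = sequenced length) or *alignment* mode (primary mapped
alignments, bases = mapped bases); on error-free alignments the two are
identical.
"""

from __future__ import annotations

import json
import math
from dataclasses import dataclass, field, asdict
from decimal import Decimal, ROUND_HALF_UP
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
import pandas as pd
from scipy import stats as sps

from .iofmt import (
    AlignmentRecord,
    Decision,
    DecisionRecord,
    PoreScanRecord,
    SummaryRecord,
    PORE_STATE_ACTIVE,
    filter_alignments,
)

POOLS = ("bulk", "as_accepted", "as_rejected")
TOP_NS = (50, 100, 150, 500, 1000)
LENGTH_EDGES = (200, 400, 600, 1000, math.inf)


@dataclass(frozen=True)
class CountTable:
    """Per-transcript read/base tallies for one named read pool."""

    pool: str
    rows: dict[str, tuple[int, int]]  # id -> (reads, bases)

    def __post_init__(self):
        if self.pool not in POOLS:
            raise ValueError(f"unknown pool {self.pool!r}")

    @property
    def total_reads(self) -> int:
        return sum(r for r, _ in self.rows.values())

    @property
    def total_bases(self) -> int:
        return sum(b for _, b in self.rows.values())

    def reads(self, tid: str) -> int:
        return self.rows.get(tid, (0, 0))[0]

    def bases(self, tid: str) -> int:
        return self.rows.get(tid, (0, 0))[1]


# ---------------------------------------------------------------------------
# Preprocessing
# ---------------------------------------------------------------------------

def qc_filter(summary: Iterable[SummaryRecord], q_min: float = 7.0
              ) -> set[str]:
    """Read ids whose mean Q passes the threshold (inclusive)."""
    return {r.read_id for r in summary if r.mean_q >= q_min}


def split_by_channel(
    summary: Iterable[SummaryRecord],
    as_channels: tuple[int, int],
    n_channels: int = 512,
) -> tuple[set[str], set[str]]:
    """Partition read ids into (bulk half, adaptive-sampling half)."""
    lo, hi = as_channels
    bulk: set[str] = set()
    as_side: set[str] = set()
    for r in summary:
        if not 1 <= r.channel <= n_channels:
            raise ValueError(
                f"read {r.read_id}: channel {r.channel} outside flow cell"
            )
        (as_side if lo <= r.channel <= hi else bulk).add(r.read_id)
    return bulk, as_side


def pool_by_decision(
    as_ids: set[str],
    decisions: Iterable[DecisionRecord],
) -> tuple[set[str], set[str]]:
    """Group adaptive-sampling reads into (accepted, rejected) pools.

    Accepted = ``stop_receiving`` or ``no_decision``; rejected =
    ``unblock``.  An adaptive-sampling read without a decision row is an
    error (surfaced data corruption), not a silent accept.
    """
    by_read = {d.read_id: d.decision for d in decisions}
    missing = sorted(as_ids - by_read.keys())
    if missing:
        raise ValueError(
            f"{len(missing)} adaptive-sampling read(s) lack a decision row: "
            f"{missing[:5]}{'...' if len(missing) > 5 else ''}"
        )
    accepted = {
        rid for rid in as_ids
        if by_read[rid] in (Decision.STOP_RECEIVING, Decision.NO_DECISION)
    }
    rejected = {rid for rid in as_ids if by_read[rid] == Decision.UNBLOCK}
    return accepted, rejected


def assignment_from_alignments(
    alignments: Iterable[AlignmentRecord],
) -> dict[str, tuple[str, int]]:
    """read_id -> (transcript, mapped bases) from primary mapped records."""
    out: dict[str, tuple[str, int]] = {}
    for a in filter_alignments(alignments):
        if a.read_id in out:
            raise ValueError(f"read {a.read_id} has two primary alignments")
        out[a.read_id] = (a.target_id, a.mapped_bases)
    return out


def count_reads_bases(
    ids: Iterable[str],
    assignment: Mapping[str, tuple[str, int]],
    pool: str,
) -> CountTable:
    """Tally reads and bases per transcript for one pool.

    Reads absent from the assignment (e.g. unmapped) are skipped.
    """
    rows: dict[str, list[int]] = {}
    for rid in ids:
        if rid not in assignment:
            continue
        tid, bases = assignment[rid]
        acc = rows.setdefault(tid, [0, 0])
        acc[0] += 1
        acc[1] += bases
    return CountTable(pool, {k: (v[0], v[1]) for k, v in rows.items()})


# ---------------------------------------------------------------------------
# Derived statistics
# ---------------------------------------------------------------------------

def _round(value: float, decimals: int, mode: str) -> float:
    if mode == "half_up":
        q = Decimal(1).scaleb(-decimals)
        return float(Decimal(repr(value)).quantize(q, rounding=ROUND_HALF_UP))
    if mode == "truncate":
        scale = 10 ** decimals
        return math.trunc(value * scale) / scale
    raise ValueError(f"unknown rounding mode {mode!r}")


def percent_increase(bulk: float, as_count: float, decimals: int = 0,
                     rounding: str = "half_up") -> float:
    """``(as/bulk - 1) * 100`` rounded to ``decimals``.

    ``rounding="half_up"`` reproduces whole-percent claims;
    ``"truncate"`` is the variant used for one-decimal base-level claims.
    """
    if bulk <= 0:
        raise ValueError("percent_increase undefined for bulk <= 0")
    return _round((as_count / bulk - 1.0) * 100.0, decimals, rounding)


def fold_reduction(bulk: float, as_count: float, decimals: int = 2,
                   rounding: str = "half_up") -> float:
    """``bulk / as`` rounded to ``decimals``."""
    if as_count <= 0:
        raise ValueError("fold_reduction undefined for as <= 0")
    return _round(bulk / as_count, decimals, rounding)


def rejected_pool_stats(
    rejected: CountTable,
    targets: set[str],
    mode: str,
) -> tuple[float, float]:
    """(purity, false-rejection rate) of the rejected pool.

    The intent-consistent class is the target set in depletion mode and
    the non-target complement in enrichment mode; purity is its share of
    the rejected pool and the false-rejection rate is the remainder.
    """
    total = rejected.total_reads
    if total == 0:
        raise ValueError("rejected pool is empty")
    consistent = sum(
        reads for tid, (reads, _) in rejected.rows.items()
        if (tid in targets) == (mode == "deplete")
    )
    purity = consistent / total
    return purity, 1.0 - purity


def composition(ct: CountTable) -> dict[str, float]:
    """Read-count fractions per transcript; sums to 1."""
    total = ct.total_reads
    if total == 0:
        raise ValueError(f"pool {ct.pool!r} is empty")
    return {tid: reads / total for tid, (reads, _) in ct.rows.items()}


def top_share(ct: CountTable, n: int) -> float:
    """Fraction of pool reads held by the n most-read transcripts."""
    total = ct.total_reads
    if total == 0:
        raise ValueError(f"pool {ct.pool!r} is empty")
    counts = sorted((r for r, _ in ct.rows.values()), reverse=True)
    return sum(counts[:n]) / total


def binned_efficiency(
    bulk: CountTable,
    accepted: CountTable,
    attr: Mapping[str, float],
    edges: Sequence[float] = LENGTH_EDGES,
    restrict: Optional[set[str]] = None,
) -> pd.DataFrame:
    """Per-bin pool shares (%) for bulk vs adaptive-sampling accepted.

    ``attr`` maps transcript id to the binned attribute (length,
    abundance, polyA length); a transcript counted in either pool but
    absent from ``attr`` is an error.  ``restrict`` limits the table to a
    transcript subset (e.g. the depletion targets).  The depletion ratio
    column is bulk% / AS% (NaN where the AS share is zero).
    """
    tids = set(bulk.rows) | set(accepted.rows)
    if restrict is not None:
        tids &= restrict
    missing = sorted(t for t in tids if t not in attr)
    if missing:
        raise ValueError(f"transcript(s) missing binned attribute: "
                         f"{missing[:5]}")
    bt, at = bulk.total_reads, accepted.total_reads
    rows = []
    for lo, hi in zip(edges, edges[1:]):
        members = [t for t in tids if lo <= attr[t] < hi]
        b_pct = 100.0 * sum(bulk.reads(t) for t in members) / bt
        a_pct = 100.0 * sum(accepted.reads(t) for t in members) / at
        rows.append({
            "bin": f"{lo:g}-{hi:g}" if math.isfinite(hi) else f">{lo:g}",
            "lo": lo, "hi": hi,
            "n_transcripts": len(members),
            "bulk_pct": b_pct,
            "as_pct": a_pct,
            "depletion_ratio": b_pct / a_pct if a_pct > 0 else math.nan,
        })
    return pd.DataFrame(rows)


def reference_normalized_ratio(
    bulk: CountTable,
    accepted: CountTable,
    class_ids: set[str],
    reference_ids: set[str],
) -> float:
    """Depletion ratio of a transcript class against an unaffected reference.

    ``(B_class / B_ref) / (A_class / A_ref)`` with B from the bulk pool and
    A from the accepted pool.  Ejecting part of the pool mechanically
    renormalizes every composition, inflating the apparent share of
    untouched transcripts; dividing by a reference class that the run does
    not act on cancels that factor, so the ratio estimates 1/P(accept) for
    the class — exactly 1 for transcripts the decision rule spares.
    """
    b_cls = sum(bulk.reads(t) for t in class_ids)
    b_ref = sum(bulk.reads(t) for t in reference_ids)
    a_cls = sum(accepted.reads(t) for t in class_ids)
    a_ref = sum(accepted.reads(t) for t in reference_ids)
    if min(b_cls, b_ref, a_ref) == 0:
        raise ValueError("empty class or reference counts")
    if a_cls == 0:
        return math.inf
    return (b_cls / b_ref) / (a_cls / a_ref)


@dataclass(frozen=True)
class PoreDecayFit:
    """Log-linear fit of active-pore counts over time for one half."""

    times_h: tuple[float, ...]
    counts: tuple[int, ...]
    rate_per_hour: float  # decay rate (positive = losing pores)
    stderr: float


def pore_decay(
    scans: Iterable[PoreScanRecord],
    halves: Mapping[str, tuple[int, int]],
) -> dict[str, PoreDecayFit]:
    """Active-pore counts per scan and fitted exponential decay per half.

    Counts channels in the ``single_pore`` state at each scan time within
    each half, then fits ``log(count) ~ time`` by least squares; the decay
    rate is the negated slope in units of 1/hour.
    """
    scans = list(scans)
    times = sorted({s.scan_time for s in scans})
    if len(times) < 2:
        raise ValueError("pore_decay needs at least 2 scans")
    out = {}
    for name, (lo, hi) in halves.items():
        counts = []
        for st in times:
            counts.append(sum(
                1 for s in scans
                if s.scan_time == st and lo <= s.channel <= hi
                and s.state == PORE_STATE_ACTIVE
            ))
        hours = [t / 3600.0 for t in times]
        kept = [(h, c) for h, c in zip(hours, counts) if c > 0]
        if len(kept) < 2:
            raise ValueError(f"half {name!r}: fewer than 2 non-zero scans")
        x = np.array([h for h, _ in kept])
        y = np.log([c for _, c in kept])
        fit = sps.linregress(x, y)
        out[name] = PoreDecayFit(tuple(hours), tuple(counts),
                                 -fit.slope, fit.stderr)
    return out


def pore_hazard_mle(
    scans: Iterable[PoreScanRecord],
    half: tuple[int, int],
) -> tuple[float, float]:
    """Hazard estimate (per hour) and its standard error for one half.

    Uses the binomial survival MLE from the first and last scans:
    ``h = -log(S/N) / T`` with ``Var(h) = (1-p) / (N p T^2)`` by the delta
    method.  Unlike the per-scan log-linear fit, whose OLS standard error
    ignores that the same channels persist between scans, this gives a
    calibrated uncertainty for comparing two halves.
    """
    scans = list(scans)
    times = sorted({s.scan_time for s in scans})
    if len(times) < 2:
        raise ValueError("need at least 2 scans")
    lo, hi = half
    t0, t1 = times[0], times[-1]

    def active(st):
        return sum(1 for s in scans
                   if s.scan_time == st and lo <= s.channel <= hi
                   and s.state == PORE_STATE_ACTIVE)

    n0, n1 = active(t0), active(t1)
    if n0 == 0 or n1 == 0:
        raise ValueError("no surviving channels to estimate a hazard from")
    span_h = (t1 - t0) / 3600.0
    p = n1 / n0
    rate = -math.log(p) / span_h
    se = math.sqrt((1 - p) / (n0 * p)) / span_h
    return rate, se


def coverage_profile(
    alignments: Iterable[AlignmentRecord],
    transcript_length: int,
) -> tuple[np.ndarray, float]:
    """Per-position depth and mean covered fraction for one transcript.

    Ejected reads cover only the 3' end of their molecule, so a depleted
    transcript shows depth piled at the 3' end and a bare 5' half.
    """
    depth = np.zeros(transcript_length, dtype=int)
    fracs = []
    for a in filter_alignments(alignments):
        depth[a.target_start:a.target_end] += 1
        fracs.append((a.target_end - a.target_start) / transcript_length)
    return depth, (float(np.mean(fracs)) if fracs else 0.0)


# ---------------------------------------------------------------------------
# Report assembly
# ---------------------------------------------------------------------------

@dataclass
class EnrichmentReport:
    """All derived statistics for one split-flow-cell run."""

    mode: str
    targets: tuple[str, ...]
    counts: dict[str, dict[str, tuple[int, int]]]  # pool -> id -> (r, b)
    compositions: dict[str, dict[str, float]]
    percent_increase_reads: dict[str, float]  # per transcript, AS vs bulk
    fold_reduction_reads: dict[str, float]  # per target (deplete mode)
    target_percent_increase: Optional[float]
    offtarget_percent_increase: Optional[float]
    rejected_pool_purity: Optional[float]
    false_rejection_rate: Optional[float]
    top_shares: dict[str, dict[int, float]]
    median_reject_len: Optional[float]
    binned: dict[str, list[dict]] = field(default_factory=dict)
    pore_decay: dict[str, dict] = field(default_factory=dict)

    def to_json(self, path=None) -> str:
        text = json.dumps(asdict(self), indent=2, default=str)
        if path is not None:
            with open(path, "w") as fh:
                fh.write(text + "\n")
        return text

    def counts_frame(self) -> pd.DataFrame:
        rows = []
        for pool, table in self.counts.items():
            for tid, (r, b) in table.items():
                rows.append({"pool": pool, "transcript": tid,
                             "reads": r, "bases": b})
        return pd.DataFrame(rows)


def build_report(
    summary: Sequence[SummaryRecord],
    decisions: Sequence[DecisionRecord],
    assignment: Mapping[str, tuple[str, int]],
    mode: str,
    targets: set[str],
    as_channels: tuple[int, int] = (257, 512),
    n_channels: int = 512,
    q_min: float = 7.0,
    attrs: Optional[Mapping[str, Mapping[str, float]]] = None,
    length_edges: Sequence[float] = LENGTH_EDGES,
    scans: Sequence[PoreScanRecord] = (),
) -> EnrichmentReport:
    """Run the full accounting pipeline and assemble the report.

    ``assignment`` maps read ids to (transcript, bases) from either the
    truth table or primary alignments.  ``attrs`` optionally supplies
    per-transcript attributes keyed by name (``length``, ``abundance``,
    ``polya``) for the binned-efficiency tables.
    """
    passing = qc_filter(summary, q_min)
    kept = [r for r in summary if r.read_id in passing]
    bulk_ids, as_ids = split_by_channel(kept, as_channels, n_channels)
    accepted_ids, rejected_ids = pool_by_decision(as_ids, decisions)

    bulk_ct = count_reads_bases(bulk_ids, assignment, "bulk")
    acc_ct = count_reads_bases(accepted_ids, assignment, "as_accepted")
    rej_ct = count_reads_bases(rejected_ids, assignment, "as_rejected")

    comps = {}
    shares: dict[str, dict[int, float]] = {}
    for ct in (bulk_ct, acc_ct, rej_ct):
        if ct.total_reads:
            comps[ct.pool] = composition(ct)
            shares[ct.pool] = {n: top_share(ct, n) for n in TOP_NS}

    pct_inc = {}
    for tid in sorted(set(bulk_ct.rows) | set(acc_ct.rows)):
        b = bulk_ct.reads(tid)
        if b > 0:
            pct_inc[tid] = percent_increase(b, acc_ct.reads(tid), decimals=1)
    folds = {}
    if mode == "deplete":
        for tid in sorted(targets):
            if acc_ct.reads(tid) > 0 and bulk_ct.reads(tid) > 0:
                folds[tid] = fold_reduction(bulk_ct.reads(tid),
                                            acc_ct.reads(tid))

    def _group_pct(tids: set[str]) -> Optional[float]:
        b = sum(bulk_ct.reads(t) for t in tids)
        a = sum(acc_ct.reads(t) for t in tids)
        return percent_increase(b, a, decimals=1) if b > 0 else None

    all_ids = set(bulk_ct.rows) | set(acc_ct.rows) | set(rej_ct.rows)
    tgt_pct = _group_pct(all_ids & targets) if targets else None
    off_pct = _group_pct(all_ids - targets)

    purity = frr = None
    if mode in ("enrich", "deplete") and rej_ct.total_reads > 0:
        purity, frr = rejected_pool_stats(rej_ct, targets, mode)

    rej_lens = [r.read_length for r in kept if r.read_id in rejected_ids]
    med = float(np.median(rej_lens)) if rej_lens else None

    binned = {}
    if attrs:
        for name, mapping in attrs.items():
            edges = length_edges if name == "length" else _decile_edges(
                mapping, bulk_ct)
            restrict = set(targets) if (mode == "deplete" and targets) \
                else None
            df = binned_efficiency(bulk_ct, acc_ct, mapping, edges,
                                   restrict=restrict)
            binned[name] = df.to_dict("records")

    decay = {}
    if len({s.scan_time for s in scans}) >= 2:
        lo, hi = as_channels
        halves = {"as": (lo, hi)}
        if lo > 1:
            halves["bulk"] = (1, lo - 1)
        for name, fit in pore_decay(scans, halves).items():
            decay[name] = {
                "rate_per_hour": fit.rate_per_hour,
                "stderr": fit.stderr,
                "counts": list(fit.counts),
                "times_h": list(fit.times_h),
            }

    return EnrichmentReport(
        mode=mode,
        targets=tuple(sorted(targets)),
        counts={ct.pool: dict(ct.rows)
                for ct in (bulk_ct, acc_ct, rej_ct)},
        compositions=comps,
        percent_increase_reads=pct_inc,
        fold_reduction_reads=folds,
        target_percent_increase=tgt_pct,
        offtarget_percent_increase=off_pct,
        rejected_pool_purity=purity,
        false_rejection_rate=frr,
        top_shares=shares,
        median_reject_len=med,
        binned=binned,
        pore_decay=decay,
    )


def _decile_edges(attr: Mapping[str, float],
                  bulk: CountTable) -> list[float]:
    """Decile edges of the attribute over transcripts seen in bulk."""
    vals = sorted(attr[t] for t in bulk.rows if t in attr)
    if not vals:
        return [0.0, math.inf]
    qs = np.quantile(vals, np.linspace(0, 1, 11))
    edges = sorted(set(float(q) for q in qs[:-1]))
    edges.append(math.inf)
    return edges
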