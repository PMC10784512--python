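"""Stochastic simulator of direct-RNA adaptive sampling ("read until").

Each flow-cell channel is an independent renewal process: wait an
exponential capture time, draw a molecule in proportion to molar
abundance, sequence it 3'->5'.  Bulk channels always sequence to
completion.  Adaptive-sampling channels apply the decision rule of
:func:`decide` at a single decision point ``break_time`` seconds into the
read:

* molecules that finish before the decision point are ``no_decision``;
* otherwise the decision is ambiguous with probability ``p_ambiguous``
  (``no_decision``, sequenced fully);
* otherwise the molecule's class (target / non-target) is perceived with
  class-specific misclassification probabilities and the run mode maps the
  perceived class to ``stop_receiving`` (sequence to completion) or
  ``unblock`` (eject: the sequenced length is the ``speed * break_time``
  bases acquired before the decision, and the pore is occupied for
  ``break_time + eject_latency`` seconds).

In depletion mode a perceived-target molecule whose full length is below
``min_seq_len`` is stop-received rather than ejected, mirroring the
``deplete_stop_receiving_min_sequence_length`` control: this is why
sub-600-base transcripts resist depletion.

Channel death is a constant-hazard process (identical across flow-cell
halves); pore scans are emitted every ``scan_interval`` seconds recording
``single_pore`` for live channels.  A closed-form renewal oracle
(:func:`analytic_composition`) gives the expected accepted-read rate per
transcript and is used to cross-check the simulator.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import Iterable, Optional

import numpy as np

from .iofmt import (
    Decision,
    DecisionRecord,
    PoreScanRecord,
    SummaryRecord,
    AlignmentRecord,
    PORE_STATE_ACTIVE,
    PORE_STATE_INACTIVE,
)
from .synthesize import TranscriptSet

#: Hazard (per second) at which ~half the pores survive a 68 h run.
DEFAULT_PORE_HAZARD = math.log(2) / (68 * 3600.0)

BULK = "bulk"
ENRICH = "enrich"
DEPLETE = "deplete"


@dataclass(frozen=True)
class RunConfig:
    """All adaptive-sampling and flow-cell parameters for one run."""

    mode: str = BULK
    targets: frozenset[str] = frozenset()
    break_time: float = 3.5  # s; the decision point
    speed: float = 70.0  # bases/s RNA translocation
    eject_latency: float = 0.5  # s to reverse current and clear the pore
    capture_mean: float = 1.0  # s, mean exponential capture wait
    min_seq_len: int = 600  # bases; depletion-mode keep-short threshold
    q_mean: float = 9.5
    q_sd: float = 1.5
    p_target_misclass: float = 0.04
    p_offtarget_misclass: float = 5e-4
    p_ambiguous: float = 0.02
    n_channels: int = 512
    as_channels: Optional[tuple[int, int]] = None  # inclusive, 1-based;
    # default: the upper half of the flow cell
    duration: float = 3 * 3600.0  # s
    scan_interval: float = 5400.0  # s between pore scans
    pore_hazard: float = 0.0  # per-second channel death rate
    seed: int = 0

    def __post_init__(self):
        if self.mode not in (BULK, ENRICH, DEPLETE):
            raise ValueError(f"unknown mode: {self.mode!r}")
        if self.break_time <= 0 or self.speed <= 0:
            raise ValueError("break_time and speed must be positive")
        for name in ("p_target_misclass", "p_offtarget_misclass",
                     "p_ambiguous"):
            p = getattr(self, name)
            if not 0.0 <= p <= 1.0:
                raise ValueError(f"{name} outside [0, 1]")
        if self.as_channels is None:
            object.__setattr__(
                self, "as_channels",
                (self.n_channels // 2 + 1, self.n_channels),
            )
        lo, hi = self.as_channels
        if not (1 <= lo <= hi <= self.n_channels):
            raise ValueError("as_channels outside the flow cell")
        if not isinstance(self.targets, frozenset):
            object.__setattr__(self, "targets", frozenset(self.targets))

    @property
    def decision_bases(self) -> float:
        """Bases acquired before the decision point."""
        return self.speed * self.break_time

    def is_as_channel(self, channel: int) -> bool:
        lo, hi = self.as_channels
        return lo <= channel <= hi


@dataclass(frozen=True)
class ReadRecord:
    read_id: str
    channel: int
    true_transcript: str
    start_time: float
    sequenced_length: int
    full_length: int
    decision: str  # stop_receiving | unblock | no_decision | bulk
    mean_q: float


@dataclass(frozen=True)
class RunOutput:
    reads: tuple[ReadRecord, ...]
    decisions: tuple[DecisionRecord, ...]
    summary: tuple[SummaryRecord, ...]
    pore_scans: tuple[PoreScanRecord, ...]
    config: RunConfig


def decide(
    full_length: int,
    is_target: bool,
    cfg: RunConfig,
    rng: np.random.Generator,
) -> tuple[str, int, float]:
    """Adaptive-sampling outcome for one molecule on an AS channel.

    Returns ``(decision, sequenced_length, occupancy_seconds)`` where the
    occupancy excludes the capture wait.
    """
    if cfg.mode not in (ENRICH, DEPLETE):
        raise RuntimeError("decide() is only defined for enrich/deplete "
                           "channels; bulk channels never decide")
    full_occ = full_length / cfg.speed
    if full_length <= cfg.decision_bases:
        return Decision.NO_DECISION.value, full_length, full_occ
    if rng.random() < cfg.p_ambiguous:
        return Decision.NO_DECISION.value, full_length, full_occ
    p_flip = cfg.p_target_misclass if is_target else cfg.p_offtarget_misclass
    perceived_target = is_target ^ (rng.random() < p_flip)
    reject_len = int(round(cfg.decision_bases))
    reject_occ = cfg.break_time + cfg.eject_latency
    if cfg.mode == ENRICH:
        if perceived_target:
            return Decision.STOP_RECEIVING.value, full_length, full_occ
        return Decision.UNBLOCK.value, reject_len, reject_occ
    # depletion mode
    if not perceived_target:
        return Decision.STOP_RECEIVING.value, full_length, full_occ
    if full_length < cfg.min_seq_len:
        return Decision.STOP_RECEIVING.value, full_length, full_occ
    return Decision.UNBLOCK.value, reject_len, reject_occ


def run_simulation(ts: TranscriptSet, cfg: RunConfig) -> RunOutput:
    """Simulate one run; deterministic given ``cfg.seed``.

    One global RNG stream seeded from ``cfg.seed`` is consumed in
    documented order: channels ascending; per channel one death-time draw,
    then per read a capture wait, a transcript index, a quality draw, and
    the decision draws of :func:`decide` (AS channels only, in the order
    its docstring states).
    """
    if cfg.duration <= 0:
        raise ValueError("duration must be positive")
    rng = np.random.default_rng(cfg.seed)
    ids = ts.ids
    lengths = np.array([t.length for t in ts])
    cum = np.cumsum(ts.abundances())
    cum[-1] = 1.0
    target_mask = np.array([tid in cfg.targets for tid in ids])

    reads: list[ReadRecord] = []
    decisions: list[DecisionRecord] = []
    summary: list[SummaryRecord] = []
    scans: list[PoreScanRecord] = []

    scan_times = np.arange(0.0, cfg.duration + 1e-9, cfg.scan_interval)
    for channel in range(1, cfg.n_channels + 1):
        death = (rng.exponential(1.0 / cfg.pore_hazard)
                 if cfg.pore_hazard > 0 else math.inf)
        horizon = min(cfg.duration, death)
        as_side = cfg.is_as_channel(channel)
        t = 0.0
        idx = 0
        while True:
            t += rng.exponential(cfg.capture_mean)
            if t >= horizon:
                break
            k = int(np.searchsorted(cum, rng.random(), side="right"))
            full_length = int(lengths[k])
            mean_q = rng.normal(cfg.q_mean, cfg.q_sd)
            if as_side and cfg.mode != BULK:
                decision, seq_len, occ = decide(
                    full_length, bool(target_mask[k]), cfg, rng
                )
            else:
                decision, seq_len, occ = (
                    BULK, full_length, full_length / cfg.speed
                )
            if t + occ > horizon:
                break  # pore still busy at run end; read not completed
            read_id = f"r{channel:04d}-{idx:06d}"
            reads.append(ReadRecord(read_id, channel, ids[k], t, seq_len,
                                    full_length, decision, mean_q))
            summary.append(SummaryRecord(read_id, channel, t, seq_len,
                                         mean_q))
            if as_side and cfg.mode != BULK:
                decisions.append(
                    DecisionRecord(read_id, channel, Decision(decision))
                )
            t += occ
            idx += 1
        for st in scan_times:
            state = PORE_STATE_ACTIVE if st < death else PORE_STATE_INACTIVE
            scans.append(PoreScanRecord(float(st), channel, state))

    scans.sort(key=lambda s: (s.scan_time, s.channel))
    return RunOutput(tuple(reads), tuple(decisions), tuple(summary),
                     tuple(scans), cfg)


def simulate_pore_scans(
    n_channels: int,
    hazard: float,
    duration: float,
    scan_interval: float = 5400.0,
    seed: int = 0,
    first_channel: int = 1,
) -> list[PoreScanRecord]:
    """Pore-scan table for a bank of channels dying at a constant hazard.

    The same death model :func:`run_simulation` uses, without generating
    reads — the pore-health analysis only needs the scan table.
    """
    rng = np.random.default_rng(seed)
    scan_times = np.arange(0.0, duration + 1e-9, scan_interval)
    scans = []
    for channel in range(first_channel, first_channel + n_channels):
        death = rng.exponential(1.0 / hazard) if hazard > 0 else math.inf
        for st in scan_times:
            state = PORE_STATE_ACTIVE if st < death else PORE_STATE_INACTIVE
            scans.append(PoreScanRecord(float(st), channel, state))
    scans.sort(key=lambda s: (s.scan_time, s.channel))
    return scans


def polya_ambiguity(ts: TranscriptSet, cfg: RunConfig,
                    min_classifiable: int = 50) -> float:
    """Abundance-weighted chance the decision window is all polyA.

    RNA threads 3'->5', so the first bases acquired are the polyA tail;
    a read is not classifiable until ``min_classifiable`` transcript-body
    bases have been seen.  Short decision times therefore leave most
    decisions ambiguous — the mechanism that makes a 1 s decision time
    ineffective.  Use the returned value as ``p_ambiguous`` for a sweep
    over ``break_time``.
    """
    return float(sum(
        t.abundance
        for t in ts
        if cfg.decision_bases - t.polya_len < min_classifiable
    ))


# ---------------------------------------------------------------------------
# Closed-form renewal oracle
# ---------------------------------------------------------------------------

def _decision_distribution(
    length: int, is_target: bool, cfg: RunConfig
) -> list[tuple[float, str, int, float]]:
    """Exact outcome distribution of :func:`decide` for one molecule.

    Returns ``(probability, decision, sequenced_length, occupancy)`` rows.
    """
    full_occ = length / cfg.speed
    if cfg.mode == BULK:
        return [(1.0, BULK, length, full_occ)]
    if length <= cfg.decision_bases:
        return [(1.0, Decision.NO_DECISION.value, length, full_occ)]
    rows = [(cfg.p_ambiguous, Decision.NO_DECISION.value, length, full_occ)]
    rest = 1.0 - cfg.p_ambiguous
    p_flip = cfg.p_target_misclass if is_target else cfg.p_offtarget_misclass
    p_perc_target = (1.0 - p_flip) if is_target else p_flip
    reject_len = int(round(cfg.decision_bases))
    reject_occ = cfg.break_time + cfg.eject_latency
    if cfg.mode == ENRICH:
        p_stop, p_unblock = p_perc_target, 1.0 - p_perc_target
    else:  # DEPLETE
        if length < cfg.min_seq_len:
            p_stop, p_unblock = 1.0, 0.0
        else:
            p_stop, p_unblock = 1.0 - p_perc_target, p_perc_target
    rows.append((rest * p_stop, Decision.STOP_RECEIVING.value, length,
                 full_occ))
    rows.append((rest * p_unblock, Decision.UNBLOCK.value, reject_len,
                 reject_occ))
    return [r for r in rows if r[0] > 0.0]


ACCEPTED_DECISIONS = {BULK, Decision.STOP_RECEIVING.value,
                      Decision.NO_DECISION.value}


@dataclass(frozen=True)
class RenewalSummary:
    """First/second moments of the per-channel renewal cycle."""

    mean_cycle: float  # s
    var_cycle: float  # s^2
    p_accept: dict[str, float]  # transcript -> P(read accepted)
    accept_rate: dict[str, float]  # transcript -> accepted reads/channel/s

    def expected_accepted(self, tid: str, channel_seconds: float) -> float:
        return self.accept_rate[tid] * channel_seconds

    def count_sd(self, tids: Iterable[str], abund: dict[str, float],
                 channel_seconds: float) -> float:
        """Approximate sd of the accepted-read count summed over ``tids``.

        Treats the count as a thinning of the total renewal count with
        mark probability q = sum_i a_i P(accept_i):
        Var = q^2 Var(N) + q(1-q) E[N], Var(N) = T sigma^2 / mu^3.
        """
        q = sum(abund[t] * self.p_accept[t] for t in tids)
        en = channel_seconds / self.mean_cycle
        varn = channel_seconds * self.var_cycle / self.mean_cycle ** 3
        return math.sqrt(max(q * q * varn + q * (1 - q) * en, 0.0))


def renewal_summary(ts: TranscriptSet, cfg: RunConfig) -> RenewalSummary:
    """Closed-form renewal moments for one channel under ``cfg``."""
    e_occ = 0.0
    e_occ2 = 0.0
    p_accept: dict[str, float] = {}
    for t in ts:
        rows = _decision_distribution(t.length, t.id in cfg.targets, cfg)
        occ1 = sum(p * occ for p, _, _, occ in rows)
        occ2 = sum(p * occ * occ for p, _, _, occ in rows)
        e_occ += t.abundance * occ1
        e_occ2 += t.abundance * occ2
        p_accept[t.id] = sum(
            p for p, dec, _, _ in rows if dec in ACCEPTED_DECISIONS
        )
    mean_cycle = cfg.capture_mean + e_occ
    # Var(W + occ) with W ~ Exp(capture_mean) independent of the molecule
    var_cycle = cfg.capture_mean ** 2 + (e_occ2 - e_occ ** 2)
    rates = {
        t.id: t.abundance * p_accept[t.id] / mean_cycle for t in ts
    }
    return RenewalSummary(mean_cycle, var_cycle, p_accept, rates)


def analytic_composition(ts: TranscriptSet, cfg: RunConfig) -> dict[str, float]:
    """Expected accepted reads per channel-second for each transcript.

    Valid for hazard 0; the renewal-reward rate is
    ``abundance_i * P(accept_i) / (capture_mean + E[occupancy])``.
    """
    return renewal_summary(ts, cfg).accept_rate


def median_decision_length(output: RunOutput) -> Optional[float]:
    """Median sequenced length of the ejected (unblock) reads.

    Returns ``None`` when the run contains no rejected reads.
    """
    lens = [r.sequenced_length for r in output.reads
            if r.decision == Decision.UNBLOCK.value]
    if not lens:
        return None
    return float(np.median(lens))


# ---------------------------------------------------------------------------
# Artifact emission and truth-derived alignments
# ---------------------------------------------------------------------------

def emit_run(output: RunOutput, outdir, write_fastq: bool = True) -> dict:
    """Write the run artifacts a real sequencer would leave behind.

    Emits the decision CSV (AS reads only), sequencing-summary TSV,
    pore-scan TSV, per-read truth TSV and optionally a FASTQ of
    uniform-random bases.  Returns the path map.
    """
    from pathlib import Path
    from . import iofmt

    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "decisions": outdir / "adaptive_sampling.csv",
        "summary": outdir / "sequencing_summary.txt",
        "pore_scan": outdir / "pore_scan_data.txt",
        "truth": outdir / "truth.tsv",
        "fastq": outdir / "reads.fastq",
    }
    iofmt.write_decisions(output.decisions, paths["decisions"])
    iofmt.write_summary(output.summary, paths["summary"])
    iofmt.write_pore_scan(output.pore_scans, paths["pore_scan"])
    iofmt.write_truth(
        [(r.read_id, r.true_transcript, r.sequenced_length)
         for r in output.reads],
        paths["truth"],
    )
    if write_fastq:
        rng = np.random.default_rng(output.config.seed)
        bases = "ACGU"
        with open(paths["fastq"], "w") as fh:
            for r in output.reads:
                seq = "".join(
                    bases[i] for i in
                    rng.integers(0, 4, size=r.sequenced_length)
                )
                qch = chr(int(round(max(r.mean_q, 0))) + 33)
                fh.write(f"@{r.read_id}\n{seq}\n+\n"
                         f"{qch * r.sequenced_length}\n")
    else:
        paths.pop("fastq")
    return paths


def perfect_alignments(output: RunOutput,
                       ts: TranscriptSet) -> list[AlignmentRecord]:
    """Error-free transcript-space alignments implied by the truth labels.

    Because RNA threads 3'->5', a read of n bases covers the 3'-most n
    bases of its molecule: transcript coordinates ``[L - n, L)``.
    """
    by_id = ts.by_id
    recs = []
    for r in output.reads:
        L = by_id[r.true_transcript].length
        recs.append(
            AlignmentRecord(r.read_id, r.true_transcript,
                            L - r.sequenced_length, L, "+", 0,
                            r.sequenced_length)
        )
    return recs


def genome_alignments(output: RunOutput,
                      ts: TranscriptSet) -> list[AlignmentRecord]:
    """Project truth reads into genome space for placed transcripts.

    A plus-strand transcript placed at ``(contig, s, e)`` has its 3' end at
    ``e``, so a read of n bases spans ``[e - n, e)``; a minus-strand
    transcript has its 3' end at ``s``, so the read spans ``[s, s + n)``.
    The alignment strand is the transcript strand.
    """
    by_id = ts.by_id
    recs = []
    for r in output.reads:
        t = by_id[r.true_transcript]
        if t.placement is None:
            raise ValueError(f"{t.id} has no genomic placement")
        contig, s, e = t.placement
        n = r.sequenced_length
        if t.strand == "+":
            start, end = e - n, e
        else:
            start, end = s, s + n
        flags = 16 if t.strand == "-" else 0
        recs.append(
            AlignmentRecord(r.read_id, contig, start, end, t.strand,
                            flags, n)
        )
    return recs
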