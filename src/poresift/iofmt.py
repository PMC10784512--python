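"""Readers and writers for the run artifacts the pipeline touches.

Covers the three MinKNOW-style tables (adaptive-sampling decision CSV,
sequencing-summary TSV, pore-scan TSV), transcript/genome alignments in
SAM or PAF, and annotation in GFF3 or BED6.  All coordinates are held
internally as 0-based half-open intervals with explicit strand; the GFF3
boundary converts to and from 1-based closed coordinates.

Dialects: the decision table is comma-delimited with a header naming at
least ``read_id,channel,decision``; the summary and pore-scan tables are
tab-delimited.  Extra columns are ignored on read and not re-emitted.
"""

from __future__ import annotations

import enum
from dataclasses import dataclass
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
import pysam


class FormatError(ValueError):
    """Raised when an input file does not match its declared dialect."""


class Decision(str, enum.Enum):
    """Adaptive-sampling outcome for one read."""

    STOP_RECEIVING = "stop_receiving"
    UNBLOCK = "unblock"
    NO_DECISION = "no_decision"


#: Pore-scan channel states. ``single_pore`` is an active sequencing-capable
#: pore; anything else counts as unavailable for the pore-health analysis.
PORE_STATE_ACTIVE = "single_pore"
PORE_STATE_INACTIVE = "unavailable"

# SAM flag bits removed by ``samtools view -F 2308``
FLAG_UNMAPPED = 4
FLAG_REVERSE = 16
FLAG_SECONDARY = 256
FLAG_SUPPLEMENTARY = 2048
EXCLUDE_MASK = FLAG_UNMAPPED | FLAG_SECONDARY | FLAG_SUPPLEMENTARY  # 2308


@dataclass(frozen=True)
class DecisionRecord:
    read_id: str
    channel: int
    decision: Decision


@dataclass(frozen=True)
class SummaryRecord:
    read_id: str
    channel: int
    start_time: float  # seconds from run start
    read_length: int  # bases
    mean_q: float  # mean per-base Phred score


@dataclass(frozen=True)
class PoreScanRecord:
    scan_time: float  # seconds from run start
    channel: int
    state: str


@dataclass(frozen=True)
class AlignmentRecord:
    """One alignment line, SAM or PAF, reduced to what counting needs."""

    read_id: str
    target_id: str
    target_start: int  # 0-based half-open
    target_end: int
    strand: str  # "+" or "-"
    flags: int
    mapped_bases: int

    @property
    def is_mapped(self) -> bool:
        return not self.flags & FLAG_UNMAPPED

    @property
    def is_primary(self) -> bool:
        return not self.flags & (FLAG_SECONDARY | FLAG_SUPPLEMENTARY)


@dataclass(frozen=True)
class AnnotationRecord:
    """One annotated feature with 0-based half-open coordinates."""

    id: str
    contig: str
    start: int
    end: int
    strand: str


# ---------------------------------------------------------------------------
# MinKNOW-style tables
# ---------------------------------------------------------------------------

_DECISION_COLS = ["read_id", "channel", "decision"]
_SUMMARY_COLS = ["read_id", "channel", "start_time", "read_length", "mean_q"]
_SCAN_COLS = ["scan_time", "channel", "state"]


def _load_table(path, required: Sequence[str], sep: str) -> pd.DataFrame:
    df = pd.read_csv(path, sep=sep, dtype={"read_id": str, "state": str},
                     float_precision="round_trip")
    missing = [c for c in required if c not in df.columns]
    if missing:
        raise FormatError(f"{path}: missing required column(s) {missing}")
    return df


def read_decisions(path) -> list[DecisionRecord]:
    """Parse an adaptive-sampling decision CSV into records.

    Unknown decision tokens are rejected with the offending token named.
    """
    df = _load_table(path, _DECISION_COLS, sep=",")
    valid = {d.value for d in Decision}
    bad = set(df["decision"].astype(str)) - valid
    if bad:
        raise ValueError(f"unknown decision token(s): {sorted(bad)}")
    return [
        DecisionRecord(str(r.read_id), int(r.channel), Decision(r.decision))
        for r in df.itertuples(index=False)
    ]


def write_decisions(records: Iterable[DecisionRecord], path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.channel, r.decision.value) for r in records],
        columns=_DECISION_COLS,
    )
    df.to_csv(path, index=False)


def read_summary(path) -> list[SummaryRecord]:
    """Parse a sequencing-summary TSV."""
    df = _load_table(path, _SUMMARY_COLS, sep="\t")
    recs = []
    for r in df.itertuples(index=False):
        length = int(r.read_length)
        if length < 1:
            raise ValueError(f"read {r.read_id}: read_length must be >= 1")
        if r.start_time < 0:
            raise ValueError(f"read {r.read_id}: negative start_time")
        recs.append(
            SummaryRecord(str(r.read_id), int(r.channel), float(r.start_time),
                          length, float(r.mean_q))
        )
    return recs


def write_summary(records: Iterable[SummaryRecord], path) -> None:
    df = pd.DataFrame(
        [(r.read_id, r.channel, r.start_time, r.read_length, r.mean_q)
         for r in records],
        columns=_SUMMARY_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


def read_pore_scan(path) -> list[PoreScanRecord]:
    """Parse a pore-scan TSV; scan times must be non-decreasing per channel."""
    df = _load_table(path, _SCAN_COLS, sep="\t")
    recs = [
        PoreScanRecord(float(r.scan_time), int(r.channel), str(r.state))
        for r in df.itertuples(index=False)
    ]
    last: dict[int, float] = {}
    for r in recs:
        if r.channel in last and r.scan_time < last[r.channel]:
            raise ValueError(
                f"channel {r.channel}: scan times not monotone "
                f"({r.scan_time} after {last[r.channel]})"
            )
        last[r.channel] = r.scan_time
    return recs


def write_pore_scan(records: Iterable[PoreScanRecord], path) -> None:
    df = pd.DataFrame(
        [(r.scan_time, r.channel, r.state) for r in records],
        columns=_SCAN_COLS,
    )
    df.to_csv(path, sep="\t", index=False)


# ---------------------------------------------------------------------------
# Alignments
# ---------------------------------------------------------------------------

def _sam_alignments(path) -> list[AlignmentRecord]:
    recs = []
    with pysam.AlignmentFile(str(path), check_sq=False) as fh:
        for aln in fh:
            if aln.is_unmapped:
                recs.append(
                    AlignmentRecord(aln.query_name, "*", 0, 0, "+",
                                    aln.flag, 0)
                )
                continue
            start = aln.reference_start
            end = aln.reference_end
            mapped = sum(
                n for op, n in (aln.cigartuples or []) if op in (0, 7, 8)
            )
            recs.append(
                AlignmentRecord(
                    aln.query_name,
                    aln.reference_name,
                    start,
                    end,
                    "-" if aln.is_reverse else "+",
                    aln.flag,
                    mapped,
                )
            )
    return recs


def _paf_alignments(path) -> list[AlignmentRecord]:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line:
                continue
            fields = line.split("\t")
            if len(fields) < 12:
                raise FormatError(f"{path}:{lineno}: PAF line has "
                                  f"{len(fields)} fields, expected >= 12")
            try:
                read_id = fields[0]
                strand = fields[4]
                target_id = fields[5]
                t_start = int(fields[7])
                t_end = int(fields[8])
                matches = int(fields[9])
            except ValueError as exc:
                raise FormatError(f"{path}:{lineno}: {exc}") from exc
            # tp:A:P (primary) vs tp:A:S (secondary); absent tag -> primary
            flags = 0
            for tag in fields[12:]:
                if tag.startswith("tp:A:"):
                    if tag[5:] == "S":
                        flags |= FLAG_SECONDARY
                    break
            if strand == "-":
                flags |= FLAG_REVERSE
            recs.append(
                AlignmentRecord(read_id, target_id, t_start, t_end, strand,
                                flags, matches)
            )
    return recs


def read_alignments(path, fmt: str = "sam_like") -> list[AlignmentRecord]:
    """Read alignments from SAM/BAM (``sam_like``) or PAF (``paf_like``)."""
    if fmt == "sam_like":
        return _sam_alignments(path)
    if fmt == "paf_like":
        return _paf_alignments(path)
    raise ValueError(f"unknown alignment format: {fmt!r}")


def filter_alignments(
    records: Iterable[AlignmentRecord],
) -> list[AlignmentRecord]:
    """Keep primary mapped alignments, dropping flag bits 4|256|2048.

    Mirrors ``samtools view -F 2308``; order is preserved and the filter is
    idempotent.
    """
    return [r for r in records if not r.flags & EXCLUDE_MASK]


# ---------------------------------------------------------------------------
# Annotation
# ---------------------------------------------------------------------------

def read_annotation(path, fmt: str = "gff3") -> list[AnnotationRecord]:
    """Read features from GFF3 or BED6, converting to 0-based half-open."""
    if fmt == "gff3":
        return _read_gff3(path)
    if fmt == "bed6":
        return _read_bed6(path)
    raise ValueError(f"unknown annotation format: {fmt!r}")


def _read_gff3(path) -> list[AnnotationRecord]:
    import gffutils

    db = gffutils.create_db(
        str(path), ":memory:", merge_strategy="create_unique",
        keep_order=True,
    )
    recs = []
    for feat in db.all_features(order_by=("seqid", "start")):
        # GFF is 1-based closed; internal is 0-based half-open
        start, end = feat.start - 1, feat.end
        if end <= start:
            raise ValueError(f"feature {feat.id}: end <= start")
        recs.append(
            AnnotationRecord(feat.id, feat.seqid, start, end,
                             feat.strand or "+")
        )
    return recs


def _read_bed6(path) -> list[AnnotationRecord]:
    recs = []
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            line = line.rstrip("\n")
            if not line or line.startswith(("#", "track", "browser")):
                continue
            fields = line.split("\t")
            if len(fields) < 6:
                raise FormatError(f"{path}:{lineno}: BED6 needs 6 fields")
            contig, start, end, name, _score, strand = fields[:6]
            start, end = int(start), int(end)
            if end <= start:
                raise ValueError(f"{path}:{lineno}: end <= start")
            recs.append(AnnotationRecord(name, contig, start, end, strand))
    return recs


def write_annotation(records: Iterable[AnnotationRecord], path,
                     fmt: str = "gff3") -> None:
    records = list(records)
    if fmt == "gff3":
        with open(path, "w") as fh:
            fh.write("##gff-version 3\n")
            for r in records:
                fh.write(
                    "\t".join([
                        r.contig, "poresift", "transcript",
                        str(r.start + 1), str(r.end), ".", r.strand, ".",
                        f"ID={r.id}",
                    ]) + "\n"
                )
    elif fmt == "bed6":
        with open(path, "w") as fh:
            for r in records:
                fh.write(
                    f"{r.contig}\t{r.start}\t{r.end}\t{r.id}\t0\t{r.strand}\n"
                )
    else:
        raise ValueError(f"unknown annotation format: {fmt!r}")


def read_truth(path) -> dict[str, tuple[str, int]]:
    """Read a truth TSV mapping read_id -> (true transcript, bases)."""
    df = _load_table(path, ["read_id", "true_transcript", "sequenced_length"],
                     sep="\t")
    return {
        str(r.read_id): (str(r.true_transcript), int(r.sequenced_length))
        for r in df.itertuples(index=False)
    }


def write_truth(rows: Iterable[tuple[str, str, int]], path) -> None:
    df = pd.DataFrame(rows,
                      columns=["read_id", "true_transcript",
                               "sequenced_length"])
    df.to_csv(path, sep="\t", index=False)
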