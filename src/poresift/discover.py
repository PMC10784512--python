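"""Unannotated-transcript discovery from genome-space alignments.

After depleting every annotated transcript, the reads that survive in
quantity are the ones the annotation does not explain.  The procedure:

1. flag reads whose same-strand overlap with annotation is at most a
   small fraction of their aligned span;
2. single-linkage cluster flagged reads by same-contig, same-strand span
   overlap, discarding clusters below a read-count floor (default 5, the
   conventional expression-detection floor);
3. classify each cluster: *antisense* when at least half its span is
   covered by opposite-strand annotation, *intergenic* when no annotation
   overlaps either strand, *other* otherwise.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Iterable, Sequence

from intervaltree import IntervalTree

from .iofmt import AlignmentRecord, AnnotationRecord

MAX_SAME_STRAND_OVERLAP = 0.2
MIN_READS = 5
ANTISENSE_SPAN_FRACTION = 0.5


@dataclass(frozen=True)
class NovelCandidate:
    id: str
    contig: str
    start: int
    end: int
    strand: str
    n_reads: int
    cls: str = "unclassified"  # antisense | intergenic | other

    def __post_init__(self):
        if self.end <= self.start:
            raise ValueError(f"{self.id}: end <= start")


def _annotation_trees(
    annotation: Iterable[AnnotationRecord],
) -> dict[tuple[str, str], IntervalTree]:
    trees: dict[tuple[str, str], IntervalTree] = {}
    for a in annotation:
        trees.setdefault((a.contig, a.strand), IntervalTree()).addi(
            a.start, a.end, a.id
        )
    return trees


def _overlap_bases(tree: IntervalTree | None, start: int, end: int) -> int:
    """Bases of [start, end) covered by any interval in the tree.

    Merges hits so stacked annotations are not double counted.
    """
    if tree is None:
        return 0
    hits = sorted(
        (max(iv.begin, start), min(iv.end, end))
        for iv in tree.overlap(start, end)
    )
    covered = 0
    cur_lo = cur_hi = None
    for lo, hi in hits:
        if cur_hi is None or lo > cur_hi:
            if cur_hi is not None:
                covered += cur_hi - cur_lo
            cur_lo, cur_hi = lo, hi
        else:
            cur_hi = max(cur_hi, hi)
    if cur_hi is not None:
        covered += cur_hi - cur_lo
    return covered


def flag_unannotated_reads(
    alignments: Sequence[AlignmentRecord],
    annotation: Iterable[AnnotationRecord],
    max_same_strand_overlap: float = MAX_SAME_STRAND_OVERLAP,
) -> list[AlignmentRecord]:
    """Reads the same-strand annotation fails to explain.

    A read passes when its same-strand overlap with annotated features is
    at most ``max_same_strand_overlap`` of its aligned span; a read fully
    antisense to a gene therefore passes.
    """
    trees = _annotation_trees(annotation)
    out = []
    for a in alignments:
        span = a.target_end - a.target_start
        if span <= 0:
            continue
        ov = _overlap_bases(trees.get((a.target_id, a.strand)),
                            a.target_start, a.target_end)
        if ov / span <= max_same_strand_overlap:
            out.append(a)
    return out


def cluster_reads(
    flagged: Sequence[AlignmentRecord],
    min_reads: int = MIN_READS,
) -> list[NovelCandidate]:
    """Single-linkage clusters of same-strand, same-contig overlapping reads.

    Clusters with fewer than ``min_reads`` members are discarded; the
    candidate span is the union of member spans.  The result is invariant
    under permutation of the input.
    """
    groups: dict[tuple[str, str], list[AlignmentRecord]] = {}
    for a in flagged:
        groups.setdefault((a.target_id, a.strand), []).append(a)
    candidates = []
    for (contig, strand), reads in sorted(groups.items()):
        reads = sorted(reads, key=lambda r: (r.target_start, r.target_end))
        cur: list[AlignmentRecord] = []
        cur_end = None
        clusters: list[list[AlignmentRecord]] = []
        for r in reads:
            if cur and r.target_start >= cur_end:
                clusters.append(cur)
                cur, cur_end = [], None
            cur.append(r)
            cur_end = r.target_end if cur_end is None \
                else max(cur_end, r.target_end)
        if cur:
            clusters.append(cur)
        for c in clusters:
            if len(c) < min_reads:
                continue
            start = min(r.target_start for r in c)
            end = max(r.target_end for r in c)
            candidates.append(
                NovelCandidate(
                    id=f"cand_{contig}_{strand}_{start}",
                    contig=contig, start=start, end=end, strand=strand,
                    n_reads=len(c),
                )
            )
    candidates.sort(key=lambda c: (c.contig, c.start, c.strand))
    return candidates


def classify_clusters(
    candidates: Sequence[NovelCandidate],
    annotation: Iterable[AnnotationRecord],
    antisense_span_fraction: float = ANTISENSE_SPAN_FRACTION,
) -> list[NovelCandidate]:
    """Attach antisense / intergenic / other labels to candidates."""
    trees = _annotation_trees(annotation)
    out = []
    for c in candidates:
        anti = "-" if c.strand == "+" else "+"
        span = c.end - c.start
        anti_ov = _overlap_bases(trees.get((c.contig, anti)), c.start, c.end)
        same_ov = _overlap_bases(trees.get((c.contig, c.strand)),
                                 c.start, c.end)
        if anti_ov >= antisense_span_fraction * span:
            cls = "antisense"
        elif anti_ov == 0 and same_ov == 0:
            cls = "intergenic"
        else:
            cls = "other"
        out.append(NovelCandidate(c.id, c.contig, c.start, c.end, c.strand,
                                  c.n_reads, cls))
    return out


def discover_novel(
    alignments: Sequence[AlignmentRecord],
    annotation: Sequence[AnnotationRecord],
    max_same_strand_overlap: float = MAX_SAME_STRAND_OVERLAP,
    min_reads: int = MIN_READS,
) -> list[NovelCandidate]:
    """Full flag -> cluster -> classify chain."""
    flagged = flag_unannotated_reads(alignments, annotation,
                                     max_same_strand_overlap)
    return classify_clusters(cluster_reads(flagged, min_reads), annotation)


def emit_candidates(candidates: Sequence[NovelCandidate], path) -> None:
    """Write candidates as BED6, score = supporting read count."""
    with open(path, "w") as fh:
        for c in candidates:
            fh.write(f"{c.contig}\t{c.start}\t{c.end}\t{c.id}\t"
                     f"{c.n_reads}\t{c.strand}\n")
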