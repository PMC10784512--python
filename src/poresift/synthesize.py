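"""Synthetic molecule universes for adaptive-sampling experiments.

Three generators cover the experimental designs the pipeline targets:

* :func:`make_ivt_pool` — a small in-vitro-transcribed benchmark pool with
  a stated molar composition (default: the four-transcript ACTB / GAPDH /
  18S rRNA / ENO2 mix at 5.6 / 16.3 / 15.6 / 62.5 %).
* :func:`make_transcriptome` — a fungal-scale transcriptome whose abundance
  profile is a calibrated log-normal: the default width puts 55 % of the
  molar mass on the 150 most abundant of 5316 transcripts, matching the
  read concentration observed in a *Candida albicans*-like transcriptome.
* :func:`plant_novel_transcripts` — lays a transcriptome onto a synthetic
  contig and plants unannotated transcripts, either antisense to an
  annotated gene or in an intergenic gap, recording the truth labels for
  discovery benchmarking.

All generators are pure functions of their seed.  Sequences, when emitted
as FASTA, are i.i.d. uniform nucleotides with a 3' polyA tract: the
simulator classifies reads by label, so sequences exist only to exercise
file formats.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field, replace
from typing import Iterable, Mapping, Optional, Sequence

import numpy as np
from scipy import stats

from .iofmt import AnnotationRecord

#: Library composition of the default IVT benchmark pool (molar fractions).
IVT_COMPOSITION = {
    "ACTB": 0.056,
    "GAPDH": 0.163,
    "18S_rRNA": 0.156,
    "ENO2": 0.625,
}

#: Approximate transcript lengths (bases) for the IVT pool members.
IVT_LENGTHS = {
    "ACTB": 1812,
    "GAPDH": 1310,
    "18S_rRNA": 1869,
    "ENO2": 1313,
}

#: polyA tract lengths appended to each IVT transcript (bases).
IVT_POLYA = {"ACTB": 30, "GAPDH": 30, "18S_rRNA": 30, "ENO2": 30}

#: Log-normal abundance width calibrated (by bisection on the quantile
#: profile) so the top 150 of 5316 transcripts hold 55 % of the molar mass.
DEFAULT_ABUNDANCE_SIGMA = 2.0542

#: Default transcriptome size: 319 band transcripts + 4997 others.
DEFAULT_N_TRANSCRIPTS = 5316

#: Default log-normal length parameters: median ~1100 bases, right-skewed,
#: in the 1200-1800 mean range typical of eukaryotic mRNAs after the
#: 200-base floor.
DEFAULT_LENGTH_PARAMS = (math.log(1100.0), 0.55)

#: Default polyA tail mean/sd in bases (yeast-like tails are short).
DEFAULT_POLYA_PARAMS = (60.0, 20.0)


@dataclass(frozen=True)
class Transcript:
    id: str
    length: int  # bases
    abundance: float  # relative molar fraction
    polya_len: int = 0
    strand: str = "+"
    placement: Optional[tuple[str, int, int]] = None  # (contig, start, end)
    annotated: bool = True

    def __post_init__(self):
        if self.length < 1:
            raise ValueError(f"{self.id}: length must be >= 1")
        if not 0.0 <= self.abundance <= 1.0:
            raise ValueError(f"{self.id}: abundance outside [0, 1]")
        if self.polya_len < 0:
            raise ValueError(f"{self.id}: negative polyA length")


@dataclass(frozen=True)
class TranscriptSet:
    transcripts: tuple[Transcript, ...]
    seed: int = 0

    def __post_init__(self):
        ids = [t.id for t in self.transcripts]
        if len(set(ids)) != len(ids):
            raise ValueError("transcript ids are not unique")
        total = sum(t.abundance for t in self.transcripts)
        if self.transcripts and abs(total - 1.0) > 1e-9:
            raise ValueError(f"abundances sum to {total}, expected 1")

    def __iter__(self):
        return iter(self.transcripts)

    def __len__(self):
        return len(self.transcripts)

    def __getitem__(self, tid: str) -> Transcript:
        return self.by_id[tid]

    @property
    def by_id(self) -> dict[str, Transcript]:
        return {t.id: t for t in self.transcripts}

    @property
    def ids(self) -> list[str]:
        return [t.id for t in self.transcripts]

    def abundances(self) -> np.ndarray:
        return np.array([t.abundance for t in self.transcripts])


def _normalize(values: np.ndarray) -> np.ndarray:
    total = values.sum()
    out = values / total
    # force exact unit sum so the set invariant holds to 1e-9
    out[-1] = 1.0 - out[:-1].sum()
    return out


def make_ivt_pool(
    composition: Mapping[str, float] = IVT_COMPOSITION,
    lengths: Mapping[str, int] = IVT_LENGTHS,
    polya: Mapping[str, int] = IVT_POLYA,
    seed: int = 0,
) -> TranscriptSet:
    """Build an IVT benchmark pool from a stated molar composition.

    Fractions must sum to 1 within 1e-6 and are renormalized exactly.
    """
    fracs = np.array([composition[k] for k in composition], dtype=float)
    if (fracs < 0).any():
        raise ValueError("composition fractions must be non-negative")
    if abs(fracs.sum() - 1.0) > 1e-6:
        raise ValueError(f"composition sums to {fracs.sum():.6f}, expected 1")
    fracs = _normalize(fracs)
    transcripts = tuple(
        Transcript(
            id=tid,
            length=int(lengths[tid]),
            abundance=float(frac),
            polya_len=int(polya.get(tid, 0)) if polya else 0,
        )
        for tid, frac in zip(composition, fracs)
    )
    return TranscriptSet(transcripts, seed=seed)


def make_transcriptome(
    n: int = DEFAULT_N_TRANSCRIPTS,
    abundance_sigma: float = DEFAULT_ABUNDANCE_SIGMA,
    length_params: tuple[float, float] = DEFAULT_LENGTH_PARAMS,
    polya_params: tuple[float, float] = DEFAULT_POLYA_PARAMS,
    seed: int = 0,
    abundance_method: str = "quantile",
    min_length: int = 200,
) -> TranscriptSet:
    """Generate a transcriptome with a log-normal abundance profile.

    ``abundance_method="quantile"`` (default) evaluates the log-normal at
    evenly spaced quantiles, so the concentration of mass in the top
    transcripts is a deterministic property of ``abundance_sigma``; the
    seed randomizes which transcript receives which abundance, lengths and
    polyA tails.  ``"iid"`` draws abundances independently instead.
    Lengths are log-normal floored at ``min_length``.
    """
    if n < 1:
        raise ValueError("n must be >= 1")
    if abundance_sigma <= 0:
        raise ValueError("abundance_sigma must be positive")
    rng = np.random.default_rng(seed)
    if abundance_method == "quantile":
        q = (np.arange(n) + 0.5) / n
        raw = np.exp(abundance_sigma * stats.norm.ppf(q))
        rng.shuffle(raw)
    elif abundance_method == "iid":
        raw = rng.lognormal(0.0, abundance_sigma, size=n)
    else:
        raise ValueError(f"unknown abundance_method: {abundance_method!r}")
    abund = _normalize(raw)

    mu_len, sd_len = length_params
    lengths = np.maximum(
        np.round(rng.lognormal(mu_len, sd_len, size=n)), min_length
    ).astype(int)
    pa_mean, pa_sd = polya_params
    polya = np.maximum(
        np.round(rng.normal(pa_mean, pa_sd, size=n)), 0
    ).astype(int)
    width = len(str(n))
    transcripts = tuple(
        Transcript(
            id=f"T{i:0{width}d}",
            length=int(lengths[i]),
            abundance=float(abund[i]),
            polya_len=int(polya[i]),
        )
        for i in range(n)
    )
    return TranscriptSet(transcripts, seed=seed)


def select_percentile_band(
    ts: TranscriptSet, lo: float, hi: float
) -> list[str]:
    """Ids whose abundance rank percentile lies in ``[lo, hi)``.

    Ranks ascend with abundance; ties are broken by ascending id so the
    selection is deterministic.  A transcript at rank r out of n sits at
    percentile 100*r/n.
    """
    if not 0 <= lo < hi <= 100:
        raise ValueError(f"invalid percentile band [{lo}, {hi})")
    order = sorted(ts, key=lambda t: (t.abundance, t.id))
    n = len(order)
    return [
        t.id
        for r, t in enumerate(order)
        if lo <= 100.0 * r / n < hi
    ]


#: Target lengths spanning the four efficiency bins
#: (200-400, 400-600, 600-1000, >1000 bases).
LADDER_LENGTHS = (250, 300, 350, 450, 500, 550, 700, 850, 950,
                  1300, 1700, 2200)


def make_length_ladder(
    target_abundance_total: float = 0.15,
    n_background: int = 8,
    background_length: int = 1200,
    polya_len: int = 30,
) -> tuple[TranscriptSet, frozenset[str]]:
    """A deterministic depletion benchmark: targets spanning length bins.

    Twelve equal-abundance depletion targets cover the four length bins
    (three per bin) at a modest total molar share, over a uniform
    background of non-targets; with this set the depletion-efficiency
    dependence on length — short targets spared by the minimum-sequence-
    length rule, long targets ejected — is measurable in every bin.
    Returns the set and the target id frozenset.
    """
    per_target = target_abundance_total / len(LADDER_LENGTHS)
    per_bg = (1.0 - target_abundance_total) / n_background
    transcripts = [
        Transcript(f"tgt{L:04d}", L, per_target, polya_len=polya_len)
        for L in LADDER_LENGTHS
    ]
    transcripts += [
        Transcript(f"bg{i:02d}", background_length, per_bg,
                   polya_len=polya_len)
        for i in range(n_background)
    ]
    raw = np.array([t.abundance for t in transcripts])
    norm = _normalize(raw)
    transcripts = [replace(t, abundance=float(a))
                   for t, a in zip(transcripts, norm)]
    targets = frozenset(t.id for t in transcripts if t.id.startswith("tgt"))
    return TranscriptSet(tuple(transcripts)), targets


@dataclass(frozen=True)
class NovelTruth:
    """Ground-truth record for one planted unannotated transcript."""

    id: str
    contig: str
    start: int
    end: int
    strand: str
    cls: str  # "antisense" | "intergenic"


def place_on_contig(
    ts: TranscriptSet,
    contig: str = "chrS",
    gap: int = 2000,
    seed: int = 0,
) -> TranscriptSet:
    """Lay transcripts end-to-end on one synthetic contig with fixed gaps.

    Strands alternate deterministically unless already set; existing
    placements are overwritten.
    """
    rng = np.random.default_rng(seed)
    placed = []
    pos = gap
    for i, t in enumerate(ts):
        strand = "+" if rng.random() < 0.5 else "-"
        placed.append(
            replace(t, strand=strand,
                    placement=(contig, pos, pos + t.length))
        )
        pos += t.length + gap
    return TranscriptSet(tuple(placed), seed=ts.seed)


def plant_novel_transcripts(
    ts: TranscriptSet,
    n_novel: int,
    antisense_fraction: float,
    seed: int = 0,
    novel_length_params: tuple[float, float] | None = None,
    novel_abundance_scale: float = 0.1,
    min_length: int = 200,
) -> tuple[TranscriptSet, list[AnnotationRecord], list[NovelTruth]]:
    """Plant unannotated transcripts in a placed transcriptome.

    ``round(n_novel * antisense_fraction)`` of the planted transcripts are
    antisense — placed overlapping a random annotated transcript on the
    opposite strand — and the rest intergenic, placed inside a gap between
    annotated placements; class order is shuffled by the seed.  Novel transcripts are shorter (the
    length log-mean is shifted down ~40 %) and far less abundant than
    annotated ones; the whole set is renormalized afterwards.

    Returns the augmented set, the annotation of the *annotated* features
    only, and the truth list with class labels.
    """
    if not 0.0 <= antisense_fraction <= 1.0:
        raise ValueError("antisense_fraction outside [0, 1]")
    if any(t.placement is None for t in ts):
        ts = place_on_contig(ts, seed=seed)
    rng = np.random.default_rng(seed)

    annotated = sorted(ts, key=lambda t: t.placement[1])
    annotation = [
        AnnotationRecord(t.id, t.placement[0], t.placement[1],
                         t.placement[2], t.strand)
        for t in annotated
    ]
    if n_novel == 0:
        return ts, annotation, []

    # intergenic gaps between consecutive annotated spans
    gaps = []
    for a, b in zip(annotated, annotated[1:]):
        lo, hi = a.placement[2], b.placement[1]
        if hi - lo >= min_length + 2:
            gaps.append((a.placement[0], lo, hi))
    if not gaps:
        raise ValueError("no intergenic gap available for planting")

    if novel_length_params is None:
        mu, sd = DEFAULT_LENGTH_PARAMS
        novel_length_params = (mu - 0.5, sd)  # generally shorter

    # exact class allocation: round(n * fraction) antisense, order shuffled,
    # so a stated class split (e.g. 17 of 26) is reproduced, not just expected
    n_anti = int(round(n_novel * antisense_fraction))
    class_is_anti = np.zeros(n_novel, dtype=bool)
    class_is_anti[:n_anti] = True
    rng.shuffle(class_is_anti)

    mean_abund = float(np.mean([t.abundance for t in ts]))
    new: list[Transcript] = []
    truths: list[NovelTruth] = []
    for k in range(n_novel):
        tid = f"novel{k:03d}"
        is_anti = bool(class_is_anti[k])
        length = int(max(
            round(rng.lognormal(*novel_length_params)), min_length
        ))
        abund = mean_abund * novel_abundance_scale * rng.uniform(0.5, 1.5)
        if is_anti:
            host = annotated[rng.integers(len(annotated))]
            contig, hstart, hend = host.placement
            length = min(length, hend - hstart)
            start = int(rng.integers(hstart, hend - length + 1))
            strand = "-" if host.strand == "+" else "+"
            cls = "antisense"
        else:
            contig, glo, ghi = gaps[rng.integers(len(gaps))]
            length = min(length, ghi - glo - 2)
            start = glo + 1 + int(rng.integers(ghi - glo - 1 - length))
            strand = "+" if rng.random() < 0.5 else "-"
            cls = "intergenic"
        end = start + length
        new.append(
            Transcript(tid, length, abund, polya_len=30, strand=strand,
                       placement=(contig, start, end), annotated=False)
        )
        truths.append(NovelTruth(tid, contig, start, end, strand, cls))

    all_t = list(ts) + new
    raw = np.array([t.abundance for t in all_t])
    norm = _normalize(raw)
    out = tuple(replace(t, abundance=float(a)) for t, a in zip(all_t, norm))
    return TranscriptSet(out, seed=ts.seed), annotation, truths


# ---------------------------------------------------------------------------
# Artifact emission
# ---------------------------------------------------------------------------

def write_fasta(ts: TranscriptSet, path, seed: int = 0) -> None:
    """Emit uniform-random sequences with 3' polyA tracts as FASTA."""
    from Bio import SeqIO
    from Bio.Seq import Seq
    from Bio.SeqRecord import SeqRecord

    rng = np.random.default_rng(seed)
    bases = np.array(list("ACGU"))
    records = []
    for t in ts:
        body = "".join(rng.choice(bases, size=t.length - t.polya_len)) \
            if t.length > t.polya_len else ""
        seq = body + "A" * min(t.polya_len, t.length)
        records.append(SeqRecord(Seq(seq), id=t.id, description=""))
    SeqIO.write(records, str(path), "fasta")


def write_truth_table(ts: TranscriptSet, path) -> None:
    """TSV of per-transcript ground truth attributes."""
    import pandas as pd

    rows = [
        {
            "id": t.id,
            "length": t.length,
            "abundance": t.abundance,
            "polya_len": t.polya_len,
            "annotated": t.annotated,
            "strand": t.strand,
        }
        for t in ts
    ]
    pd.DataFrame(rows).to_csv(path, sep="\t", index=False)
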