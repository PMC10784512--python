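# Methods

## Decision model

Adaptive sampling is modelled with a single decision point per read, at
`break_time` seconds after capture. Real sequencer software re-evaluates
the read in chunks, but no chunk schedule is published and the one knob
that was varied experimentally is the break time, so one decision at
`t_b` is the parsimonious model. Consequences: every ejected read carries
exactly `round(speed × break_time)` bases (70 b/s × 3.5 s = 245), and a
molecule shorter than `speed × t_b` always finishes as `no_decision`
(boundary inclusive: a 245-base molecule at 3.5 s completes).

Classification is label-level, not sequence-level: a target read is
perceived non-target with probability `p_target_misclass` (default 0.04)
and a non-target read perceived target with `p_offtarget_misclass`
(default 5×10⁻⁴, which keeps depletion-mode false rejections under 0.1 %
of the rejected pool, the regime observed in practice). The run measures
decision *outcomes*; modelling the basecall-and-map internals would add
parameters with nothing to calibrate them against. One consequence worth
stating: with a rare enrichment target, the rejected pool is dominated by
true non-targets, so its contamination by targets is
`a_t·p_t / (a_t·p_t + a_o)` — well below `p_t` itself. The per-read
misclassification probability and the measured rejected-pool
contamination are different quantities and should not be compared
directly.

Ambiguity (`p_ambiguous`, default 0.02) models decisions that time out or
cannot be called; ambiguous reads complete and land in the accepted pool.
For decision-time sweeps, `simulate.polya_ambiguity` derives an effective
`p_ambiguous` from tail geometry: RNA is read 3′→5′, so the first
`polya_len` bases of the decision window are uninformative homopolymer,
and a read is not classifiable until ~50 transcript-body bases have been
seen. At a 1 s break time (70 bases) a typical tail fills the entire
window, which is why 1 s runs behave like bulk sequencing and the
enrichment gain over break time rises and then falls.

The depletion-mode minimum-sequence-length rule is implemented as:
perceived targets whose **full molecule length** is below `min_seq_len`
(600) are stop-received rather than ejected. Whether the real control
compares basecalled length or an estimated molecule length is not
documented; this interpretation is the one that reproduces the observed
failure to deplete sub-600-base transcripts. It is a modelling choice,
not established fact.

A stated open discrepancy is left unresolved: at 70 b/s a 3.5 s decision
window is 245 bases, yet observed median rejected-read lengths (276–372
bases) and the "~350 bases" rule of thumb imply a higher effective
throughput per decision. `speed` and `break_time` are independent knobs;
the simulator reproduces the *monotone increase* of rejected-read length
with break time, not the absolute medians.

## Renewal oracle

Each channel is a renewal process with cycle = capture wait +
occupancy. `simulate.renewal_summary` computes exact first and second
moments of the cycle from the decision-outcome distribution per
transcript, giving the expected accepted-read rate
`a_i P(accept_i) / E[cycle]` and a variance approximation for counts
(thinned renewal: `Var ≈ q²·t·σ²/μ³ + q(1−q)·t/μ`, ignoring the
correlation between a cycle's mark and its length). Simulator-vs-oracle
tests use a 3-standard-deviation band on per-class accepted counts; the
variance approximation is adequate at the class sizes tested (≥50
expected reads).

Channel death is a constant hazard, identical across flow-cell halves
(the observed pore decay showed no difference between halves); the
default hazard, ln 2 / 68 h ≈ 2.83×10⁻⁶ s⁻¹, lets half the pores survive
a 68 h run. Pore scans are emitted every 1.5 h (5400 s), including one at
t = 0.

Randomness: one `numpy` Generator seeded from `RunConfig.seed`, consumed
in documented order (channels ascending; per channel a death draw, then
per read: capture wait, transcript index, quality, decision draws).
Identical seeds give bit-identical `RunOutput`.

## Synthetic universes

**IVT pool.** Four transcripts at the benchmark molar composition
(ACTB 5.6 %, GAPDH 16.3 %, 18S rRNA 15.6 %, ENO2 62.5 %) with lengths
near their real transcript lengths (1812 / 1310 / 1869 / 1313 bases) and
30-base polyA tracts.

**Transcriptome.** 5316 transcripts; log-normal abundance profile with
σ = 2.0542, frozen by bisection so the top 150 transcripts hold exactly
55 % of the molar mass — the one concentration statistic available to
calibrate against. The default profile is *quantile-spaced* on that
log-normal (evaluate the inverse CDF at evenly spaced quantiles, then
shuffle the assignment to ids): concentration is then a construction
invariant rather than a per-seed random outcome, which is the property a
benchmark universe should have; `abundance_method="iid"` draws
independently instead and reproduces 55 % only on average (±3.7 points
s.d. across seeds). Lengths are log-normal (median ~1100 bases, floored
at 200); polyA tails Normal(60, 20) clipped at 0. The abundance family is
a stand-in validated only against the printed top-N shares; lengths and
tails are plausible for a fungal polyA-selected library but uncalibrated.

**Length ladder.** A deterministic depletion benchmark: twelve
equal-abundance targets, three per length bin
(200–400 / 400–600 / 600–1000 / >1000 bases), totalling 15 % of molar
mass over a uniform 1200-base background. The modest target mass is
deliberate — keeping the ejected fraction small limits the composition
renormalization that otherwise confounds per-bin ratios (below).

**Planted novelties.** Annotated transcripts are laid end-to-end on a
synthetic contig with 2 kb gaps, strands random. `round(n·fraction)` of
the planted novel transcripts overlap an annotated gene on the opposite
strand (antisense), the rest sit inside gaps (intergenic) — exact
allocation, so a stated split such as 17 of 26 is reproduced, not merely
expected. Novels are shorter (length log-mean shifted down 0.5) and rare
(≈10 % of the mean annotated abundance each), mirroring why such
transcripts hide under abundant neighbours. FASTA sequences, when
emitted, are i.i.d. uniform bases plus the 3′ polyA tract: the simulator
classifies by label, so sequences exist only to exercise file formats.

## Accounting definitions

* Q-filter: mean per-base Phred ≥ 7, inclusive; mean-of-scores dialect.
* Pools: accepted = `stop_receiving` ∪ `no_decision`; rejected =
  `unblock`; an adaptive-half read without a decision row is an error,
  not a silent accept.
* Alignment filtering: drop flag bits 4|256|2048 (unmapped, secondary,
  supplementary), the `-F 2308` convention. Counting uses truth labels
  (bases = sequenced length) or primary alignments (bases = mapped
  bases); on error-free alignments the two agree exactly.
* Rounding: whole-percent claims use half-up; the one-decimal base-level
  claim uses truncation (22.85 → 22.8); both exposed as a flag.
* False rejection rate = share of the rejected pool inconsistent with the
  run's intent (targets in enrichment, non-targets in depletion);
  purity = 1 − FRR.
* Binned efficiency: per-transcript percent of pool reads, grouped by
  length (fixed edges 200/400/600/1000), abundance or polyA (decile edges
  over transcripts seen in bulk — no published edges exist for those).

**Reference-normalized depletion ratio.** Ejecting mass `m` from the pool
mechanically inflates every surviving transcript's accepted-pool share by
`1/(1−m(1−P_accept))`; the raw bulk-share / accepted-share ratio of a
*spared* class therefore sits below 1 by exactly that factor.
`quantify.reference_normalized_ratio` divides each class share by the
share of a reference class the run does not act on (the non-targets),
cancelling the factor; the statistic then estimates `1/P(accept)` — 1 for
spared transcripts, `1/(p_amb + p_t)` ≈ 17 for ejected ones. Mechanism
tests (short targets spared, long targets depleted) use this estimand on
the pooled <600 and >1000 classes.

**Monotonicity testing.** Under this decision model the expected
depletion ratio is *tied* within {200–400, 400–600} (both spared) and
within {600–1000, >1000} (both ejected with identical probability): the
only length effect is the 600-base threshold, since the decision sees the
same 245-base prefix regardless of molecule length. Sampled ratios break
ties by noise, so "non-decreasing across bins" is tested as: the log-ratio
difference between adjacent bins is ≥ −3 propagated binomial standard
errors. This convention is fixed here, before measurement, as the
definition of the check. The real data's finer gradient above 600 bases
(and its abundance dependence) likely reflects classification behaviour
this label-level model deliberately does not include — a known
limitation: the model predicts *no* abundance or polyA dependence of
depletion efficiency.

**Pore decay.** Per half: `single_pore` counts per scan and a log-linear
least-squares rate (descriptive). For *comparing* halves, the OLS
standard error is invalid — the same channels persist between scans, so
residuals are strongly autocorrelated — and `pore_hazard_mle` is used
instead: the binomial survival MLE `−log(S/N)/T` with delta-method
standard error. Equal-hazard halves are declared indistinguishable when
the two-estimate z-statistic is within ±3.

## Problem sizes

Tests and the acceptance script run the simulator at desk scale — 8–256
channels and 0.5–4 simulated hours (10⁴–10⁵ reads per run), 68 simulated
hours for pore-health scans — sizes chosen so class-level Monte-Carlo
error stays well inside the 3-s.d. test bands while a full suite run
completes in about a minute. Published absolute read counts are inputs to
the derived-statistic arithmetic, never simulation targets.

## Limitations

* No signal-space modelling, basecall latency, chunked re-evaluation, or
  RNA secondary-structure effects on translocation.
* Misclassification is length- and abundance-independent, so the observed
  gradients within the ejected length range, and across abundance bins,
  are outside the model (see Monotonicity above).
* Sequences are random; alignment in tests is truth-derived, so mapping
  artefacts (multimapping, clipping) are out of scope.
* The transcriptome abundance family is an assumption; only its top-N
  concentration is calibrated.
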