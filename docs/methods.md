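# Methods

This note documents the models, defaults, and numerical choices behind
`replitime`, and what the simulation studies do and do not establish.

## Generative model

A condition's replication program is a piecewise-constant latent timing
track t(x) ∈ [0, 1] over the genome (0 = earliest).  A G1 cell carries one
relative copy of every locus.  A sorted S-phase cell at progression
fraction f carries two relative copies of loci with t < f and one
otherwise, so the expected relative copy number over an S gate is
1 + P(f > t); with the default uniform progression this is 2 − t.  The
progression distribution is configurable (any distribution with a `cdf` on
[0, 1]) because the DNA-content gate boundaries of a real sort shape it in
ways that are not identifiable from the data itself; uniform is the minimal
assumption.

Reads are single-end points (the analysis is strictly per-position, BED
granularity; no fragments, no GC model, no sequence).  Per sample, counts
in each atomic interval are Poisson with mean proportional to

    length × copy(t, phase) × u × 2^ε,

where u ∈ (0, 1] is an optional annotation-scoped underreplication factor
(applied to both phases of that condition — it models a copy-number
property of the tissue's genome) and ε ~ N(0, σ) is window-level
multiplicative replicate noise drawn per 100-kb noise window, per sample.
Positions are uniform within intervals.  Totals are Poisson around the
configured library size.  MAPQ is 60 except inside an optional
low-mappability annotation, where it is drawn in {0..10} to exercise the
filter.  All draws flow through one seeded generator, so read sets are
byte-reproducible.

### Replicate noise default (σ = 0.06 log2 units)

σ is the one free nuisance parameter; it was set by requiring the model to
reproduce two observed operating characteristics simultaneously:

1. inter-replicate RT correlations of ~0.9–0.95, as seen for real
   replicate pairs — with a pooled G1 control and a timing track spanning
   the full [0, 1] range, σ = 0.06 gives r ≈ 0.93–0.95, whereas σ = 0.1
   pushes r below 0.9;
2. the documented power of the caller: at a planted RT difference of 0.3
   log2 units with 3 vs 3 replicates, the standard error of the mean
   difference is σ·√(2/3), so σ = 0.06 puts the effect at z ≈ 6 (power
   ~0.99 after BH), while σ = 0.1 caps power near 0.7 regardless of depth.

Counting (Poisson) noise adds ~1/(ln2·√N) per window of N reads and is
secondary at the depths used (≥ 500 reads per 100-kb window).

## Coverage and RT values

Windows are fixed-size (default 100 kb) on a fixed step (default 10 kb),
starting at 0 on every chromosome; trailing partial windows are dropped.
A read at position p counts in every window with start ≤ p < end.  The
MAPQ filter retains reads with MAPQ strictly greater than 10 (a flag
switches to ≥).  RPM divides by the per-sample retained total.

RT per S replicate is log2(RPM_S / RPM_G1).  The default G1 denominator
pools all G1 replicates (mean RPM) into one shared copy-number control,
mirroring a single control tissue used for every sample.  This choice is
also statistically load-bearing: a denominator shared by both conditions
cancels from between-condition mean differences and never enters
within-condition variances, so the two-sample moderated t stays calibrated.
Per-replicate or per-tissue pairings are supported through the pairing map.
Windows with zero coverage in any participating column are masked (removed
from all columns, logged) unless a pseudo-count is supplied.

Quantile normalization replaces each column's rank-r value by the mean of
the r-th order statistics across columns; ties receive the mean of the
reference values over the tied rank span.  For tie-free (continuous)
columns the map is a projection — sorted multisets become identical and a
second application is a no-op.  With within-column ties both properties can
fail by the tie-averaging rule itself (as in the standard algorithm); RT
values are continuous so this does not arise in practice.

**Known behaviour at the distribution tails.** Quantile normalization
forces identical marginals.  When a real RT difference is one-sided (one
condition has extra mass at an extreme), the forced matching slightly
compresses genuine shifts at the extremes and stretches null windows that
happen to occupy extreme ranks.  With balanced or interior differences the
effect is negligible; with strongly one-sided planted programs it produces
a small excess of calls at the timing extremes.  This is inherited from the
normalization step itself, not the test statistic.

## Differential calling

Per window, the pooled two-sample residual variance s² (d = nA + nB − 2 df)
is shrunk toward a prior scale s₀² with prior df d₀, estimated across
windows by moment-matching the marginal distribution of log s²
(digamma/trigamma equations; the trigamma inverse is solved by Newton
iteration).  The moderated statistic is

    t = (mean_A − mean_B) / ( s̃ √(1/nA + 1/nB) ),   s̃² = (d₀s₀² + d·s²)/(d₀+d),

with two-sided p-values on d₀ + d degrees of freedom (standard normal when
d₀ = ∞; d₀ = 0 reproduces the ordinary equal-variance t exactly and is
available as an override).  If every window variance is zero, the prior
falls back to d₀ = ∞ with s₀² taken from the between-window spread of the
mean difference (logged).  No variance–mean trend is fitted: after quantile
normalization RT values are variance-homogeneous by construction, and the
estimated d₀ is routinely large, which is the shrinkage behaving as
designed.  Multiple testing uses Benjamini–Hochberg; calls require
adjusted p < 0.01 AND |log2 FC| > 0.1, both strict, with the sign of the
fold change separating advanced from delayed.  Overlapping sliding windows
are tested independently — a deliberate reproduction of the established
pipeline, not a claim that neighbouring tests are independent.

Fine mapping assigns each 10-kb window the median (mean-of-middle-two for
even counts) of every 100-kb window fully containing it (≤ 10 of them) and
re-applies thresholds at adjusted p < 0.05, |log2 FC| > 0.1; fine windows
covered by zero retained coarse windows are absent.  Window-set overlap
follows bedtools `intersect -f 0.5 -u` semantics (a query window reported
once if any single subject window covers at least half of it, boundary
inclusive).  A window counts as inside an annotation when ≥ 50% of its
length lies in the merged annotation intervals.

## Profiles and domains

LOESS is tricube-weighted local *linear* regression with a fixed genomic
bandwidth (default 250 kb; must be ≥ the grid step), evaluated at every
window midpoint per chromosome and clipped to the data range.  If fewer
than two points carry weight at an evaluation point (degenerate chromosome
ends), the three nearest points are used unweighted.  Chromosomes with
fewer than two windows are skipped with a warning.

Extrema of the smoothed profile are detected with a prominence threshold
(default 0.1 log2 units; plateaus take their midpoint); where two same-type
extrema remain adjacent the lesser (lower peak / higher valley) is
discarded until the sequence alternates.  Domain boundaries sit at the
arithmetic midpoints between adjacent extrema; each domain contains exactly
one extremum and is classed early (peak) or late (valley).  Terminal
domains are clipped at chromosome ends, flagged, and excluded from size
distributions by default.  Boundaries are invariant to positive rescaling
of the profile when the prominence threshold is scaled with it.

## Spike-in contamination analysis

Mixtures take exactly round(π·total) contaminant reads (round-half-even;
the full-scale design's counts — 3×10⁵ of 3×10⁷ at 1%, etc. — are exact
multiples) and total − round(π·total) base reads, sampled uniformly without
replacement from the source replicates and provenance-tagged.  Each mixture
is compared to the pure base through the full coverage → RT → differential
pipeline; sensitivity is measured against a truth set — the generator's
planted differential windows for synthetic runs (so it is measured against
ground truth, not against the caller's own pure-comparison output; the
latter is selectable).  The zero-impurity null is a fresh subsample of the
base compared against the base itself.  The gate-purity bound is
100·e/(m+e) for m target and e contaminating cells (50% at 1024 + 1024).

## Transcript integration

Differential expression reuses the moderated-t engine on
log2 CPM with a 0.5 pseudo-count; significance follows the raw p < 0.01
convention.  CPM is a relative measure, so global abundance shifts are not
identifiable (no TMM-style compositional correction is attempted); planted
fold changes are recovered relative to the null background.  "Expressed"
means mean TPM > 0 across replicates in a condition; classes are shared /
A-specific / B-specific / silent.  Transcript→window assignment uses ≥1 bp
overlap (unlike the 50% window↔window rule) with three schemes — mean
log FC, lowest-p transcript, max-|log FC| transcript (ties broken by
smaller raw p, then transcript id) — and windows without transcripts carry
no value.  Concordance cross-tabulates RT calls against the presence of a
direction-concordant significant transcript and reports the correlation of
expression vs RT fold changes over transcript-bearing windows.

## Validation studies and problem sizes

The studies in `replitime.validation` (used by the test suite and
`scripts/acceptance.py`) run the full pipeline at sizes chosen to keep a
single-CPU run in seconds-to-minutes while staying in the depth regime
where window noise, not counting noise, dominates:

| study | design |
|---|---|
| null comparison | 20 seeds × 2000 non-overlapping 100-kb windows, identical random-block programs, 3v3, 10⁶ reads/sample |
| planted recovery | 500 windows, 15% shifted by exactly 0.3 log2 units (direction keeping t ∈ [0,1]), 3v3, 2×10⁶ reads/sample |
| RT fidelity | 8 Mb, random 100-kb blocks, 10⁶ reads/Mb, 3 replicates, sliding 100-kb/10-kb grid |
| domain recovery | 8 Mb square wave of 400-kb domains, LOESS bandwidth 100 kb (¼ of the domain size), prominence 0.1 |
| spike-in | 5 seeds × 10 Mb, 30% of windows early↔late swapped in the contaminant, 3×10⁵-read mixtures from 6×10⁵-read sources |

In the planted-recovery study the base timing spans (0.05, 0.95); planting
all shifts outside the base range instead would trigger the quantile-
normalization tail effect described above and is not representative of
tissue comparisons, where both conditions span the full timing range.

What passing these studies shows: the arithmetic of every stage is right,
the test statistic is calibrated under the generator's noise model, and
planted signals of the documented size are recovered at the documented
operating characteristics.  What they do not show: robustness to real-data
features the generator omits — mappability structure beyond a binary flag,
GC and fragment-length bias, copy-number variation other than planted
underreplication, spatially correlated biological noise, and alignment
artifacts.  Conclusions about real libraries still require the usual QC.

## Degenerate inputs and tie-breaks

Zero-variance windows: shrunk toward the prior (or the global fallback
above).  Zero-coverage windows: masked before RT, logged.  Chromosomes
shorter than one window: zero windows, not an error.  Even-count medians:
mean of the middle two.  Assignment ties: smaller raw p, then transcript
id.  Extremum ties during alternation enforcement: the first is kept.
Round-half-even for spike-in read counts.  All thresholds are strict
inequalities as documented.
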