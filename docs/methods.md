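# Methods

This note documents the models, parameter choices and numerical conventions
behind the package, and what the synthetic-data generators do and do not
emulate.

## Coordinates and data model

All intervals are 0-based, half-open `[start, end)` (the BED convention);
1-based positions appear only in labeled display output. Transcripts keep
genomic orientation (on the minus strand the TSS is the larger coordinate);
every anchored profile tiles windows in genomic order and reverses the
per-transcript vector on the minus strand so "downstream" always means
5'→3'. The center of an interval is `start + floor(len/2)`. Nearest-gene
ties break by smaller distance, then lexicographic id.

`CoverageTrack` stores per-base depth of fragments extended to 300 bp (the
expected sequencing-fragment size) plus the total mapped-fragment count;
tracks built from fragment lists also retain sorted fragment starts so bins
can be scored by overlapping-fragment counts.
RPKM of a bin is `fragments overlapping bin × 10^9 / (bin length × total
mapped)`; "per million" scaling is `× 10^6 / total mapped`.

## DamID normalization

Step one removes within-chip GC and dye bias. Probes are binned by GC
content with the zero-stage (normal-scale) width
`h = 3.49·min(sd, IQR/1.349)·n^(-1/3)`; contiguous-in-GC bins are merged
left-to-right until each holds ≥ 500 probes (probes with equal GC share a
bin). Within each bin a robust lowess (span 2/3, 3 robustifying iterations —
the classic defaults) predicts log2 cy5 (fusion channel) from log2 cy3
(Dam-only control, the co-hybridized color of the same chip); the normalized
signal is the residual divided by the bin's median absolute residual. Probes
that *are* their bin's median-|residual| element scale to exactly ±1, which
produces a handful of exact ties per chip — harmless, but visible as a
~1e-4 gap when comparing sorted columns of real chips after step two. A bin
whose median absolute residual is ≤ 1e-9 relative to the signal scale is a
numerically perfect fit; its residuals are returned unscaled (with a
warning) rather than amplifying float noise.

Step two is ordinary quantile normalization across the replicate chips
(rank-wise mean of sorted columns; ties receive the mean of their tied
ranks' reference values). Missing values are a hard error — imputation is
out of scope.

## Peak calling

The caller spools data across replicates: for probe *i* with window
`[mid − w/2, mid + w/2]` (w = 2000; windows truncate at chromosome ends),
*k* probes contribute *k·r* normalized values, *x* of which strictly exceed
the pooled `100·s` percentile (s = 0.95, linear-interpolation percentile).
With *M* the empirical count of exceedances among all *N·r* values (a
nominal `⌈(1−s)·N·r⌉` variant is available; the two differ only under ties),
the enrichment p-value is the inclusive upper tail
`P(X ≥ x), X ~ Hypergeometric(N·r, M, k·r)`, computed via log-gamma
arithmetic. Peaks are maximal runs of consecutive probes with `p < 0.001`;
runs of fewer than 6 probes are discarded. A gene is a target when a peak
overlaps `[TSS − 3 kb, TSS + 3 kb)`.

A property worth knowing: because the exceedance set is a rank-defined
random subset, under a pure null the probability that some window
concentrates enough exceedances to clear `p < 0.001` is fixed combinatorics
(~7×10⁻⁴ per window at k = 20, r = 2), and since neighboring probes share
windows such an event produces a run of ~k significant probes at once. At
100 bp probe spacing this means roughly 0.3 spurious ≥6-probe peaks per
~6,000 probes per dataset. On a realistic array this is a negligible
fraction of calls, but it is a floor on the caller's family-wise error that
no noise-level setting changes; the test suite documents it.

## Overlap statistics

The permutation test operates on disjoined units (e.g. disjoined array
probes): per permutation, one set's boolean membership vector is rotated
within each chromosome by an independent uniform offset in `[1, n]`,
wrapping at the boundary — this preserves per-chromosome marked counts and
the local run structure. Implementation detail: the overlap count for every
rotation offset is obtained exactly via the circular cross-correlation (FFT,
rounded back to integers), so 20,000 permutations reduce to sampling
precomputed values. The odds ratio is observed/permutation-mean; the
empirical two-sided p doubles the smaller tail with a +1 correction; the 95%
CI is `(observed/q97.5, observed/q2.5)` of the permutation distribution.
Because the statistic is discrete, the tail p is conservative; the result
also carries a mid-p variant (half weight on ties) which is the quantity
that is approximately uniform under the null and is used for calibration
checks. Gene-set enrichment is a two-sided Fisher exact test per set on the
(target × membership) 2×2 table, BH-corrected across sets.

## Promoter classes

For a 1,001 bp TSS-centered sequence, 500 bp subwindows slide at a
configurable step; per subwindow, GC content counts called bases only and
the CpG ratio is `observed CG / (#C·#G/L)` (0 when the expectation is 0).
HCP: some subwindow with ratio > 0.75 and GC > 0.55 (strict inequalities,
"above"); LCP: no subwindow with ratio > 0.48; else ICP. Subwindows with
more than 50% N are skipped; an all-N sequence is an error. The default step
is 1 bp: the offset grid is then mirror-symmetric, making classification
exactly reverse-complement invariant (a coarser grid such as 5 bp is not
mirror-symmetric and can flip ~0.7% of borderline random sequences between
strands; it remains available for speed).

## Profiles, heatmap filters, chromatin state

Composite profiles average per-window per-base mean depth, unweighted across
transcripts (a depth-weighted option exists but is off by default); windows
that leave the chromosome are dropped for that transcript. The per-window
normalization divides by window length once; a flag exposes the
double-division variant. Gene-body models use genes strictly longer than
2 kb, 100 equal bins each. The promoter heatmap spans −7..+3 kb of the TSS
in 20 bins, rows ranked by descending total MBD3; the DamID gene filter
applies, in order: chromosome restriction, non-missing expression, ≥1 probe
in every TSS bin, unique TSS, and no neighboring TSS within 7 kb upstream /
3 kb downstream; the MAD filter retains rows with mean absolute deviation
about the row mean > 1.0 (strict).

Mark-presence thresholds use the rank/elbow procedure on genome-wide
non-overlapping 1 kb bin RPKM: sort ascending, rescale both axes to [0, 1],
and take the value at the point where a slope-1 line is tangent to the
curve — computed as the last point maximizing (rank − value). On a convex
curve this is exactly "the first point where the discrete slope exceeds 1",
but it stays well-defined on stepped empirical curves (mostly-zero bins)
where the literal pointwise slope is degenerate. A TSS carries a mark when
any sliding 1 kb bin (step 100) within ±3 kb has RPKM strictly above the
threshold. The five 1 kb pattern classes are assigned with the precedence
1: H3K4me3+TSS, 2: H3K27me3+TSS, 3: H3K9me3, 4: H3K27ac non-TSS, 5: no
mark/no TSS, with an explicit "other" bucket so percentages are well-defined
and sum to 100.

The methylation table bins islands by `methylated reads / total reads` into
x = 0, then right-open deciles with [90, 100] closed; islands are
MBD3-associated on ≥1 bp peak overlap, and the per-bin comparison is a
two-sided pooled two-proportion z-test of the associated column against the
*total* column (which contains the associated islands, matching the printed
marginals); a Fisher-exact variant is available. For count data the exact
test behind the published non-extreme p-values is not pinned down; the
extreme (<2.2e-16) comparisons are insensitive to the choice.

## ChIA-PET and MNase

PET pairs are retained when ≥1 end overlaps some TSS ± 3 kb window; the
overlapping end (or the closer of two) is designated end 1. Each end scores
the MBD3 fragments overlapping `[center − 500, center + 500)` per million
mapped; a gene id is attached only to ends at a TSS window. Pairs are sorted
by end-1 score descending (stable under ties) and the pair at 1-based rank
*i* among *n* joins group `⌈i·10/n⌉`.

MNase fragments are kept at 120–180 bp inclusive, collapsed to midpoints
(`start + floor(len/2)`), and downsampled without replacement to the
smallest condition's count (seeded). Transcripts split into four equal-size
rank quartiles by MBD3 fragment count in TSS ± 3 kb (ties by id).
Per condition × quartile, 1 bp TSS-aligned midpoint counts over ±5 kb are
averaged across transcripts, divided by their own ±5 kb mean (so the
pre-smoothing mean is exactly 1), and smoothed with a centered 50-position
moving average (symmetric truncation at the edges).

## The synthetic cohort

Defaults: 2 chromosomes × 3 Mb, 150 transcripts placed as singleton/2/3-gene
clusters (so the neighbor filter has structure to remove; roughly half the
genes are isolated at the defaults), 60% active. MBD3 targets are 35% of
active genes (~21% of transcripts — similar to the observed target rate on
real promoter arrays) and carry planted enriched domains of TSS ± 1.5 kb,
merged when closer than the 2 kb caller window since a windowed caller
cannot resolve sub-window gaps; the planted log2 effect is 3.0 (≈8-fold,
a strong DamID contrast chosen so planted domains are recoverable at the
default noise), dye-bias amplitude 0.6 (a smooth tanh curve of GC added to
the fusion channel — exactly the structure step-one normalization exists to
remove), channel noise SD 0.35, probes every 100 bp across TSS ± 7.2 kb.
ChIP tracks draw 300 bp fragments from mixtures: MBD3 combines a bimodal
promoter component (modes ±1.5 kb of target TSSs), a 5'→3' decaying
gene-body component, a TES bump, an enhancer component (weighted 3× at
enhancers of MBD3-target genes, planting the TSS/distal co-enrichment the
ChIA-PET ranking reveals), and uniform background; H3K4me3/H3K27ac mark
active promoters and enhancers, H3K27me3 broad domains at repressed
promoters, H3K9me3 six 10 kb heterochromatic domains rejection-sampled away
from TSSs and enhancers. CpG-island methylation fractions come from a
low/high Beta mixture (modes ≈0.04/0.96, ~120–140 reads per island);
MBD3-bound islands draw the low mode with probability 0.92 versus the
configured weight (0.55) otherwise. Nucleosome dyads sit at −1..−3 and
+1..+6 phased positions (NDR at the TSS, +1 at +120 bp, period 185 bp,
midpoint jitter SD 20 bp, lengths ~N(147, 15) truncated to [100, 200] so the
mononucleosome filter retains ~95%); depletion multiplies occupancy at the
−1/+2/+3/+4 positions of MBD3-target promoters by 0.5. All generators are
bit-reproducible: each draws from an independent stream keyed by (seed,
stage name), so adding a stage never perturbs another.

What the generators do **not** emulate: real human sequence composition,
probe-specific hybridization artifacts beyond a smooth GC curve, read-level
error models and alignment, copy-number structure, replicate batch effects
beyond independent noise, and the scale of real data (~6 Mb vs 3 Gb,
~10⁵ fragments vs 10⁸). Passing tests therefore demonstrate that the
*computations* behave as specified and recover structure they were designed
to detect at realistic signal-to-noise, not that the defaults match any
particular real dataset's effect sizes. Published dataset-scale counts
(tens of thousands of peaks, genome-wide co-occurrence percentages) are not
reproducible at this scale and are not asserted; the published methylation
decile table, being pure arithmetic on printed counts, is.

## Problem sizes

The default cohort (21,526 probes × 2 replicates, ~10⁵-fragment ChIP
tracks, ~1.5×10⁵ MNase fragments per condition) runs the full pipeline in
about 15 s. Null-calibration studies use a 40-gene (5,760-probe) variant of
the same conditions with the planted effect set to 0 so multi-seed loops
stay cheap; permutation-test calibration uses 120-unit chromosomes at 500
permutations × 200 replicates.

## Known limitations

- The null false-peak floor of the windowed caller described above.
- The discrete permutation p is conservative near atoms; use the mid-p
  field for calibration diagnostics, the tail p for inference.
- The elbow threshold assumes the sorted bin-signal curve is
  background-dominated with a high tail; on all-equal input it is undefined
  (error), and on a perfectly linear ramp it returns the maximum (nothing
  "present").
- Quantile normalization's sorted-column identity is exact only in the
  absence of within-column ties.
- Island calling, SICER-style ChIP peak calling, alignment and liftover are
  consumed as inputs, never computed.
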