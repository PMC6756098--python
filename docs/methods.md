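# Methods

This note documents the models, defaults, and design choices behind
`crossonc`, in the spirit of a package vignette: what each stage assumes, which
knobs matter, what the synthetic generator does and does not emulate, and the
numerical conventions.

## Coordinate model

Internally all intervals are 0-based half-open. SEG files and coordinates as
printed in the oncogenomics literature are 1-based inclusive; BED and the
7-column synteny TSV are 0-based half-open. Conversion happens only at the I/O
boundary and is an involution (write-then-read restores internal coordinates
exactly). A `GenomeModel` is an ordered list of (chromosome, length,
centromere); arms derive from the centromere, and a region spanning the
centromere is attributed to the larger arm for focal/broad purposes.

One consequence worth stating: published interval endpoints are ingested as
1-based inclusive, so the canine focal-deletion interval
chr21:17,457,665–17,858,164 measures 400,500 bp (400 kb to the nearest
100 kb), while the human interval chr11:83,835,663–84,011,662 measures exactly
176,000 bp even though it circulates as "180 kb". The package records computed
lengths and does not round toward circulated figures.

## Segmentation

**CBS.** The circular max-t statistic scans all arc pairs (i, j] vs.
complement with both sides at least `min_width` (default 2) probes, using the
pooled-variance two-sample t. A suffix arc (i, n] and the prefix arc (0, i]
describe the same partition; candidates are canonicalized to the
lexicographically smaller pair so floating-point noise between the two
equivalent scans cannot flip tie-breaking, and remaining ties break to the
smallest (i, j). Split significance is a within-segment permutation test
(`B_seg` = 1000 by default, p-floor 1/(B+1)) at alpha = 0.01; recursion
proceeds on the up-to-three resulting pieces, and adjacent levels closer than
`merge_tol` = 0.1 log2 units are re-merged (closest pair first; the procedure
is idempotent). The O(n^2) scan is vectorized over arc lengths; no hybrid
acceleration is used, which is adequate at the chromosome sizes this package
targets. Permutation streams derive from (seed, sample id, chromosome) so
per-sample results are independent of processing order.

**Penalized least squares (the second segmenter).** The platform this package
reimplements defined copy-number profiles by the concordance of two
segmenters. Here the second method is the exact dynamic-programming minimizer
of `sum SSE + lambda * (#segments)` — deterministic and verifiable against
bounded enumeration, unlike smoothing-based alternatives. The automatic
penalty is `4 * sigma_hat^2 * ln n` with sigma estimated by the MAD of first
differences: each additional segment introduces two free parameters (level and
boundary), each costing `sigma^2 ln n` in SSE units under the BIC. Charging
only one parameter (a common shortcut) measurably over-segments at chromosome
ends, where a new segment needs only one boundary; those short spurious edge
segments co-localize across samples and leak into the recurrence stage, which
is how the deficiency was found.

**Missing probes** are dropped per sample before segmentation and absorbed
into the covering segment afterwards, so per-chromosome probe counts are
conserved; a sample/chromosome with fewer than 10 usable probes is skipped
with a warning. Probe states derive from segment means via symmetric
thresholds ±0.1 log2 units (±0.9 for high-level amplification/deep deletion);
these GISTIC-era conventions are configurable — the underlying study printed
no cut-offs.

**Concordance and consensus.** Two segmentations are compared by per-probe
3-level state agreement (with a full confusion table) and breakpoint Jaccard
at ±2 probes. The consensus policy `agree` (default) keeps a non-neutral state
only where both segmenters call it; `primary` keeps the CBS states and logs
the disagreement fraction. The source study did not state how disagreements
were resolved, so both policies are exposed rather than guessing its intent.

## Recurrence (GISTIC-style)

Segment means are projected onto the shared marker grid (each probe carries
its covering segment's mean). Per direction, the marker G-score is the
cohort-mean amplitude exceedance beyond the threshold. The null distribution
permutes each sample's marker values independently (within-sample,
genome-wide) B = 1000 times and pools all B·M null marker scores, giving
`p = (1 + #{null >= G}) / (1 + B*M)` — exactly monotone in G, identical for
equal G, floored at 1/(1+B·M). BH runs across markers separately per
direction. This Monte-Carlo null replaces the semi-exact convolution of the
original tool; it is equivalent in expectation and directly checkable. A
useful structural property: an alteration carried by a single sample can never
reach significance, because the null preserves that sample's own values —
significance requires cross-sample alignment beyond chance.

Peaks are maximal contiguous runs of q < 0.1 markers within a chromosome,
ranked by minimal q, then G. Peel-off removes, for every carrier, the entire
contiguous exceeding run overlapping the top peak (not just peak markers, to
avoid residual shoulders), then rescoring repeats up to 10 iterations; G at a
peeled peak strictly decreases, so the loop terminates. Wide-peak boundaries
are the sub-threshold run itself; confidence-region narrowing is out of scope.
A region is *broad* when it covers at least half of its arm (boundary
inclusive), *focal* otherwise. Gene-level alteration frequency counts a sample
when any state-matching segment overlaps the gene (≥1 bp by default;
a minimum-overlap fraction and a focal-only mode — the natural measure for a
focal-deletion frequency, excluding whole-arm events that merely cover the
locus — are options).

## Synteny mapping and cross-species comparison

Synteny blocks are equal-length interval pairs with orientation; mapping is
exactly affine per block, with minus-strand offsets mirrored
(`target.end - 1 - (pos - source.start)`), hence bijective within each block.
Unequal-length real-world blocks are rejected at load with a suggestion to
pre-split — silent linear rescaling would corrupt distances. Regions are
mapped fragment-wise across blocks; mapped length plus unmapped residue always
equals the source length. Peaks are lifted region-wise, every fragment
participates in intersection, and direction matching is strict. Candidates are
ranked by the worse of the two species' q_min (shared support first), ties by
combined gene alteration frequency. The sample × gene grid orders samples by
the anchor gene's 5-level state (deepest loss first) and genes by alteration
frequency.

## Differential expression and over-representation

Welch's unequal-variance t with Welch–Satterthwaite df is the default (the
source study did not state pooled vs. unequal-variance; a pooled option
exists); rows with zero variance in both groups and equal means are retained
with t = 0, p = 1. Significance requires both p < 0.05 and BH q < 0.1. The
volcano columns (log fold-change, −log10 p) are emitted alongside.
Over-representation replaces a web-service query with the same statistical
core: one-sided Fisher exact (hypergeometric upper tail) against a
user-supplied background, BH across sets.

## The synthetic generator: what it emulates, what it does not

Defaults mirror the motivating study design: 52 species-A samples on 22
autosomes vs. 9 species-B samples on 38 autosomes; genome B is built by
permuting and (p = 0.5) inverting equal-length blocks (default 5 Mb) of genome
A, so the truth synteny map is exact by construction and block-tiling,
invertibility, and length conservation are testable invariants. Centromeres
sit at 40% of chromosome length. Default chromosomes are 20 Mb at 50 probes/Mb
— an array-density model scaled down from ~180K-probe platforms.

Per sample: each (arm, sample) independently draws a whole-arm event with
probability 0.2 (sign equiprobable, amplitude ±0.3) — about nine arm events
per 22-chromosome genome, emulating high chromosomal instability; each driver
locus draws a focal event (amplitude ±1.0, length defaulting to chromosome/10
clipped to 0.2–2 Mb) with its per-species penetrance. When a sample draws both
an arm event and a focal driver on one arm, the arm event is suppressed so
every deviation traces to exactly one recorded event and the truth table stays
unambiguous. Probe noise is Gaussian with sigma = 0.15 log2 units, a typical
aCGH probe SD; the study published no noise statistics, so this is a choice,
not an inference. The default driver set is one shared focal deletion
("DLG2", penetrance 0.42 / 0.556 — the study's observed focal-loss
frequencies) plus one species-specific deletion driver per species; a fuller
"landscape" preset adds MYC (gain), CDKN2A, CDKN2B, RB1, and PTEN so that each
species' top-8 recurrent genes comprise six shared and two private drivers.

Expression matrices are Gaussian(mu_g, sigma_e = 0.5) per gene with true-DE
genes shifted by ±effect in the deleted group. For the 4-vs-3 deletion-status
scenario the default effect is 4.0 log2 units: by a noncentral-t power
calculation, that is the effect scale at which a gene is detectable (~95%
power) at n = 7 with BH-adjusted thresholds — i.e. the planted genes emulate
transcriptional consequences strong enough to have been callable in a 4-vs-3
design at all.

Not emulated: tumor purity/ploidy mixtures, allele-specific copy number, GC
waves and other probe artifacts, unequal synteny-block lengths, and
distance-dependent correlation of noise. Passing tests therefore demonstrate
correctness of the machinery and its statistical calibration under clean
Gaussian noise with exactly known truth — not robustness to the full artifact
spectrum of production arrays.

## Problem sizes for desk-scale runs

Simulation-heavy checks use reduced sizes chosen as the package's own
desk-scale defaults: the `scaled_params` preset keeps cohort sizes,
chromosome counts, and penetrances at study values but uses 5 Mb chromosomes
at 10 probes/Mb (1,100 species-A markers, 1,900 species-B markers) with 2.5 Mb
blocks; end-to-end runs use CBS with B_seg = 200 and recurrence B = 1000;
recurrence calibration runs use 1,000-marker, 20-sample cohorts at B = 1000;
driver-frequency estimates average 40 replicate cohorts. Determinism is
end-to-end: a single pipeline seed fans out via named substreams per (stage,
sample, chromosome), outputs format floats at fixed precision, and identical
(config, seed) reproduce candidate tables byte-for-byte.

## Known limitations

* The second segmenter is a penalized least-squares stand-in, not a
  reimplementation of adaptive-weights smoothing; only the two-segmenter
  consensus logic of the original platform is preserved.
* The permutation null treats markers within a sample as exchangeable;
  long-range correlation of real probe noise makes the null anti-conservative
  in principle (shared segments already absorb most of it).
* Peel-off is the simple iterative variant; arbitrated peel-off and
  gene-level variants of the original tool are not implemented.
* Probe-to-gene assignment is coordinate overlap only; no ortholog resolution
  beyond the synteny map.
* Sex chromosomes receive no special handling.
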