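# Methods

This note records the models, conventions, numerical choices and known
limitations behind `capchic`, in the order data flows through the
pipeline.

## Coordinates and containers

All coordinates are 0-based half-open. Pairs files store 1-based
positions on disk and are converted on read, matching common pairs-format
conventions. A `BinTable` tiles each captured region independently at a
fixed resolution (the last bin of a region may be short); bin indices are
global but no operation ever mixes bins across regions — captured regions
are separate observation units throughout (balancing, decay pooling
excepted: the decay profile pools all regions at each separation, since
the decay law is shared). Matrices are stored dense per region; captured
regions are at most a few hundred bins, so dense storage is both simpler
and faster than sparse. The on-disk container is a plain-text bundle
(sparse triplet TSV + bin BED + JSON metadata) — portable and diffable.

## Preprocessing

*Digestion.* The cut is placed at the 5′ start of each recognition-site
occurrence (DpnII cuts 5′ of GATC); a blunt four-cutter is assumed and
re-ligation junctions are not modeled. Fragments tile each chromosome
exactly, which a property test enforces.

*Probe design.* Fragments pass if length ≥ 140 bp, GC ∈ [0.20, 0.80]
(inclusive), mappable fraction ≥ 0.80, and they lie within 600 kb of a
target. Two 120 nt probes sit flush with the fragment ends (the sequence
directly adjacent to the restriction sites); fragments shorter than two
probe lengths get a single centered probe. Mappability is taken from a
supplied track when available; the built-in fallback scores exact 50-mer
uniqueness within the supplied genome (both strands), which is adequate
for synthetic genomes but is *not* a substitute for read-mapper-based
mappability on a real genome.

*Pair filtering.* Removal order is: self-ligations (both mates in one
fragment), exact duplicates (canonical mate order, first kept — ties
carry no information), then, if capture regions are given, pairs whose
fragment midpoint falls outside every capture region. The midpoint rule
avoids double-counting fragments straddling a region edge; an
any-overlap rule is available (`capture_rule="overlap"`). Because
self-ligation removal precedes deduplication, a duplicate of a
self-ligated pair is counted as a self-ligation — the counts in a
`FilterReport` partition the input exactly.

## Balancing

Knight–Ruiz balancing is applied per region: find positive weights
`w` such that `B = diag(w) A diag(w)` has equal row sums over valid
bins. The implementation is the inner–outer Newton/conjugate-gradient
scheme of the KR method with a box constraint on each outer step's
multiplicative update; the matrix is pre-scaled to mean row sum 1 so the
unit vector starts near the fixed point. Convergence demands per-row
residual ≤ tol/2 (default tol 1e-8 relative), which guarantees pairwise
row-sum agreement within tol. If KR stalls, a damped symmetric
Sinkhorn–Knopp iteration (`x ← sqrt(x² / (Ax))`) takes over, with the
fallback logged; if both fail the call raises with the residual.
Weights are rescaled so their mean over valid bins is 1 — the absolute
scale is arbitrary and only ratios matter downstream.

Bins with zero marginal, or marginal below the 2% quantile of the
nonzero marginals (`min_coverage_fraction=0.02`), are masked invalid
before balancing. This mask exists to drop unmappable or artifact bins
in real data. **Caveat for simulated data:** the generator plants no
coverage artifacts, so the lowest-marginal bins are genuinely the most
insulated (boundary) bins; masking them removes the very minima the
boundary caller needs. Simulation studies therefore balance with
`min_coverage_fraction=0`, and the same is recommended for any input
known to be free of coverage artifacts.

## Decay and observed/expected

The cis-decay profile pools balanced scores across regions at each
separation (in bins) and records median and 25th/75th percentiles; a
separation with a single observation keeps its median but has no IQR.
The diagonal (separation 0) is excluded by default: at
restriction-fragment scale it is dominated by self-ligation artifacts
(`include_diagonal` overrides). O/E divides each entry by the decay
median at its separation; entries with zero or absent expected value are
missing, and a separation observed in the matrix but absent from the
profile is an error rather than a silent NaN.

## Insulation and boundaries

The insulation statistic at bin *i* for window *w* is the mean balanced
score over the `w × w` square `[i−w, i−1] × [i+1, i+w]`. It is missing
when the bin is invalid, lies within *w* bins of a region edge, or more
than half the window cells are missing (`max_missing_fraction=0.5`).
The reported score is `log2(raw_i / mean(raw over the region))`; the
log2-to-regional-mean convention centers profiles near 0 so minima and
maxima are comparable across regions and cell types (raw output is
available). Window sets used in practice: {3, 5, 7, 10, 15} bins for
5 kb capture matrices, {15, 20, 25, 40, 50} for 2 kb pooled data,
{7, 10, 15} for 10 kb genome-wide maps.

Local minima are bins strictly below both neighbors; a tied plateau is
attributed to its leftmost bin. The boundary ("delta") score is
`min(mean(scores[i−3..i−1]), mean(scores[i+1..i+3])) − score_i` — the
conservative, smaller of the two flank rises; all six flanking scores
must be present. Robust boundaries keep candidates scoring ≥ 0.1 in ≥ 2
distinct window sizes, clustering candidates (across windows, within a
region) whose bins are ≤ 1 bin apart, transitively; the boundary spans
the member bins and its score is the mean of the member scores.
Sub-threshold candidates do not join clusters or dilute the mean.

Boundary sets are compared by Jaccard index with the matched count taken
from a maximum bipartite matching on interval overlap (after optional
symmetric extension by `slack_bins`), so a wide boundary overlapping two
calls in the other set is counted once. Distribution comparisons use the
asymptotic two-sample KS test and Spearman correlation (average ranks,
t-approximation p); exact small-sample p-values are out of scope. PCA of
replicate profiles drops bins with any missing score listwise, centers
columns without scaling, and uses the SVD; coordinates are defined up to
sign, as usual.

## Differential maps and virtual 4C

The differential map standardizes `diff = A − B` over upper-triangle
entries valid in both inputs: `z = (diff − mean) / sd` with the
*population* standard deviation, pooled per captured region by default —
regions differ in decay regime, so pooling them would let one region's
variance set another's z-scale (`pool="all"` overrides). If sd = 0
(identical inputs) the map is flagged degenerate and z ≡ 0. The
construction makes mean(z) = 0, sd(z) = 1 exactly, and the map is
antisymmetric under swapping the inputs.

Virtual 4C takes the row of the bin containing the bait midpoint and
applies a centered running mean of 3 bins, truncated at region edges,
with missing values excluded from each window. The bait's self-contact
is kept by default (`mask_bait` removes it).

## Metagene compaction

Gene-to-bin assignment is by bin-midpoint containment. The intragene
score is the median O/E over all unordered pairs of distinct gene bins
(diagonal excluded for the same self-ligation reason as above), defined
only for genes covering ≥ 10 bins (≥ 100 kb at 10 kb resolution) —
below that, the median rests on fewer than 45 pair values and is
unstable. It is strand-invariant by construction. Gene-body signal is
the median over fixed 10 kb genome-tiled bins overlapping the gene, each
bin a coverage-weighted mean of the track with uncovered sequence
counted as 0. Differential compaction takes per-gene
`log2(score_A/score_B)` vs `log2(signal_A/signal_B)`, dropping genes
with missing or nonpositive values (logged), and reports the Spearman
correlation of the ratios.

Pileups scale each eligible gene's O/E submatrix so the gene occupies 10
pseudo-bins between 40-bin flanks (90 pixels per axis). The scaling
operator is area-weighted block averaging with fractional bin weights —
it conserves the mean and reduces to exact identity when the gene is
already 10 bins and to k×k block means at integer ratios; interpolation
was rejected because it does not conserve mass and manufactures values
at missing pixels. Minus-strand genes are flipped on both axes so the 5′
end is always leftmost. Flank pixels beyond the matrix propagate as
missing rather than zero. Expression groups are formed by sorting
eligible genes on (expression, gene_id) — the id breaks ties
deterministically — and splitting into equal quarters, Q1 lowest.

## Synthetic data

The generator emulates, per region:
`E[i,j] = base · max(d,1)^(−α) · Π block enrichments · gene compaction ·
boundary attenuation`, with α = 1 by default (the canonical cis-decay
slope at sub-megabase scale). A boundary multiplies crossing pairs by
`strength^r`, where the ramp `r = clip(min(b−i, j−b+1)/width, 0, 1)`
equals 1 for sharp boundaries and rises linearly over `broadening_bp`
for broadened ones — a phenomenological stand-in for a border widened by
elongating polymerase, not a loop-extrusion simulation. Counts are
independent Poisson draws per unordered pair with total mass scaled to
the requested depth; overdispersion (negative binomial) is left as an
extension, so replicate variance in the simulations is at the Poisson
floor — real replicates disperse more. Pair lists are multinomial draws
with positions uniform within bins; contamination (self-ligations as
identical-position mates, duplicates, one mate displaced outside the
capture regions) is planted at stated rates and reported in the ground
truth. Tracks assign each gene a mean level via a monotone power-law
link from its compaction multiplier, with truncated-Gaussian per-bin
noise; expression is the mean level with lognormal noise. Everything is
driven by one config seed, and two same-seed calls are bit-identical.

Study conditions used by the test suite and acceptance script (chosen
once as realistic for the data type, then frozen):

- *Boundary recovery:* one 600 kb region at 5 kb (120 bins), three
  boundaries of strength 0.3, 1e6 informative pairs — comparable per
  bin-pair to a well-covered capture region; 20 Poisson seeds.
- *Cell-type comparison:* three simulated cell types over one region at
  5e6 pairs (robust borders are called on pooled replicates, which are
  deeper than single libraries), sharing a two-boundary backbone, with
  a thymocyte-shared boundary pair, one DP-specific boundary, one
  ESC-specific boundary, and a thymocyte-compacted gene subdomain.
- *Metagene:* 200 genes of 100–200 kb at 10 kb bins, spread over ten
  ~3.5 Mb regions with 100–300 kb intergenic gaps (genes must stay a
  small fraction of each bin's marginal, as on a real chromosome —
  otherwise balancing absorbs the planted compaction), lognormal
  compaction multipliers (log-mean 0.3, log-sd 0.4), signal link scale
  5 with per-bin noise sd 1, expression noise σ = 0.3, 3e7 pairs.

What passing these simulations does *not* show: robustness to coverage
bias (none is planted), to overdispersed counts, to trans contacts
(never simulated), or to real-genome mappability structure. The
simulations validate the pipeline's logic and statistical contracts, not
its behavior on any particular real library.

## Known limitations

- Boundary calling reports a called interval; a planted cut between
  bins b−1 and b legitimately yields its minimum on either side, so
  recovery is judged within ±1 bin.
- The spreadsheet reader for called-boundary tables auto-detects
  cell-type columns by name prefix ({ESC, DN3, DP} by default) and
  expects chrom/start/end columns; exotic layouts need renaming first.
- ICE balancing, multi-resolution pyramids, directionality-index or
  HMM TAD callers, and windowed structural-similarity scanning (CHESS;
  published parameters for reference: 40-bin windows, step 1,
  signal-to-noise > 0.5, ssim z < −1) are intentionally out of scope.
- Read mapping and bigWig generation are upstream of this package; it
  consumes pairs text and bedGraph.
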