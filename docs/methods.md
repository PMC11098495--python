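# Methods

This note documents the models, conventions, and design choices behind
hicsuite, in the spirit of the methods documentation of mature scientific
Python packages. Nothing here asserts an empirical result that the test
suite or `scripts/acceptance.py` does not itself compute.

## Data model

hicsuite operates on the cooler HDF5 schema v3 (groups `chroms`, `bins`,
`pixels`, `indexes`; multi-resolution files store one such group per
`resolutions/<N>`). Coordinates are 0-based, half-open everywhere; interval
tables are emitted as 0-based half-open TSV. Pixels hold only the upper
triangle (`bin1_id ≤ bin2_id`, sorted, duplicate-free); any dense
materialization symmetrizes explicitly. Balancing weights are
multiplicative — the balanced value of a pixel is `count · w_i · w_j` — and
a missing weight marks a filtered ("bad") bin, whose balanced values are
all missing. These are the cooler conventions, so files written by
hicsuite open in other cooler-schema readers and vice versa.

All per-region analyses run over a *genomic view*: an ordered set of
named, non-overlapping intervals (whole chromosomes by default, or e.g.
chromosomal arms split at centromere coordinates). Bins are assigned to
the region containing their midpoint. Pixel processing streams over chunks
of the pixel table (default 10⁷ pixels per chunk); every aggregation is a
pure sum, so results are exactly independent of the chunk size — a
property the tests pin for expected, coverage, and insulation.

Dense block access caches a CSR copy of the full map. This is deliberate:
the package targets maps up to tens of thousands of bins (the synthetic
fixtures are 600 bins); the chunked pixel path, not the dense cache, is
what carries the scalable aggregations.

## Balancing (fixture plumbing)

`io.iterative_correction` is a symmetric Sinkhorn iteration provided so
fixtures carry realistic weights; it is not a publication-grade balancer.
Bins with zero marginal, or marginal below the 2nd percentile of nonzero
marginals (`min_marginal_quantile=0.02`), are dropped before iterating.
Convergence is declared when balanced marginals agree to `tol=1e-6`
relative. Weights are scaled so the mean nonzero balanced pixel value is
1.0; published files use various scalings, and all analyses here treat
weights as given.

The synthetic generator calls the balancer with
`min_marginal_quantile=0`: the generator knows its bad bins exactly (their
pixels are zeroed, so they drop out via zero marginals), and letting the
quantile filter guess additional bad bins would systematically mask
chromosome ends and boundary-flanking bins — the lowest-marginal bins of a
structured map — and misrepresent the generator's own truth tables.

## Expected / P(s)

Cis expected aggregates, per region and separation d (in bins; bp only at
output), the number of valid bin pairs `n_valid(d)`, raw and balanced
sums, and their ratios. Valid-pair counts come from the weight mask, so
zero pixels and masked bins are accounted exactly without dense matrices.
Pixels spanning two same-chromosome regions (e.g. two arms) aggregate into
distance-free inter-region records; trans expected averages each
region-pair rectangle.

Smoothing is a Gaussian kernel in log₁₀ distance (default sigma 0.1
decades, truncated at 3 sigma), weighting each source distance by
`n_valid` — i.e. the smoothed value is `Σ K·balanced_sum / Σ K·n_valid` —
which makes the curve robust where the data are sparse. Separations below
`min_dist` (default 2 bins) pass through unsmoothed, since the first
couple of diagonals are dominated by ligation artifacts in real data and
carry no information about the decay. The log-derivative uses central
finite differences on (log₁₀ s, log₁₀ P), one-sided at the ends.

## Compartment eigenvectors

Cis, per region: dense balanced matrix → divide each diagonal by its mean
(O/E) → clip O/E symmetrically at the [0.1, 99.9] percentiles (sparse far
diagonals otherwise contribute wild outliers) → subtract 1.0 (the natural
center of an O/E map; not row-mean centering) → drop bad rows/columns →
enforce symmetry by (M + Mᵀ)/2 → `eigh` → top `n_eigs` by descending
signed eigenvalue (compartments are a positive-association pattern).
Vectors are unit-norm over valid bins with NaN reinserted at bad bins.
Regions with fewer than `n_eigs + 1` valid bins return all-missing vectors
with a warning.

Trans: the genome-wide balanced matrix has each cis block replaced by
values drawn uniformly (seeded) from the valid trans pixels involving that
chromosome, symmetrized; the matrix is divided by the global trans mean,
clipped, centered, and decomposed as above. Global (not per-chromosome-
pair) trans O/E is used; a per-pair variant would be a straightforward
extension.

Phasing multiplies each vector by the sign of its Pearson correlation with
the supplied track over jointly valid bins; `sort="correlation"` reorders
vectors by descending correlation, since the compartment signal is not
always the first eigenvector.

## Saddles

A quantitative track is digitized into `n_classes` (default 5) classes at
quantile edges spanning [`lo_q`, `hi_q`] = [0.025, 0.975] by default, so
extreme-valued bins land in outlier classes (0 and n+1) that are excluded
from aggregation; an equal-width-in-value mode covers discrete tracks such
as planted ±1 vectors. Mean O/E per class pair is averaged over *matrix
positions*, not stored pixels — zero pixels count toward the denominator —
otherwise sampling zeros would inflate every entry. Cis aggregation is
restricted to intra-region pixels at separations ≥ `min_dist` (consistent
with expected's `min_dist`) with a defined expected value; trans uses
region-pair averages. Accumulating both orientations before dividing
symmetrizes S without upper-triangle bias. The strength summary is
(mean TL corner + mean BR corner) / (mean TR + mean BL) over an
`extent × extent` corner.

## Insulation and boundaries

The diamond at bin i covers pairs (a, b) with `i−w ≤ a ≤ i < b ≤ i+w`
(window w in bins; the self-pixel a=b excluded, distance-1 pairs
included). The raw score is the *mean* balanced value over valid positions
in the window — mean rather than sum, so edge truncation and masked bins
do not mechanically depress the score — and the reported score is
log₂(raw / region mean of raw). Scores are missing within w of region
edges and where the valid fraction `n_valid / w²` falls below
`min_valid_frac` (default 0.66). A diamond of valid pairs but zero
contacts yields −inf: a legitimate, maximally deep score that splits
nothing (only NaN breaks the profile into runs).

The sparse implementation scatters each pixel into its range of window
centers with a difference array and one cumulative sum, so any pixel
chunking gives bit-identical profiles; validity counts are combinatorial
(valid-a count × valid-b count).

Minima are bins strictly below both neighbors; plateaus report their
leftmost bin with the plateau size noted. Prominence walks outward from
each minimum until a strictly lower value or the region end, recording the
maximum encountered; the prominence is the smaller directional maximum
minus the minimum's score, so a shallow minimum next to a deeper one is
limited by the saddle between them. Thresholding (per window size) uses
scikit-image's Li or Otsu estimators on the finite prominences of all
minima, or a fixed value; infinitely prominent minima are always strong.
Degenerate prominence sets (fewer than two distinct values) flag all
minima strong with a warning rather than failing.

## Dot calling

Kernels are odd-sized boolean masks centered on the scored pixel; the four
stock kernels at half-widths (w=5, p=2 at 10 kb, scaled with resolution)
follow the HiCCUPS geometry and are pinned pixel-by-pixel in the tests.
For each kernel, the local factor `f_k = Σ_kernel(balanced obs) /
Σ_kernel(balanced expected)` rescales the distance expected into an
expected *raw* count `λ_k = f_k · E(s) / (w_i w_j)`. Scoring runs on tiles
(default 5 Mb) overlapped by the kernel half-width, each pixel assigned to
exactly one tile with full context, making calls exactly independent of
the tile size. Pixels are scored between `min_dist` (2 bins) and
`max_dist` (2 Mb, the range where mammalian loops concentrate); positions
where any kernel covers less than half its footprint with valid data
(`min_kernel_frac=0.5`) are dropped — a stricter floor discards callable
pixels whenever two bad bins fall inside the narrow band kernels, while
≥ 50% of background pixels still give an unbiased local factor.

Zero-count positions are retained in the scored table: they belong in the
FDR denominator. Significance uses lambda chunks with geometric edges
`base^m` (base 2^(1/3)); within each chunk the p-value is the Poisson
upper tail `P(X ≥ obs)` evaluated at the chunk's *upper* edge
(conservative), followed by Benjamini–Hochberg across the chunk. A pixel
must be significant under every kernel by default (`require_all=False`
relaxes to any). Significant pixels are single-linkage clustered at a
centroid radius of 39 kb (≈ touching pixels at typical resolutions;
tunable for small genomes); each cluster's most significant pixel (lowest
worst-kernel q, ties by count then coordinates, for determinism) is the
centroid, then filtered by donut and lowerleft enrichment ≥ 1.75. Both
steps are skippable.

## Snipping and pileups

Anchors given as intervals map to the bin containing their midpoint; pairs
are oriented so anchor1 ≤ anchor2 (upper triangle; no strand flipping).
Windows are (2f+1)² in bins; cells outside the anchor's view region are
missing, never truncated, so stacks are rectangular. O/E mode divides each
cell by the anchor region's expected at that cell's separation. Pileups
are the element-wise nan-mean (or nan-median) with a per-cell count of
contributing snippets. Snippets may be fetched by any number of workers
(`nproc`); partitioning is by feature index and results are bit-identical
to serial execution.

## Map operations

Coverage adds each off-diagonal pixel to both incident bins and diagonal
pixels once (a self-contact; an option to double it for marginal
consistency with balancing would be trivial but is not the default).
Downsampling draws each pixel's count from Binomial(count, f)
independently — indistinguishable from without-replacement subsampling at
contact-map scales — and writes a valid cooler-schema file; seeded.

Adaptive smoothing builds a pyramid of 2×-coarsened raw-count matrices
(sums; odd edges padded) and resolves each cell at the finest level whose
co-located aggregate count reaches `cutoff_counts` (default 10, roughly
the count at which a balanced value's relative Poisson error is ~30%).
Cells resolving at a coarse level share the balanced mass of their block
*net of cells already resolved at finer levels* — the observed counts are
split across the starved bins rather than double-counted — which conserves
total balanced mass exactly when no cells are missing. Assigning the whole
block mean instead would re-count the well-sampled cells and inflate mass.

## Synthetic maps and what they do (not) show

The generator samples counts as Poisson(N · M/ΣM) over the upper triangle
with intensity

    M_ij = base · s^α                     (cis; s = max(|i−j|, 1) bins)
         = trans_level                    (trans)
    M_ij ×= 1 + A·v_i·v_j                 (compartments, v ∈ {−1, +1})
    M_ij ×= depletion^−(boundaries crossed)   (domains, cis only)
    M_ij ×= 1 + (enr − 1)·G(di, dj)       (dots; Gaussian spot, cis)

Defaults: 2 chromosomes × 300 bins at 10 kb (small enough for dense
oracles, deep enough for FDR statistics), α = −1, cis base 1, trans level
0.005 (long-range cis ≈ trans territoriality), compartment blocks of 30
bins, 2% bad bins, depth N = 10⁶ contacts, structural features off unless
requested. Planted dot anchors are excluded from bad-bin selection — a dot
zeroed by a bad bin no longer exists in the map, so listing it as truth
would be wrong. Weights are fitted to the *sampled* map, so fixtures carry
realistic weight noise. Acceptance fixtures place dots at separations of
5–40 bins (50–400 kb, the typical mammalian loop range) with enrichments
drawn uniformly from 3–5×.

The generator emulates the canonical map features but not: distance-
dependent compartment strength, nested or hierarchical domains, loop
anchors shared across dots (grids), copy-number or mappability gradients,
trans compartmentalization differing from cis, or ligation artifacts at
the first diagonals. Passing recovery tests therefore demonstrates
correctness of the estimators under Poisson sampling with known structure,
not robustness to every artifact of real libraries.

Problem sizes throughout (600-bin genomes, depths 10⁵–2×10⁶, 3 replicate
maps for dot metrics, 20 null maps for the false-positive rate, 50 seeds
for downsampling) are chosen so dense brute-force oracles remain feasible
and recovery statistics are stable across seeds.

## Known limitations

- The dense-block cache makes whole-genome trans eigendecomposition
  memory-bound around ~3×10⁴ bins; the chunked paths (expected, coverage,
  insulation, saddles) have no such limit.
- Balancing is fixture-grade (no MAD-max filtering, no per-chromosome
  mode).
- Insulation is 1D only; no 2D domain segmentation.
- Dot calling is cis-only and single-condition; saddles assume the
  digitized track is bin-aligned to the store.
- The CLI reads bedGraph tracks and BED/BEDPE features; bigWig input is
  not supported.
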