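# Methods

## Coordinates, intervals, reads

All coordinates are 0-based half-open (BED convention); 1-based inputs
must be converted at the reader boundary.  Interval merging uses a
sorted sweep; intervals that merely touch at a shared boundary are
merged by default (`merge_abutting=True`) — this changes no covered
base and keeps promoter sets disjoint, which read counting requires.
Strand is carried through readers and writers but ignored by all
counting, since the histone-mark reads are unstranded after mapping.

Reads are single-end, fixed-length (36 bp default) and held per
chromosome as sorted start arrays.  A read counts toward a region iff it
overlaps at least one base; a read spanning the gap between two regions
is assigned to the *leftmost* region it overlaps, so no read is counted
twice against a disjoint region set.  No duplicate-read removal and no
fragment extension are applied by default (`quantify` exposes the
mapped-interval rule only; callers wanting fragment logic get it from
the peak caller's binning).

## Promoter-anchored density

For sample *s* and region *r* of length *L*:

    d(r, s) = c(r, s) / (L · N_prom(s) / 10^6)

where `N_prom(s)` is the number of reads overlapping any merged TSS ± 2 kb
promoter region (chrY excluded by default).  Anchoring the denominator
on promoter reads rather than library size makes samples comparable when
genome-wide background varies, and puts the analysis thresholds — the
trajectory density floor 0.01 and the differential floor 0.005 — on one
scale.  The promoter-occupancy heatmap additionally length-normalizes
per region; both normalizations compose in `build_density_matrix`.

## Peak caller

The caller is a deliberately simplified local-Poisson scan, not a
re-implementation of any external tool: fixed windows of width `2·bw`
stepping by `bw` (default bw = 230, tsize = 36), read midpoints binned at
`bw` resolution, and for each window an exact Poisson upper tail of the
treatment count against

    λ_local = scale · max(λ_1kb, λ_5kb, λ_10kb, λ_genome)

estimated from the control (input or another ChIP sample), with `scale`
the ratio of total mapped reads.  Windows with p ≤ 1e-5 (default) that
overlap or abut are merged into peaks; a peak reports its read count,
its scaled control expectation λ, the minimum window log10 p, and
count/λ.  There is no model shifting, no duplicate filtering, no
FDR-by-swap and no broad mode.  p-values are kept as log10 throughout to
avoid underflow.  Consequences: absolute peak counts are not comparable
with those of full-featured callers, and the deep-library differential
threshold p < 1e-20 quoted for such callers is not transferable (see
below).

A chromosome with treatment reads but an empty control falls back to the
control's genome-wide rate (logged).  On background-only data the
realized fraction of significant windows stays well below 10× the window
threshold (the type-I study in the test suite).

## Trajectory classification

Samples partition into prenatal (age ≤ 0 years, i.e. at or before a
40-gestational-week term), infant (0 < age < 1) and older (≥ 1 year).
Infants never enter the test but are retained in profiles.  A region is
**down** iff

1. prenatal mean density ≥ 0.01 (the floor applies to the higher group),
2. prenatal/older fold ≥ 2,
3. two-sided Welch t-test p ≤ 0.05 (prenatal vs older densities), and
4. region length ≥ 1 kb;

**up** by the reciprocal criteria (older mean ≥ 0.01, older/prenatal
≥ 2).  Welch (unequal-variance) is the default because the two groups
are 3 vs ~25 samples with no reason to assume equal variance; a
pooled-variance flag exists.  Regions with zero variance in both groups
have an undefined statistic and are reported as `none` with p = NaN.

For clustering, regions ≥ 1 kb whose prenatal *or* older mean clears the
floor (chrY excluded) are max-normalized — each profile divided by its
maximum across samples, so values lie in [0, 1] with max exactly 1 —
and clustered with Euclidean k-means, k = 5, best of 10 k-means++
restarts at a fixed seed.  Cluster centroids are labeled up/down/flat by
Spearman rank correlation with age at |ρ| ≥ 0.5; the threshold is a
package choice (narrative labels in the literature are assigned by
inspection), exposed as a parameter.

## Cohort structure

The differential count for the ordered pair (i, j) is the number of
peaks from calling i against j as control that additionally pass
p ≤ the differential threshold, promoter-normalized density ratio
`d_i/d_j` above the ratio floor (zero denominator counts as infinite),
and `d_i` above 0.005.  The resulting n×n matrix (zero diagonal,
generally asymmetric) enters PCA as rows-as-feature-vectors: columns are
mean-centered, *not* variance-scaled (counts share a scale; scaling
would inflate near-empty columns), components come from the
eigendecomposition of the column covariance in descending-eigenvalue
order, and each component's sign is fixed by making the first sample's
loading non-negative so scores are bit-reproducible.  Group separation
is scored with a two-sided Mann–Whitney rank test of PC1 scores
(prenatal vs rest) and PC2 (prenatal+infant vs rest); two-sided because
the sign convention is arbitrary with respect to age.

Library defaults keep the deep-library filter set (p < 1e-20, ratio > 4,
density > 0.005) for users with real, deeply sequenced cohorts.  The
synthetic structure study instead runs caller and filter at p ≤ 1e-4
with ratio > 2: a pre-run power analysis of the planted conditions
(fold-4 regulated regions, ~27 expected treatment reads per window
against λ ≈ 17) shows the p < 1e-20 regime is unreachable at toy depths
while 1e-4 plus the ratio and density gates keeps same-group pairs near
zero false differentials.

## Integration

Peak–gene links require TSS distance ≤ 2 kb, measured as the bp gap to
the nearest covered base (0 if the TSS lies inside the peak), boundary
inclusive.  Genes with two or more up/down-called promoter peaks no more
than 100 kb apart are classed `up+down` (any discordant pair),
`up+up`, or `down+down`.

Per-CpG methylation tests are the same Welch prenatal-vs-older contrast
on beta values; Benjamini–Hochberg FDR is computed across all testable
CpGs (constant CpGs are excluded from the family and logged) with
direction from the sign of the older-minus-prenatal mean at the chosen
cutoff (0.05 default; 1e-10 supported as a robustness check).  The
anti-correlation contingency cross-tabulates CpGs at up- vs down-called
genes against significant methylation decrease and scores the up row
with an exact hypergeometric upper tail.  Generic over-representation
uses the same tail per term over a flat term→gene table (no ontology
graph), BH across terms, and `−log10(FDR)` enrichment scores; two
enrichment landscapes are compared by Pearson correlation over terms
with FDR < 0.85 in either list.

## Synthetic cohort: what it emulates and how it is calibrated

The generator mirrors the real design: 31 ChIP samples at the study's
printed ages (34 gw–81 yr; gestational weeks mapped to negative years
via `(gw − 40)·7/365.25`) plus one input control, 36 bp reads, and
regions laid out on a jittered grid over a toy multi-chromosome genome,
each tied to a gene whose TSS lies inside the region for a configurable
fraction (default 0.66, matching the TSS-proximal share of regulated
loci in such data) and 3–10 kb away otherwise.  Up/down/flat classes are
assigned in exact rounded proportions (defaults 5% up, 10% down);
default kinetics run from density 0.01 to 0.04 (fold 4) with τ drawn
uniformly from 0.5–2 yr — values chosen so that the largest changes fall
within the first one or two years of life, as reported for this system;
they are free parameters of the generator, not fitted quantities.

Calibration anchors realized densities on the planted scale.  If `S` is
the TSS-proximal sum of planted density × length, the per-sample read
scale `C` (reads per density·bp) solves `C·(10^6 − S) = B_prom`, with
`B_prom` the expected background reads in promoters; then the realized
promoter total is `10^6·C` and realized densities equal planted ones in
expectation.  Flat "constitutive promoter" densities are drawn lognormal
and rescaled so the proximal signal load hits a configured fraction of
the promoter pool (default 0.985, emulating the strong promoter
dominance of real libraries).  Enriched reads are placed uniformly in
the region extended by half a fragment (115 bp) per side, with the draw
inflated so the *overlapping* expectation matches the target; input
samples receive background only, at `input_depth_factor` (default 2×)
the ChIP background so input libraries are deep, as in real designs.
All randomness flows from one master seed through named substreams
(annotation / models / per-sample reads / methylation / expression), so
every output is reproducible and stable under call reordering.

Methylation: for a coupled fraction `anti_rho` of up-class genes the
promoter CpGs lose methylation along the same saturating kinetics
(β 0.7→0.3), mirrored for down-class genes; the rest are age-flat;
truncated Gaussian noise (σ = 0.05) keeps β in [0, 1].  Expression is an
affine image of the region density plus Gaussian noise (σ = 0.3 log2
units), so flat genes stay flat.

What the generator does **not** emulate: sequence content and
mappability, fragment-length variation, duplicate reads, GC bias,
copy-number or allelic effects, non-monotone trajectories, and
cell-composition mixtures.  Passing recovery studies therefore
demonstrate the correctness and statistical behavior of the analysis
chain under the planted model — not performance on real tissue data.

## Study configurations and problem sizes

* **Classification recovery** — the default cohort: 31 samples,
  2,000 regions (grid pitch 32 kb, four chromosomes, ≈ 66 Mb),
  background 100k reads/sample (≈ 1M total per sample with enrichment);
  20 replicate cohorts, sensitivity ≥ 0.90 and FDP ≤ 0.10 per replicate.
* **Structure recovery** — a reduced 12-sample cohort (three samples in
  each of four age strata), 300 regions on one sparse 120 Mb chromosome
  (pitch 400 kb), background 2.26M reads/sample: pairwise differential
  calling needs the real-data geometry in which enriched regions occupy
  ~1% of the genome, so the genome-wide λ stays below per-window
  enrichment.  PC1 separation at rank-test p < 0.05 in ≥ 18 of 20
  replicates.
* **Clustering recovery** — default cohort, one replicate: up- and
  down-trend clusters capture ≥ 90% of planted directional regions.
* **Null control** — 20 replicates of 100k background reads on a 10 Mb
  chromosome; significant-window fraction ≤ 10× the 1e-5 threshold.
* **Contingency response** — planted coupling 0, 0.4, 0.8; the median
  contingency p over 20 replicates decreases monotonically.

The pipeline's file-based demonstration config is smaller still
(12 samples, 60 regions, stronger planted effects 0.1→0.5) because the
BED handoff writes every read as text; it exists to exercise the
end-to-end plumbing, not the recovery statistics.

## Numerical choices and degenerate inputs

Exact tails come from `scipy.stats` log-survival functions (Poisson,
hypergeometric) and are asserted in the test suite against brute-force
pmf summation and exhaustive enumeration; BH against a hand step-up.
Merging is idempotent and base-conserving (checked against per-base
coverage masks).  Degenerate cases are explicit: empty annotation warns
and yields an empty promoter set; a sample with zero promoter reads is
excluded, never divided by; zero-variance samples get NaN correlation
rows; an all-zero differential matrix refuses PCA ("no structure");
empty gene-set/expression intersections are errors that report both set
sizes.

## Known limitations

* The peak caller is a teaching-grade simplification; its absolute peak
  counts, p-scale, and boundary precision (one window step, 230 bp) are
  not comparable with production callers.
* The prenatal group of the emulated design has three samples; the Welch
  test at n = 3 is fragile to outliers, which the fold and floor gates
  only partly mitigate.
* The contingency test inherits every upstream thresholding choice; its
  p-values are meaningful comparatively (across coupling strengths or
  cohorts), not as calibrated genome-wide error rates.
* Age encoding compresses gestational weeks onto a single linear axis;
  discontinuities around birth are not modeled.
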