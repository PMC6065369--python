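# Methods

## Local Invasion Index

Cancer-cell nuclei inside an analysis region (a rectangle, or a polygon for
circular tissue-microarray cores) are treated as a planar point pattern. For
each cell the nearest-neighbor distance (NND) is the Euclidean distance to
the most proximal other cell; the tumor-level LII is the arithmetic mean NND
over cells that survive border correction. The implementation uses a k-d
tree (`scipy.spatial.cKDTree`) but is contractually identical to the
all-pairs O(n²) computation — the test suite and the acceptance battery
compare every distance for exact equality. Distance ties are broken toward
the lowest neighbor id (detected via a third-neighbor query, resolved by a
radius search). Duplicate points are rejected with an error rather than
returning an NND of zero: identical centroids indicate an upstream
segmentation fault, not biology.

**Border correction.** A cell is included iff the closed disc centered at
the cell with radius equal to its NND lies entirely inside the region
(distance to the region boundary ≥ NND, with tangency counting as contained,
up to a 1e-9 relative slack for polygon boundary distances). Exclusion never
modifies NND values, only inclusion flags. For included cells the measured
NND equals the true NND — no point outside the region can be closer — so the
correction removes censoring.

**Known bias.** Because inclusion conditions on the cell's *own* NND
(a point at border distance *b* is kept only if its NND ≤ *b*), near-border
cells contribute only their smaller NNDs and the included-cell mean is
slightly *negatively* biased. Against the homogeneous-Poisson closed form
E[NND] = 1/(2√λ), the measured bias in a 500 × 500 µm window runs from
−1.6% at λ = 0.005 cells/µm² to −0.4% at λ = 0.1 (shrinking with window
size as the boundary fraction falls). The recovery check therefore uses a 2%
tolerance band rather than a pure Monte-Carlo standard-error band, which the
bias would dominate at a few hundred replicates. Unbiased alternatives
(Hanisch-weighted estimators) exist but would change the index's definition,
so they are deliberately not used.

**Binning and populations.** Tumors are classified LII-low (≤ 7 µm) or
LII-high (≥ 9 µm); both cuts are parameters, the boundary is inclusive on
both sides, and the open interval between them is reported explicitly as
"intermediate". Per-cell population comparisons (e.g. before vs after a
treatment) summarize each group by a median split — cells exactly at the
median go to the lower subset, making the two subsets a partition — and a
percentage histogram over configurable bins (default edges 0, 7, 9, ∞,
aligned with the LII bins); groups are compared with Welch's
unequal-variance t test. Two groups that are both constant have no variance
to test against and raise an error rather than returning a degenerate
statistic.

## Segmentation

Cancer cells are identified by cytokeratin positivity: the cytokeratin
channel is thresholded into a binary mask (Otsu by default — deterministic
and parameter-free — with a fixed-value override recorded in the mask's
provenance), nuclei are segmented from the nuclei channel, and only nuclei
whose centroid pixel falls inside the cytokeratin mask are retained. Nucleus
segmentation labels connected components of the nuclei mask, drops
components below `min_area` (default 4 µm²), splits touching nuclei by
local-maximum marker seeding plus watershed, and reports intensity-weighted
centroids in µm (pixel centers at ((j+0.5)·px, (i+0.5)·px), 0-based).
`threshold_channel` accepts an optional Gaussian matched filter
(`smooth_sigma_um`) before thresholding: at low snr the raw histogram is
near-unimodal and Otsu lands inside the noise, while object-scale smoothing
restores the bimodality it needs. Nuclei touching the image border are
retained here; border handling is the LII edge exclusion's job.

Invasion counting in 3D cultures takes the maximum-intensity projection of
the nuclei z-series (so the count is invariant to z-order), smooths at the
nucleus scale, thresholds, labels, and counts components whose centroid
falls outside the central-region polygon. Centroids exactly on the polygon
boundary count as invaded: the exclusion zone is the region's open interior,
a deterministic tie-break.

At snr ≥ 5 and nucleus separation ≥ 3 radii the pipeline recovers every
planted cell with centroid RMSE ≈ 0.34 px and LII within a fraction of a
percent of the ground-truth value (validated over 8 rendered 300 × 300 µm
images, ~1400 cells).

## DCIS index

For a tumor mid-section with `n` intact (non-disseminated) in-situ
structures, tumor area `A_t` (whole tumor region) and cellular area `A_c`
(cancer-cell area excluding stroma), the cellular coefficient is `A_c / A_t`
and the DCIS index is `n · (A_c / A_t) / A_t` — structures per unit tumor
area, cellularity-corrected. Areas default to mm² with the unit declared
alongside the index. On synthetic sections the tumor area is measured as the
convex hull of the thresholded tissue mask, the cellular area by Otsu on the
cells channel, and structures as bright ring-shaped components above 75% of
the channel's dynamic range with a 50 µm² minimum area. Structure
identification on real H&E material is a pathologist call; the automated
counter is validated only against synthetic sections, and a manual count
override is accepted.

## Exact 2×2 odds-ratio meta-analysis

Each study contributes counts (a, b; c, d) of exposure × outcome. Studies
with fewer than 10 patients in either treatment group, or with incomplete
counts, are excluded with a recorded reason. The per-study estimate is the
sample OR (a·d)/(b·c); if any cell is zero the Haldane–Anscombe 0.5
correction is applied to all four cells and the result flagged.
Significance is the two-sided Fisher exact p by the point-probability
method (sum of hypergeometric probabilities of tables, at the observed
margins, no more probable than the observed one), via
`scipy.stats.fisher_exact`; the test suite checks it against a full
enumeration oracle to 1e-12 for all n ≤ 40. The 95% CI is the conditional
exact (Cornfield-type) interval obtained by inverting noncentral
hypergeometric tail tests at α/2 per side
(`scipy.stats.contingency.odds_ratio(kind="conditional")`), hitting 0 /
∞ when the first cell is at its conditional extreme and raising on
degenerate margins. These central intervals are conservative: measured
coverage at a planted OR of 1 (50 patients/arm, binomial outcomes) is
≈ 95–97%. Pooling across studies is opt-in (Mantel–Haenszel), since the
per-study forest table is the primary output.

Note on null simulation summaries: the sample OR is skewed upward in small
samples (mean ≈ 1.11 at 50/arm under a true OR of 1), so null checks
summarize the geometric mean (the log-OR scale), which sits within 1% of 1.

## Kymograph dynamics and the leading-edge band

A kymograph is a space × time raster (rows: µm along the line, columns:
frames). Membrane ruffles appear as bright sloped streaks; detection
normalizes the raster to [0, 1], takes 8-connected components above a
contrast threshold (default 0.4 — low enough that the flanking rows of a
rendered streak stay attached at steep slopes, high enough that noise
components stay below the 10-pixel minimum size), and fits each trace with
least squares of position on time; speed is |slope| converted to µm/min.
A Theil–Sen median-slope option is available for crossing traces. A trace
confined to one frame has no time extent and speed 0 by contract. Planted
traces (0.5–5 µm/min) are recovered with exact counts and speeds within
~1%.

The leading-edge band restricts marker quantification (pMLC, Arp2/3, …) to
the cell periphery: per z-slice, the actin-derived cell mask's Euclidean
distance transform identifies cell pixels within `width_um` (default 3 µm)
of the boundary; slices are stacked into a 3D mask (2.5D — matching
slice-wise mask construction, not full 3D distance). The distance transform
measures distance to the nearest *background pixel center*, which sits about
half a pixel beyond the geometric boundary, so the cutoff is
`width_um + px/2`; with that correction a 3 µm band on a 10 µm disc cell
reproduces the analytic annulus ratio (10² − 7²)/10² = 0.51 within 2% at
0.2 µm/px. Band means are plain arithmetic means over band voxels; the
enrichment-recovery check additionally excludes a 1-pixel guard zone on both
sides of the band boundary, because boundary pixels are mixtures of the two
compartments.

## Volcano gene screen

For a curated gene list across a two-group expression matrix, fold change is
the ratio of linear-scale group means reported as log2, and p comes from
Welch's t test on log2 intensities (the simplest defensible per-gene test;
the original per-dataset statistics behind public microarray portals are not
specified). A gene is a hit iff |fold| ≥ 2 and p ≤ 0.05 — deliberately
*without* multiple-testing correction, matching the per-gene threshold rule;
Benjamini–Hochberg is available behind a flag. Genes with zero variance in
both groups are flagged, not dropped. Recurrence across independent datasets
ranks genes, ties broken by mean −log10 p.

## Synthetic data: what it does and does not emulate

The generators provide: spatially cohesive (Thomas/Neyman–Scott) vs
dispersed (hardcore, dart-throwing) vs random (Poisson) tumor architectures
at tissue-plausible densities; two-channel renders with Gaussian nuclei
blobs (s.d. = radius/2), disc-union cytokeratin footprints and additive
Gaussian noise at σ = peak/snr; staggered non-crossing kymograph streaks;
disc cells with a planted band enrichment; DCIS sections with an exact
cellular-area fraction (quantile-thresholded smooth random field) and
non-overlapping ring structures; binomial 2×2 tables with odds scaled by a
planted OR; and log-normal expression with a multiplicative planted fold
change. Thomas parents are simulated in a window enlarged by 4σ on all
sides (plus-sampling) so offspring intensity has no edge deficit. Every
generator is bit-reproducible from (seed, parameters), and every rendered
object has exactly one ground-truth record.

Deliberately *not* emulated: histology texture and stain variability,
overlapping/aspherical nuclei, autofluorescence and illumination gradients,
stain deconvolution, 3D nucleus shapes, or real study-to-study
heterogeneity in the meta-analysis. Passing recovery tests therefore
demonstrates the correctness of the measurement chain, not robustness to
every artifact of real tissue.

Defaults were chosen once as plausible study conditions: tissue intensities
of 0.002–0.01 cells/µm² put the Poisson LII in the 5–11 µm range the 7/9 µm
bins straddle; nucleus radius 3 µm at 0.5 µm/px matches 20× tissue imaging;
kymographs use 0.2 µm/px and 5 s/frame over 45 rendered minutes; z-series
use 0.2 µm steps at 100× scale. The cohesive-vs-dispersed cohort uses
Thomas clusters (σ = 6 µm, 15 offspring/parent, λ = 0.004) against hardcore
patterns (λ = 0.0025, minimum distance 6 µm), chosen so the two classes'
expected LII fall on opposite sides of the 7–9 µm gap.

## Validation problem sizes

The acceptance battery runs, per seed: 100 random patterns (n ≤ 2000)
for the NND oracle; 200 Poisson replicates at each of four intensities in a
500 × 500 µm window for the closed form; 100 replicates per process for the
clustering ordering; 8 rendered images (~1400 cells) at snr 5 for
segmentation recovery; 1000 random tables (n ≤ 40) for the Fisher oracle
and 1000 simulated tables per planted OR for CI coverage; 50 kymographs;
40 + 40 rendered tumors for cohort discrimination; and 4 DCIS sections.
The full battery completes in about a minute on one CPU.

## Known limitations

- The LII border correction's truncation bias (above) is inherent to the
  index's definition; report window size with any cross-study comparison.
- The ruffle detector assumes non-crossing, roughly linear traces; heavily
  crossing traces need the robust slope option and may still merge.
- The DCIS structure counter is a stand-in for expert annotation, validated
  on synthetic rings only.
- The screen reproduces threshold logic, not any specific portal's
  normalization; per-dataset results on real arrays will differ.
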