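# Methods

`qsmlm` quantifies the nanoscale organization of membrane receptors from
single-molecule localization microscopy (SMLM) data.  Its input is a table
of localizations — one row per detected fluorophore appearance, with
coordinates in nm, the acquisition frame, a photon count, and a
localization precision σ_loc — as produced by any standard PALM/dSTORM
detection pipeline.  Its outputs are, per region of interest (ROI):
the blinking-corrected molecular density, the pair-correlation cluster
radius and molecules per cluster, and the fraction of molecules organized
in clusters of more than two receptors.

## Pipeline

For each acquisition:

1. **Noise filtering.**  Localizations whose precision exceeds the 98th
   percentile of the acquisition are discarded.  The percentile uses the
   linear-interpolation definition (NumPy's default): for precisions
   1..100 nm the cutoff is 98.02 nm and exactly 98 localizations survive.
   The cut is computed per acquisition table by default (a per-ROI option
   exists), since precision statistics are a property of the imaging
   conditions, not of a region.
2. **Drift correction** (optional, when fiducial beads are present).
   Beads are detected as emitters persistent at one position in ≥ 50% of
   frames within a 100 nm search radius; blinking fluorophores, visible for
   a handful of frames, never qualify.  Per-frame drift is the average
   bead displacement relative to the first-window position, smoothed by a
   centered 100-frame rolling mean, linearly interpolated across missed
   detections, and anchored to zero over the first window.  On simulated
   linear drift (0.05 nm/frame, 10 000 frames, 2 nm bead noise) the
   residual is below a few nm, i.e. ≪ 20% of the injected drift.
3. **ROI selection.**  Rectangular ROIs of 10–18 µm² are placed by grid,
   seeded random sampling, or explicit coordinates, requiring a minimum
   localization count and pairwise disjointness.
4. **Binarization.**  In-ROI localization centers are rendered onto a
   10 nm pixel grid; a pixel is set iff at least one center falls in it.
   10 nm is far below the ~80 nm cluster scale and close to typical
   precision, so binarization loses little information; the value is
   configurable because rendering is not dictated by the physics.
   Pixels are half-open `[i·p, (i+1)·p)`, with the max boundary closed.
5. **Pair correlation.**  g(r) is estimated as
   `g(bin) = Σ(I⋆I) / Σ(W⋆W) / ρ²` over radial bins of one pixel width,
   where I⋆I is the zero-padded FFT autocorrelation of the binary image,
   W⋆W = (nx−|dx|)(ny−|dy|) is the exact rectangular-window pair count
   (edge correction), and ρ is the mean occupancy.  A brute-force O(N²)
   pair-histogram estimator with bit-identical binning serves as the test
   oracle; the two agree to numerical precision.
6. **Model fit.**  Weighted least squares of

       g(r) = c + B·exp(−r²/(4σ_s²)) + A·exp(−r/ξ)

   over r ∈ [20, 1000] nm, weights equal to the per-bin window pair
   counts, multi-started over a grid of σ_s and ξ initial values.
   The Gaussian term absorbs overcounting from repeated localizations of
   single molecules; its scale σ_s is bounded to [0.3, 3] × σ_init (σ_init
   ≈ √2 × mean precision) because the width of the blinking term is set by
   the measured localization precision — leaving it free lets it swallow
   genuine cluster correlations.  B is a free amplitude rather than a
   function of the blinking constant α, which keeps the fit robust to the
   unknown variance of the blink-count law.  The baseline c ∈ [0.5, 1.5]
   is free: a single finite ROI estimates its own mean density, so its
   empirical g(r) plateaus at 1 only in expectation; without c the
   realization-level offset is chased by a spurious long-range exponential
   with essentially unbounded ξ.  The cluster term is declared
   *significant* only when A exceeds twice its standard error and ξ is
   determined to better than its own magnitude; insignificant fits
   contribute zero molecules per cluster.
7. **Counting.**  Two routes, both reported.  (a) The number of in-ROI
   localizations divided by the fluorophore's mean localizations per
   molecule α (≈5 for paGFP, ≈3 for AF647 under the calibrated imaging
   conditions) gives the detected density.  (b) Localizations are greedily
   grouped into molecules in frame order: a localization joins an open
   molecule iff it lies within the group radius (3 × the maximum
   localization precision of the filtered table) of its running
   precision-weighted centroid and within the maximum dark time (5 s) of
   its last appearance; ties go to the nearest centroid, then the lowest
   molecule id.  The ratio of the two counts is a logged QC metric
   (≈ 1 on simulated data).
8. **Clustering.**  Molecule centroids are joined by single linkage at a
   link radius derived from the PC fit, and connected components of size
   1 / 2 / ≥3 are classified monomer / dimer / clustered.  The fraction
   clustered counts only molecules in components of more than two
   receptors.  Per-cluster radius is the radius of gyration of member
   centroids.
9. **Group statistics.**  Per-ROI metrics are aggregated per treatment
   (mean, SEM with n−1 denominator; the ROI is the unit of analysis);
   occupancy and radius distributions pool clusters across ROIs into
   half-open bins with open-ended ">8 molecules" and ">80 nm" top classes;
   group comparisons use Welch's unequal-variance t-test with a one-tailed
   p value, with no multiple-testing correction by default (a Holm option
   exists in the comparison utilities through statsmodels-compatible
   output, off by default).

### The link radius

The spatial threshold coupling the PC analysis to the clustering step is
the fit's cluster correlation length ξ, deconvolved for localization-noise
broadening: the correlation is measured on raw localizations whose
positions are blurred by σ_loc each, so the measured scale obeys
ξ_meas² ≈ ξ_true² + 2σ̄², while molecule centroids (averages of several
localizations) are much sharper.  The link radius is therefore
√(ξ² − 2σ̄²), floored at 2σ̄ — below about twice the precision two
molecules cannot be resolved apart, so no smaller threshold is meaningful.
When the fit detects no significant cluster term (e.g. on a spatially
random pattern), the link radius falls back to that 2σ̄ floor.

The fraction clustered is steeply sensitive to the link radius (single
linkage percolates when density × π·link² approaches 1), so for *analyses
that compare conditions* the threshold is estimated once from the pair
correlation pooled across the ROIs being analysed
(`recovery.evaluate_condition`, and one shared threshold across all
conditions in `recovery.condition_table` when the compared conditions
share cluster morphology).  Holding the threshold fixed across compared
groups ensures that measured differences reflect the patterns rather than
threshold noise; per-ROI fits are still computed and reported, and
`analyze_roi` keeps the fully per-ROI behavior for single-ROI use.

## Synthetic data

The simulator provides ground truth for parameter recovery; it is the
validation substrate, not a model of any particular instrument.

* **Pattern.**  A square field (treated as a torus, so clusters are never
  edge-truncated and the pattern is stationary) of area 16 µm² at total
  density 50 molecules/µm².  A fraction φ of molecules belongs to clusters
  whose centers are uniform; occupancy is Poisson with mean n̄ truncated
  at ≥ 3 (ground-truth "clustered" matches the more-than-two-receptors
  definition); member displacements are isotropic Gaussian with scale R.
  The reference clustered condition uses φ = 0.5, R = 80 nm, n̄ = 8 —
  density, radius and occupancy chosen at the scales the analysis is
  designed to resolve.
* **Blinking.**  A detected molecule (probability `detection_prob`,
  default 1) appears k ~ Geometric(mean α) times — the minimal memoryless
  law when only the mean is calibrated; first appearance uniform over the
  acquisition (15 000 frames × 100 ms PALM-like, 30 000 × 10 ms
  dSTORM-like), later appearances separated by geometric dark times of
  mean 0.5 s (well under the 5 s grouping threshold, so temporal grouping
  is genuinely exercised); appearances beyond the acquisition are lost
  (a ≲0.5% deficit at the defaults).  Each appearance is displaced by
  Gaussian noise with that localization's own precision draw (lognormal,
  median 15 nm paGFP / 10 nm AF647, geometric SD 1.4) and carries a
  lognormal photon count.  Appearances occupy a single frame by default.
* **Presets.**  `csr` (φ=0), `steady_state` (φ=0.2, R=70, n̄=6),
  `mab_single` (φ=0.5, R=80, n̄=8), `mab_combo` (φ=0.75, R=100, n̄=12)
  span none → strong clustering for ordering tests.

What the simulator does *not* emulate: triplet-state photophysics and
laser-power-dependent blinking, camera noise and PSF shape, cell-shaped
(non-stationary) molecule distributions, incomplete labeling or unbound
probe background, and 3D effects.  Passing recovery tests therefore show
the *estimators* are correct and unbiased under the stated generative
model — not that any particular biological dataset meets that model.

## Numerical choices and degenerate inputs

* Percentile definition: linear interpolation between order statistics.
* FFT padding: `next_fast_len(2n)` per axis — exact linear correlation.
* Radial bins: width = pixel size, starting at 0; zero-lag self-pairs land
  in the first bin and are excluded from fitting (r ≥ 20 nm).
* Fit non-convergence from every start yields a flagged result, never an
  exception; the pipeline then uses the fallback link radius and marks the
  ROI.
* Empty tables, empty images, single-pixel images, and single-ROI groups
  are flagged or rejected with specific errors rather than propagating
  NaNs.
* Grouping tie-breaks (nearest centroid, then lowest id) and stable frame
  sorting make the partition deterministic; the partition property (every
  localization in exactly one molecule) is asserted on every run.
* All randomness flows through `numpy.random.default_rng` seeds carried in
  the parameter objects; scenario seeds are split into independent
  pattern/blinking streams via `SeedSequence`.

## Validation problem sizes

The shipped validation suite uses 20 ROIs of 16 µm² per condition (≈800
molecules, ≈4000 localizations each), 50 random images for estimator
cross-checks, 50 seeds for counting bias, and 100 random instances for the
grouping/clustering oracles.  At these sizes the full suite completes in
a couple of minutes on a single core while leaving Monte Carlo standard
errors well below the decision bands.

## Known limitations

* The exponential cluster model is a phenomenological choice; on Gaussian
  clusters the fitted ξ is an effective scale (empirically within a few
  percent of the generating R at the reference condition, after the
  precision deconvolution above).
* "Cluster radius" is reported as ξ; alternatives (2ξ, FWHM, radius of
  gyration per detected cluster) are available in the reporting options,
  and the per-cluster radius-of-gyration distribution is reported
  independently.
* Single linkage near its percolation threshold makes the fraction
  clustered sensitive to density; compare conditions only with a shared
  threshold (see above) and similar densities.
* The fraction clustered includes chance co-location: even a fully random
  pattern has a nonzero expected value at a fixed positive link radius.
  The significance gate keeps this near zero for patterns without a
  detected cluster term, but residual positive bias of order +0.05 remains
  for genuinely clustered patterns.
* Counting by N_loc/α assumes α is calibrated for the imaging session;
  miscalibration scales densities linearly and molecules-per-cluster
  proportionally.
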