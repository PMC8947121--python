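# Methods

## The calibration model

dMRI tractography returns pairwise streamline counts S_ij in arbitrary units
assumed proportional to the number of axons linking parcels i and j. The
corpus callosum provides the absolute anchor: its cross-sectional area A_cc
(mm², per subject) times the histological callosal packing density ρ
(axons/mm²) counts the axons it carries, and all interhemispheric
corticocortical axons are taken to route through it. Per subject s,

    c_s = (A_cc,s · ρ) / Σ_{i∈L, j∈R} S_ij,s

and the cohort conversion factor c̄ is the arithmetic mean of the c_s (the
"mean of quotients"; the ratio of cohort means is reported alongside as a
diagnostic — the two differ when callosal areas and streamline sums covary
across subjects). Absolute counts are N = c̄ · S̄ with S̄ the cohort-mean
streamline matrix. Key assumptions, each testable in the package:

1. proportionality of streamlines to axons (any global rescale of S cancels
   in c̄·S̄ — asserted numerically to 1e-10 relative tolerance);
2. parity of tractography sensitivity to intra- and interhemispheric fibers
   (the `distance` module's regressions and permutation test);
3. packing density roughly uniform across hemispheric white matter, so the
   callosal a = 1/ρ serves as the effective per-axon cross-section (axon
   proper plus myelin, glia and extracellular space) in volume budgets.

Densities are used as shrinkage-corrected literature values
(ρ_callosal = 3.7 × 10⁵, ρ_ipsilateral = 3.5 × 10⁵ axons/mm²); the
`shrinkage_corrected` flag is metadata, no shrinkage arithmetic is performed.

## Downstream accounting

* **Summaries.** Medians pool unordered pairs, intrahemispheric across both
  hemispheres and interhemispheric across left–right pairs, including
  zero-count pairs by default (they are observed pairs; a flag restricts to
  connected pairs). The adjacent-pair fraction is the axon-weighted share of
  physically adjacent parcel pairs. Projection fractions divide total (or
  nonadjacent) axons by the cortical pyramidal-cell count (default
  11.5 × 10⁹), attributing each interareal axon to exactly one projecting
  neuron — an upper bound on the fraction of pyramidal cells projecting
  beyond their parcel. Log histograms use base-10 bins of width 0.25 dex
  (presentational only).
* **Distance parity.** Both pair sets are restricted to the intersection of
  their length ranges ("distance-matched" means the common domain; no 1:1
  pair matching). Zero-weight pairs are excluded from log fits and counted.
  The correlation comparison permutes group labels *within equal-width length
  strata* (default 15): an unstratified shuffle would confound the label with
  fiber length because the two sets occupy different parts of the common
  domain, and the stratified null is what makes the permutation p uniform
  under a shared decay law. A Fisher-z comparison is reported as a parametric
  secondary. Bootstrap CIs are percentile, resampling pairs within groups.
  Permutation ties within float tolerance count as exceedances
  (conservative).
* **Volume.** Occupied volume is Σ over unordered pairs of N_ij·L_ij·a.
  Reference white-matter volumes and white-gray areas are user-supplied
  inputs, never derived from images. `subcortical_budget` and the
  full-interconnectivity comparison are exposed only as parameterized linear
  helpers; their literature inputs are not bundled.
* **Tract fractions.** A fasciculus' mid-tract capacity is its cross-section
  times the ipsilateral density; the trans-terminal numerator sums N over
  (anterior × posterior) termination-field pairs within one hemisphere.
  Upper-bound semantics: every field-to-field axon is assumed to travel the
  tract. Termination fields are YAML data; the shipped AF/SLF specs carry the
  published cross-sections (arcuate 160.6/51.5 mm², SLF 213.8/174.4 mm²,
  left/right) and conservative (44, 45, 6r, IFSa, IFSp, FOP4 vs PSL, RI,
  STV, PFcm) or liberal (+47l, p47r vs +PF, PFm, PGi) fields.
* **Sensitivity.** Two adjustment modes: uniform multiplication of pairs
  shorter than a threshold (default <40 mm, ×2), and a multiplier
  m(L) = 1 + slope·(1/L − 1/L_ref) growing with inverse length and anchored
  to 1 at the reference length (default: the longest observed fiber, where
  the callosal calibration is most trusted). The slope is expressed in mm;
  `slope_for_multiplier` converts a target multiplier at the shortest length
  into this unit, since an inverse-length "slope" is only meaningful relative
  to a length scale. Under `hold_volume_constant` the per-axon area is
  rescaled by the inverse of the reported `density_factor` so the occupied
  volume is exactly invariant — the physical co-constraint that more axons in
  fixed white matter must be thinner axons. Reports flag whether the
  adjustment preserved the weak ordering of pair counts; when it does,
  medians cannot move unless the median pair itself is adjusted.

## The synthetic cohort generator

The generator emulates the statistical structure the analyses assume, not
brain anatomy:

* **Geometry.** Parcels are embedded uniformly in a 1.5 × 1 rectangle per
  hemisphere, mirrored across a small midline gap. Adjacency is the Delaunay
  triangulation (planar-like, connected, mirror-symmetric; two parcels per
  hemisphere degrade to a single edge). Surface areas are Dirichlet-
  distributed (concentration 8, coefficient of variation ≈ 1/3 across
  parcels), mirrored, and sum exactly to the configured total
  (1.77 × 10⁵ mm² by default). Ten network labels are assigned by angular
  sector.
* **Lengths.** Embedding distances are mapped monotonically (by rank) onto
  quantiles of a normal distribution truncated to `length_range`
  (default 10–300 mm, mean 155 mm, SD = range/8). The monotone map keeps
  adjacent pairs shortest and interhemispheric pairs longer on average while
  giving pair lengths the bell shape real tract-length distributions show —
  which is what makes the resulting weights approximately log-normal.
* **Weights.** log S_ij = log S₀ − λ·L_ij (+ log boost for adjacent pairs)
  + σ·z_ij per subject, with z symmetric standard normal. The decay rate λ
  applies identically to intra- and interhemispheric pairs: tractography
  parity is built in, and hemisphere-asymmetric nulls are produced in tests
  by post-multiplying one pair set.
* **Calibration closure.** Each subject's callosal area is
  r·ΣS_inter/ρ + ε with ε ~ N(0, `callosal_area_sd`) truncated at zero, and
  S₀ is solved so the expected area equals `callosal_area_mean`
  (689.45 mm²). Calibration therefore recovers the ground-truth ratio r
  exactly when `callosal_area_sd = 0` and within sampling error otherwise.
  The manifest also records a white-matter volume reference set so the
  cohort's expected occupied volume is 96% of it, mirroring the
  near-saturation of hemispheric white matter by interareal axons.
* **Demographics.** Sex uniform; age groups 22-25/26-30/31-35/36+ with
  weights 0.21/0.41/0.35/0.03, roughly a young-adult cohort mix.

Defaults not fixed by the emulated study conditions were chosen once on
field realism: λ = 0.05/mm (an exponential distance rule giving ~7 decades
of connectivity across 10–300 mm), σ = 1.0 natural-log units of pair
scatter, adjacency boost 4 (adjacent pairs disproportionally strong beyond
their short length), callosal-area SD 80 mm² (≈12% of the mean), 50
subjects. These are free `GeneratorConfig` parameters.

What the generator does **not** emulate: cortical geometry and surface-based
parcel shapes, distance-dependent noise, directedness, subject-level
covariance structure beyond the shared mean, U-fibers, or any diffusion
signal/tracking process. Passing closure tests therefore validates the
pipeline's arithmetic and statistical calibration, not the anatomical
accuracy of any particular real-data estimate.

## Numerical and testing choices

* Matrices are validated as square, finite, nonnegative, zero-diagonal;
  asymmetry below 1e-8 relative is symmetrized by averaging (float
  round-trip through text), larger asymmetry is an error naming the worst
  cell.
* Interhemispheric sums count each unordered left–right pair once; all
  matrices are treated as undirected.
* Degenerate bootstrap resamples (no length spread) are redrawn; empty
  length bins are reported with NaN means rather than dropped.
* The log-normality check on generated weights uses Shapiro–Wilk on seeded
  subsamples of ~500 nonadjacent intrahemispheric pairs. At much larger
  sample sizes the test detects the mild negative skew (|skew| ≈ 0.1) that
  any bounded-length exponential-distance generator necessarily imprints by
  excluding the shortest, adjacency-linked pairs — "approximately
  log-normal" is the designed property, and moderate-n Shapiro is the
  appropriate instrument for it.
* Statistical calibration tests (permutation-p uniformity across 200 seeded
  cohorts, bootstrap CI coverage across replicates) run at reduced problem
  sizes (24 parcels per hemisphere, few subjects, a few hundred resamples),
  chosen so the whole suite completes in well under a minute of statistics
  time while keeping Monte-Carlo error small relative to the asserted
  bands.
* Group comparisons require ≥2 levels with ≥2 subjects each; with sparse
  sex × age cells the interaction F is reported as NaN (rank-deficient
  contrast) rather than silently refit.

## Known limitations

* Real printed cohort statistics that depend on the deposited connectome
  matrices (pairwise medians, total axon count, the 2.00 cohort ratio,
  AF/SLF trans-terminal percentages) can be recomputed by feeding those
  matrices through the documented TSV/CSV schema, but are not reproduced
  from synthetic data, whose totals and medians reflect the generator
  configuration.
* The inverse-length sensitivity slope is package-defined (mm units,
  anchored at the longest fiber); published slopes in other unit conventions
  must be converted via the multiplier-at-minimum-length helper.
* The trans-terminal fraction inherits its upper-bound semantics from the
  routing assumption; no streamline-level tract membership is computed.
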