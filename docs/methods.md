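# Methods

This note documents the models, conventions and design choices behind each
stage of the pipeline, what the synthetic-data generator does and does not
emulate, and the known limitations.

## Conventions

Images are `(C, Z, Y, X)` float arrays; single planes use `Z = 1` so the 3D
code path is the only one. Coordinates are 0-based in `z, y, x` order with
half-open extents. Physical voxel sizes default to (0.5, 0.1, 0.1) µm in
`z, y, x` — 500 nm optical sectioning with ~0.1 µm lateral sampling, the
regime of high-NA condensate imaging. All sizes are reported in µm²/µm³
when voxel metadata is present, in voxels (flagged) otherwise.

## Segmentation

**Otsu threshold.** Classical formulation with 256 bins spanning the
observed min–max range; the returned threshold is a bin *edge*, and
foreground is strictly above it. Ties in the between-class variance are
broken toward the lowest edge, which makes the result deterministic and
affine-equivariant: rescaling intensities by `a·x + b` (a > 0) rescales the
threshold accordingly and leaves the mask unchanged. A constant image
raises a degenerate-histogram error rather than returning an arbitrary
number. The test suite checks equivalence against an exhaustive
search over all candidate edges.

**Field vs cell thresholding.** The threshold is global per field by
default. For fields dominated by empty background (as in the synthetic
scenes), `segment_puncta` first builds a cell mask (Otsu again, cells vs
background) and computes the puncta threshold over cell voxels only —
otherwise the background/cell split dominates the histogram and whole cells
are "detected". Per-cell thresholding is available through the `cell_mask`
argument.

**Labelling.** Full connectivity (8 in 2D, 26 in 3D); puncta are compact,
so full connectivity does not bridge distinct objects at realistic
densities. Minimum object size defaults to 4 voxels in 2D and 8 in 3D —
below these an "object" is indistinguishable from shot noise; both are
configurable. Components are renumbered consecutively after every filter,
so label k always means "the k-th surviving object".

**Nuclear exclusion.** An object intersecting the DAPI-derived nuclear mask
by ≥ 1 voxel is removed entirely (any-overlap rule); the operation is
idempotent. Nuclear masks are Otsu on DAPI with per-plane hole filling and
a 100-voxel minimum; an empty DAPI channel produces an empty mask and a
warning, not an error, so batch runs survive occasional bad fields.

**Cell assignment.** With no membrane marker, objects are assigned to cells
by majority vote over a cell-label map when one exists, or to the nearest
nucleus centroid (physical distance) otherwise.

## Condensate metrics

**Percent of signal in objects.** `100 · Σ(corrected object signal) /
Σ(cell signal)`. The optional background correction (modal non-object
intensity of the cell, or an explicit offset) is applied to the object
voxels in the numerator only: it removes the diffuse pool that happens to
lie under the object masks, while the denominator remains the cell's total
signal. Correcting both sums with the modal level would cancel the diffuse
pool from the denominator entirely and force the ratio toward 100 %.
With no correction, `percent inside + percent outside = 100` exactly.

**Per-object Pearson.** The standard coefficient over the voxels strictly
inside each object mask (no shell), invariant under positive affine
rescaling of either channel; objects in which either channel is constant
are flagged undefined and excluded from summaries rather than contributing
a NaN silently.

**Content classification.** An object "contains" a protein when its mean
intensity exceeds `enrichment_factor` (default 1.5) × the median non-object
intensity of its cell. The factor is a free parameter with no canonical
value; it is recorded in every output.

**Docking events.** The gap between an SG and a P-body counts the
background voxels between their surfaces (Chebyshev metric, matching the
full-connectivity convention): gap 0 means touching or overlapping, and the
default criterion gap ≤ 1 means "touching after one dilation". Each
(SG, P-body) pair is counted once; the relation is symmetric in its
arguments, and events are also reported per SG.

## FRAP

**Normalisation chain.** (1) subtract the background ROI; (2) divide by the
background-subtracted reference ROI scaled to its own pre-bleach mean —
this cancels acquisition photobleaching exactly when bleaching affects both
ROIs proportionally; (3) map linearly so the first post-bleach value is
exactly 0 % and the highest pre-bleach value exactly 100 % (the division is
performed before the ×100 scaling so these anchors are exact in floating
point). When no reference ROI exists the photobleach correction is skipped
and flagged — it is not estimated from the bleached ROI itself, which would
invent signal. A trace whose pre-bleach maximum does not exceed the first
post-bleach value raises "no bleach detected". The chain is idempotent and
invariant to a common positive rescaling of all three ROIs.

**One-phase association fit.** `Y = Y0 + (plateau − Y0)(1 − e^(−Kx))` with
`x = 0` at the first post-bleach frame, fitted to post-bleach points only
by bounded nonlinear least squares: Y0 ∈ [−20, 20] %, plateau ∈ [0, 150] %,
K ∈ (0, 10] s⁻¹. Y0 is left free (the printed model has it) rather than
pinned to the 0 % anchor, so residual bleach-point noise does not bias the
plateau. Initial values: Y0 = first post value, plateau = mean of the last
three points, K = ln 2 / (time to half of that plateau, by scan). An
all-zero post-bleach series returns mobile fraction 0 with K undefined and
a flag; non-convergence returns a flagged result, never an exception or a
silent number. `t½·K = ln 2` holds to machine precision by construction.
Mobile fraction = plateau − Y0.

**QC and exclusions.** Traces whose first post-bleach raw value exceeds
80 % of the pre-bleach mean are flagged as insufficiently bleached (the
protocol aims at ~50 % bleach efficiency). Group summaries exclude
non-converged fits and fits with R² < 0.5, always listing exclusions with
reasons; no value-based outlier trimming is applied. Summaries report
mean ± sd, CV, and the K² normality verdict when n ≥ 8.

**Adaptive timestamps** are used as recorded; no resampling or
interpolation.

## Kinetics

Formation time is the earliest recorded time-point with ≥ 5 SGs (threshold
configurable, monotone: a higher threshold can only delay or censor it);
dispersal time is the earliest time-point with 0 SGs in a series that
starts with SGs present. Both read the frames literally: reported times are
always members of the timestamp grid, a transient zero counts as dispersal
even if SGs recur (first-zero rule), and series that never reach the event
are returned as censored, with censoring counts carried into every summary.
Fraction-of-cells curves require a common timestamp grid — no interpolation
between frames. Percent-of-control normalisation divides by the control
mean, so the control group itself averages exactly 100 %.

## Statistics

**D'Agostino–Pearson K².** `Z(√b₁)² + Z(b₂)²` using D'Agostino's (1970)
skewness transform and the Anscombe–Glynn (1983) kurtosis transform on the
moment (biased) estimators — the convention shared by the common reference
implementations, against which the tests check agreement to 1e-6. The
p-value uses χ² with 2 df; n ≥ 8 is required (the transforms are undefined
below), and constant samples are rejected. At n = 50 the χ² approximation
is mildly anti-conservative (empirical type-I error ≈ 0.06 at α = 0.05),
a property of the test itself, shared by the reference implementation.

**Test selection** is a pure function of the per-group normality verdicts:
all normal → unpaired t-test (2 groups) or one-way ANOVA; any non-normal →
Mann–Whitney U or Kruskal–Wallis. Groups too small for K² (n < 8) are
treated as unverifiable and routed to the rank-based branch unless the
parametric branch is forced. All tests are two-sided; no multiple-testing
correction is applied by default. The decision trace (each group's K², p
and verdict, and the selected test) is attached to every result.

**Coefficient of variation** is `100·sd/mean` with the n−1 sample standard
deviation (so CV of {1, 2, 3} is exactly 50 %).

**Sample size** inverts the noncentral-F power of a balanced one-way ANOVA
(λ = f²·k·n) by scanning n upward; for two groups this coincides with the
two-sided t-test computation at d = 2f. The returned n achieves the target
power and n − 1 does not.

## Synthetic data

The generator reproduces the statistical structure the analysis assumes,
not optics:

- **Cells**: non-overlapping elliptical nuclei (uniform DAPI intensity)
  inside larger cytoplasm ellipsoids carrying a uniform per-channel
  background. Placement is rejection-sampled with whole-configuration
  restarts, and an impossible packing fails loudly, naming the spec field.
- **Condensates**: isotropic Gaussian spots truncated at 3σ, with σ chosen
  so the spot FWHM equals the spec radius and the PSF added in quadrature.
  Ground truth records the *rendered* per-channel sum of every spot, so
  photon conservation against the image is exact before noise. Rendered
  footprints of distinct objects are kept ≥ 3 background voxels apart:
  segmented masks never merge and never dock by accident, which is what
  makes exact docking recovery a meaningful test.
- **Docking**: a docked P-body centre is placed at
  `(r_SG + r_PB)/2 + gap`, `gap ~ U(0, contact distance)`, from its partner
  — contact between the rendered half-maximum surfaces (which sit at
  radius/2 under the FWHM-=-radius convention), so the detector's criterion
  is exercised on both sides of the decision boundary.
- **Channel correlation**: within each object's footprint, channel B is the
  exact ρ-mixture of the standardised channel-A profile and independent
  noise, so the expected within-object Pearson coefficient equals ρ.
- **Noise**: Poisson on expected photons, then additive Gaussian read noise
  — the standard camera model — applied strictly after ground truth is
  recorded.
- **FRAP traces**: pre-bleach plateau, instantaneous bleach to the
  configured depth, recovery exactly one-phase with the configured mobile
  fraction and half-time, multiplicative per-frame acquisition bleaching on
  ROI and reference alike, plus Gaussian noise expressed as a fraction of
  the bleached amplitude (so "3 % noise" means ≈ 3 points on the normalised
  0–100 % scale). Default protocol: 3 pre-bleach frames, 25 post-bleach
  frames with intervals growing geometrically from 0.1 s to a 5 s cap —
  adaptive acquisition dense immediately after the bleach, covering the
  plateau for half-times up to several seconds.
- **SG-count trajectories**: counts rise monotonically (cumulative Poisson
  arrivals) from a per-cell Gaussian onset to a per-cell Poisson plateau,
  and fall monotonically (cumulative removals) after a dispersal onset.
  True formation/dispersal times are read from the realised trajectory with
  the same definitions the analysis uses, censoring included. The default
  cohorts use a control formation onset of 33 ± 8 min (so measured
  formation times land in the tens of minutes at 3-min framing) and a
  DM1-like arm with ~1.5× later onset and ~⅔ the dispersal onset —
  unambiguous directional effects at n = 25 cells per arm.
- A single integer seed expands into independent substreams (placement,
  object properties, noise), so adding noise does not reshuffle geometry.

Not emulated: diffraction beyond a Gaussian PSF, depth-dependent
aberrations, cell motility or division, uneven illumination, and
autofluorescence texture. Passing recovery tests therefore demonstrates
that the measurement chain is correct and calibrated on data satisfying its
assumptions — not that segmentation is robust to every real-microscopy
artefact.

## PrLD scan

A two-state hidden Markov model: a background state emitting residues at
human-proteome frequencies and a prion-like state emitting at the
composition of experimentally verified yeast prion-forming domains (both
tables vendored with provenance notes in `granulekit/data/`). Run lengths
are geometric; the prion state's expected run equals the core-length
parameter (default 30 aa) and the background's defaults to 400 aa, with the
stationary distribution as prior. The per-residue track is the *posterior*
prion-state probability from forward–backward decoding — a continuous
probability that can be plotted and cut at 0.5 — rather than a Viterbi
paint; domains are maximal runs above 0.5, reported 1-based inclusive so
the printed length equals `end − start + 1`. `X` is tolerated and scored
equally under both states; other non-standard residues are rejected with
their positions listed. Posterior computation is cross-checked against an
independent HMM implementation in the tests.

Limitations: the vendored frequency tables are transcribed from the
published composition data and the scan is a posterior-decoding
approximation of the original PLAAC scoring scheme, so domain boundaries on
real proteins can differ from the original tool by a few residues;
per-residue agreement with it on specific human proteins is not claimed.

## Problem sizes in tests and the acceptance script

Synthetic scenes are single-plane 256²–400² fields with 2 cells and 5–20
condensates; the FRAP grid uses 50 traces per condition (28 frames each);
segmentation recovery uses 100 scenes; colocalisation calibration 200
objects per ρ; normality calibration 2000 replicates at n = 50. These sizes
put Monte-Carlo error comfortably inside the asserted tolerances while the
full suite runs in well under a minute of compute.
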