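# granulekit

Quantitative image analysis of biomolecular condensates — stress granules
(SGs), P-bodies and nuclear RNA foci — in multi-channel fluorescence
microscopy, with the downstream dynamics and statistics that condensate
studies report. The package was built around the measurements used to
characterise altered SG/P-body behaviour in cellular models of myotonic
dystrophy type 1 (DM1), where expanded-CUG-repeat RNA sequesters MBNL1 into
nuclear foci and perturbs cytoplasmic condensate dynamics, but every stage
is generic.

It is aimed at cell biologists and image analysts who need a scriptable,
testable replacement for interactive quantitation modules: segmentation and
per-object measurement, colocalisation, docking-event counting, FRAP curve
fitting, SG assembly/disassembly kinetics, normality-driven test selection,
and prion-like-domain (PrLD) scanning — plus a synthetic-microscopy
generator with exact ground truth, so the whole pipeline can be validated
without any raw images.

## What it computes

**Segmentation** (`granulekit.segmentation`). Global Otsu thresholding (the
bin edge maximising the between-class variance `w₀w₁(µ₀−µ₁)²`, lowest edge
on ties), full-connectivity component labelling with a minimum object size,
DAPI-based nuclear masks, and removal of every object that intersects the
nuclear mask by even one voxel. Objects are measured per channel (voxel
count, physical size from anisotropic voxel metadata, centroid, mean and
integrated intensity).

**Condensate metrics** (`granulekit.metrics`). Percent of total cellular
signal in condensates, nucleocytoplasmic partition, per-object Pearson
correlation between two channels, protein-content classification of
P-bodies against the median cytoplasmic background, per-cell counts and
sizes, and SG–P-body *docking events*: pairs of objects whose surfaces are
separated by at most a configurable number of background voxels (default 1,
i.e. touching after one dilation), reported per SG.

**FRAP** (`granulekit.frap`). Background subtraction, acquisition-photobleach
correction against an unbleached reference ROI, and the standard
normalisation that pins the first post-bleach frame to 0 % and the highest
pre-bleach frame to 100 %. Recovery is fitted (post-bleach points only,
nonlinear least squares) with the one-phase association

    Y = Y0 + (plateau − Y0) · (1 − e^(−K·x))

giving the mobile fraction `plateau − Y0` and half-time `t½ = ln 2 / K`.
`OnePhaseAssociation(norm).fit()` returns a results object with estimates,
standard errors, R², QC flags and a `summary()`.

**Kinetics** (`granulekit.kinetics`). From per-cell SG-count time series:
formation time (first time-point with ≥ 5 SGs), dispersal time (first
time-point with 0 SGs), both censoring-aware; fraction-of-cells-with-SGs
curves; percent-of-control normalisation.

**Statistics** (`granulekit.stats`). An own implementation of the
D'Agostino–Pearson omnibus K² normality test (skewness and kurtosis
Z-transforms, χ²₂ p-value), the normality-driven test-selection rule
(all groups normal → t-test / one-way ANOVA; otherwise Mann–Whitney U /
Kruskal–Wallis) with a full decision trace, noncentral-F power analysis
(smallest per-group n for a Cohen's f at a target power), and the
coefficient of variation.

**PrLD scan** (`granulekit.prld`). A two-state HMM over amino-acid
composition (yeast prion-forming-domain emissions vs human-proteome
background), posterior-decoded per residue; PrLDs are maximal runs with
prion-state probability > 0.5, with the expected domain length set by the
core-length parameter (default 30 aa).

**Synthetic data** (`granulekit.synthetic`). Scenes with elliptical nuclei
and cytoplasm, Gaussian-spot condensates with configurable counts, sizes
and intensities, controlled within-object channel correlation, docking
geometry, Poisson + Gaussian noise; FRAP traces whose normalised recovery
is exactly a one-phase association; SG-count trajectories with known
formation/dispersal times. Everything is a pure function of (spec, seed)
and returns a `GroundTruth` for recovery testing.

## Worked example

```python
from granulekit import synthetic as syn
from granulekit import segmentation as seg, metrics
from granulekit.frap import correct_and_normalize, fit_one_phase

spec = syn.SceneSpec(
    image_shape=(1, 400, 400), n_cells=2, cytoplasm_scale=2.5,
    cytoplasm_intensity={"gfp": 20.0, "stain": 20.0},
    condensates=[
        syn.CondensateClassSpec(name="sg", compartment="cytoplasmic",
                                count_mean=4, radius_mean_um=0.4,
                                peak_intensity={"gfp": 200.0}),
        syn.CondensateClassSpec(name="pbody", compartment="cytoplasmic",
                                count_mean=10, radius_mean_um=0.3,
                                peak_intensity={"stain": 150.0}),
    ],
    docking_fraction=0.5, seed=42)
stack, truth = syn.generate_scene(spec)

sg_labels, nuclei, cells = seg.segment_puncta(stack, "gfp")
pb_labels, _, _ = seg.segment_puncta(stack, "stain", cell_mask=cells)
events = metrics.docking_events(sg_labels, pb_labels, max_gap_voxels=1)
print(f"SGs: {sg_labels.n_objects}   P-bodies: {pb_labels.n_objects}")
print(f"docking events: {events.attrs['n_events']} "
      f"({events.attrs['events_per_sg']:.2f} per SG; "
      f"ground truth {len(truth.docked_pairs)})")

trace = syn.simulate_frap_trace(syn.FRAPSimSpec(
    mobile_fraction_true=69.6, t_half_true=2.5, noise_sd=0.03, seed=7))
fit = fit_one_phase(correct_and_normalize(trace))
print(fit.summary())
```

prints

```
SGs: 8   P-bodies: 20
docking events: 6 (0.75 per SG; ground truth 6)
One-phase association fit  Y = Y0 + (plateau - Y0)(1 - exp(-K x))
  n post-bleach points : 25
  Y0                   :     0.73 %
  plateau              :    64.69 %
  K                    :   0.3139 1/s
  mobile fraction      :    63.96 %
  half-time t1/2       :    2.208 s
  R^2                  :   0.9838
  converged            : True
```

The two cells contain 8 SGs and 20 P-bodies; half of the P-bodies were
placed in contact with an SG and the detector recovers exactly those 6
docked pairs. The FRAP trace was simulated with a 69.6 % mobile fraction
and 2.5 s half-time at 3 % noise; a single noisy trace fits to 64 %/2.2 s
(the estimator is unbiased — medians over many traces converge to truth, as
the test suite verifies).

A command-line interface mirrors the library: `granulekit simulate|segment|
coloc|metrics|frap-fit|kinetics|stats|prld`, each writing CSV/JSON plus a
`run_config.json` with the resolved parameters and seed.

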