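# Methods

This note records the models implemented in `cmrquant`, their
assumptions, the defaults and why they were chosen, and what the
synthetic phantoms do and do not establish about real data.

## Perfusion quantification

### Model

Myocardial signal intensity during first-pass contrast transit is
modelled as the convolution of the arterial input function c_a(t)
(LV blood-pool signal on the basal slice) with a tissue impulse
response, under the assumption that signal is proportional to
gadolinium concentration.  This linearity holds at the low first-pass
dose regime (≈0.05 mmol/kg); no saturation or dual-bolus correction is
applied, and none is needed for the phantoms, which are generated under
the same linear model.

The impulse response is the Fermi function

    h(t) = A · (1 + exp(−w/k)) / (1 + exp((t − t_d − w)/k)),  t ≥ t_d
    h(t) = 0,                                                 t < t_d

with amplitude A (the plateau, equal to MBF in mL/min/g), arrival delay
t_d (s), shoulder w (s, plateau duration before roll-off) and decay
width k (s).  The discrete forward model is
`tissue = conv(aif, h) · dt / 60`, which makes a plateau expressed in
per-minute flow units dimensionally consistent with second-sampled
curves.

### MBF readout

MBF is reported as the plateau of the fitted impulse response evaluated
on the acquisition time grid — the maximum of h over the frame times —
rather than the analytic parameter A.  The distinction matters: on
discretely sampled curves the triple (A, t_d, w) is not identifiable,
because shifting t_d between two samples while adjusting w and A
reproduces the sampled response exactly (we observe distinct parameter
sets with residuals at machine zero whose A values differ by ~1%).  The
grid-sampled plateau is pinned by the data and is what the acquisition
can actually resolve; with it, noise-free closure against the forward
model is exact to machine precision.

### Fitting

* Curves are baseline-corrected by subtracting the mean of the first
  3 pre-contrast frames (configurable).
* Frame times with more than 1% jitter are linearly resampled to a
  uniform grid.
* The fit runs over the first-pass window only, where the Fermi model is
  valid: from contrast arrival (first AIF sample above 5× the
  pre-contrast SD, with a 5%-of-peak floor so noise-free curves still
  threshold) to the AIF minimum between the first-pass and recirculation
  peaks (last frame if no recirculation peak is detected).
* Bounded trust-region least squares (A ∈ [0, 10] mL/min/g,
  t_d ∈ [0, 10] s, k ∈ [0.1, 20] s, w ∈ [0, 30] s), restarted from three
  fixed initializations; the lowest residual wins and ties go to the
  smaller amplitude, so repeated runs are bit-reproducible.  Hitting the
  function-evaluation cap clears the convergence flag; flagged segments
  are reported, never silently dropped.
* An all-zero AIF raises a degenerate-input error; an all-zero tissue
  curve short-circuits to MBF = 0.

MPR is stress/rest MBF per segment; segments with non-positive rest flow
have undefined MPR and are excluded.  Regional values are unweighted
means over the segments of each label class (volume weighting would
require per-segment myocardial volumes, which planimetric perfusion
analysis does not usually carry).

### Segment model

The standardized 16-segment model: six equiangular basal, six mid, four
apical sectors, numbered counterclockwise from the anterior RV insertion
point, each mapped to a coronary territory (LAD/RCA/LCX).  The
"targeted" label marks the territory under treatment and is
configuration, not inference: in the emulated study design the treated
territory was identified by electromechanical mapping against nuclear
and CMR perfusion, which is outside this package's scope.

## LGE scar partitioning

Per slice, the reference is the mean μ and sample SD σ (ddof = 1) of a
remote normal-myocardium ROI *on the same slice* (pooled references
would be confounded by slice-level coil shading).  Classification of
myocardial voxels is:

* total scar: SI > μ + 2σ
* core: SI > μ + 3σ
* peri-infarct: μ + 2σ < SI ≤ μ + 3σ

Boundary conventions are fixed for exactness: membership above a
threshold is strict, and a voxel exactly at μ + 3σ stays peri-infarct
(the 2-to-3 SD band is closed on top).  With a degenerate reference
(σ = 0) both thresholds collapse to μ and any voxel strictly above the
remote mean is core — the limit of both rules.  Remote ROIs under
8 voxels trigger an unreliable-reference warning.

No morphology (minimum cluster size, hole filling) is applied by
default: pure thresholding is the reproducible core of the published
semiautomatic approach, whose exact post-processing is not specified.

Masses are voxel count × voxel volume × 1.05 g/mL.  Scar burden is
reported three ways: %MDE_total (percent of LV mass, mass-based),
core/peri as percent of total scar, and — in the cohort table — core and
peri as percent of LV mass so that total = core + peri within subject.

Transmural extent casts rays from the myocardial centroid (36 per
sector), takes per ray the ratio of enhanced to total wall samples, and
averages per sector; classes are <50%, 50–75%, >75% with boundaries
closed on the left (exactly 50% → middle class).  Rays that never cross
the wall (degenerate geometry) are skipped with a warning.

## LV function

Volumes are Simpson summations Σ area × (slice thickness + gap), areas
by planimetry of the traced polygon (validity-checked: self-intersecting
contours are rejected).  A configurable basal-slice inclusion cutoff
(endocardial area > 1 cm² by default) handles the outflow-tract slice;
mass uses only slices carrying both contours, so the cutoff cannot
unbalance the epi−endo difference.  EF = 100·(EDV − ESV)/EDV; mass =
(epi − endo) ED volume × 1.05 g/mL.  Papillary muscles are treated as
blood pool (excluded from mass), the common planimetric convention.

Wall thickness per sector is the mean epi−endo radial distance along
rays from the endocardial centroid (36 rays/sector); this assumes
star-shaped contours, which short-axis LV sections satisfy.  Percent
systolic thickening is 100·(ES − ED)/ED, the conventional definition.
Sectors with non-positive ED thickness are excluded.

## Cohort statistics

Two-sided paired Student's t tests on per-subject differences,
α = 0.05: t = d̄ / (s_d/√n), p from the t distribution on n − 1 degrees
of freedom.  Pairs with a missing side are dropped and counted.
Zero-variance differences are handled explicitly: all-zero → t = 0,
p = 1; nonzero → p = 0 with a degenerate flag.  The targeted vs
non-targeted contrast within a timepoint is also paired (each subject
contributes both regions).  No multiplicity correction is applied to the
primary calls — conventional for small exploratory cohorts — but a
clearly supplementary Holm-adjusted column is emitted alongside.

## Synthetic phantoms

The generator emulates the *study conditions*: 12 subjects, paired
baseline/6-month examinations, dynamic series of 60 frames at 1 s
(covering the first 30–60 heart beats), three short-axis levels, and
the following default effect sizes (mean ± SD baseline → follow-up):

| metric | baseline | follow-up |
|---|---|---|
| EF (%) | 51 ± 10 | 56 ± 9 |
| EDV (mL) | 150 ± 33 | 146 ± 30 |
| mass (g/m²) | 99 ± 28 | 95.6 ± 28.5 |
| targeted wall thickening (%) | 48.1 ± 10.2 | 53.4 ± 8.6 |
| targeted MPR | 1.2 ± 0.3 | 1.5 ± 0.4 |
| non-targeted MPR | 2.1 ± 0.6 | 2.3 ± 0.6 |
| targeted MBF rest/stress | 0.67 ± 0.17 / 0.83 ± 0.16 | 0.75 ± 0.3 / 1.12 ± 0.5 |
| non-targeted MBF rest/stress | 0.97 ± 0.9 / 2.01 ± 0.7 | 1.01 ± 0.5 / 2.3 ± 0.7 |
| %MDE_total / peri / core (% LV) | 20 ± 8 / 8 ± 4 / 12 ± 6 | 15.4 ± 7 / 5 ± 3 / 11 ± 6 |

Scar absolutes are a design choice (the emulated study reports only the
relative changes, ≈−23% total and −38% peri-infarct, which these
defaults reproduce); flow, reserve, function and thickening values are
the reported group statistics.  Paired draws use a Gaussian copula with
within-subject correlation ρ = 0.7 (only marginals are reported; 0.7 is
a typical test–retest correlation for these metrics).  Positive-only
metrics are floored at 0.05 — necessary because some reported SDs are
large enough to put normal draws below zero.

Structural choices:

* **AIF**: gamma-variate bolus (amplitude 50, onset 8 s, shape 3,
  scale 1.5 s → peak at 12.5 s) plus a recirculation copy delayed 20 s
  and scaled by 0.15.  Analytic, differentiable, and the standard
  first-pass form.
* **Tissue curves**: the forward model of the perfusion stage itself
  (AIF ⊛ Fermi at the planted MBF), which is what makes noise-free
  closure a meaningful test; noise is additive Gaussian by default
  (Rician available, immaterial at curve-level SNR).
* **Internal consistency**: a subject's embedded stress flow is
  rest × drawn MPR, so the recovered reserve closes on the drawn value;
  the embedded core scar is total − peri (the three scar percentages are
  drawn marginally and cannot all three be honoured at once).
* **LGE phantom**: remote voxels ~ N(μ = 100, σ = 10), with the upper
  tail iteratively clipped until the sample maximum sits within its own
  sample mean + 2 SD (a plain ~100-voxel normal sample has an expected
  maximum z-score ≈ 2.5 and would pollute the partition); core and peri
  voxels are planted at μ̂ + 4σ̂ and μ̂ + 2.5σ̂ *of the realized remote
  sample*, and normal-myocardium draws are clipped to the 2σ̂ threshold.
  This makes the planted partition exactly recoverable at zero added
  noise; the optional noise term deliberately breaks that guarantee.
* **Cine phantom**: cylindrical (for exact closure on EF, mass and
  thickening) and prolate-ellipsoid (for Simpson-rule accuracy checks)
  contour stacks with 96-vertex polygons; polygon discretisation of a
  circle biases areas by ≈0.23%, which cancels in EF and stays well
  inside the 2% volumetry tolerance.

What the phantoms do **not** emulate: MR physics (k-space,
saturation-recovery signal equations, motion and breathing artifacts,
coil inhomogeneity), partial-volume effects at mask edges, observer
variability in contouring, and nonlinearity between signal and
concentration.  Passing recovery tests therefore certifies the
*numerics* of the analysis chain — deconvolution, thresholding,
volumetry, statistics — not robustness to acquisition artifacts.

## Problem sizes and determinism

Demo/pipeline phantoms default to a 24 × 24 grid, 3 slices and 60
frames; the packaged end-to-end determinism check uses 2–3 subjects at
20 × 20 × 40 frames, which exercises every stage in seconds.  All
randomness flows from a single integer seed through
`numpy.random.default_rng`/`SeedSequence`; identical configurations
produce checksum-identical output bundles (the run log, which carries
timestamps, is the only exception).  Every run writes a provenance
record with the canonicalized-config SHA-256, the seed and library
versions.

## Known limitations

* The Fermi model regularizes deconvolution by construction and cannot
  represent multi-compartment washout; model-independent deconvolution
  is not implemented.
* Breathing-displacement correction is limited to what mask definitions
  provide; no image registration is performed.
* Transmural extent on coarse grids is raster-limited; fractions within
  ~1 voxel/wall-thickness of a class boundary can fall either side.
* The CLI reads the package's own NIfTI + JSON-sidecar dialect; DICOM
  import is out of scope (`pydicom`-based conversion would sit upstream).
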