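# Methods

`cacstudy` is an in-silico re-creation of a cardiac-phantom experiment on
coronary-calcium quantification with a photon-counting fan-beam CT bench:
how does the regularization strength of iterative reconstruction (IR),
through its effect on spatial resolution (MTF), control Agatston scores and
calcium volumes, across radiation dose levels realized by detector frame
averaging?  This note records the models, the synthetic study conditions,
the numerical choices, and what the passing tests do and do not establish.

## Digital phantoms

**Cardiac rod.**  A 9-cm-diameter soft-tissue cylinder (+35 HU) containing

* a centered 3-cm "heart" cylinder at +30 HU over background, giving a
  well-posed two-class Otsu segmentation for CNR estimation;
* nine calcium-hydroxyapatite (CaHA) insert cylinders, 7.0 mm high, on a
  30-mm ring: densities {100, 250, 400} mg/cm³ × diameters
  {1.2, 3.0, 5.0} mm, spanning CAD grades from "no CAD" to "severe";
* a thin air gap (one voxel wide, 20 mm long, tilted 3° to the pixel rows)
  between the heart and the insert ring, whose oversampled line-spread
  function drives MTF estimation.

**Epoxy rod.**  A homogeneous cylinder (+30 HU) of the same diameter, used
only for noise and noise-power-spectrum (NPS) estimation.  Measuring noise
here rather than on the cardiac rod matters for strongly regularized IR
(see *Noise versus regularization strength* below).

Cylinders are rasterized with 3×3×3 subvoxel supersampling; boundary voxels
carry volume-weighted attenuation mixtures, which is what makes the
partial-volume behavior of Agatston scoring (blooming of dense inserts,
vanishing of faint ones) reproducible on a grid.  Ground-truth insert
volumes integrate these coverage fractions and converge to πr²h under grid
refinement.  Label masks assign whole voxels by majority coverage; inserts
smaller than a voxel still label the voxels on their axis so that
ground-truth masks are never empty.

**Attenuation model.**  Monoenergetic at 60 keV (water 0.0206 mm⁻¹, air 0);
HU = 1000·(μ−μw)/μw.  The source experiment never reports insert HU values,
so the CaHA calibration is a free parameter of the synthetic system: a
linear slope of 1.6 HU/(mg/cm³) puts the 100 mg/cm³ inserts partially below
the 130 HU scoring threshold (volume underestimation) and the 400 mg/cm³
inserts far above it (overestimation by blooming), the qualitative regime
the published score tables show.  Absolute score magnitudes are therefore
not a reproduction target; directional patterns are.

## Acquisition model

2D fan-beam, flat detector, full scan.  Source–detector distance 1953.0 mm,
isocenter–detector 133.8 mm (the bench geometry).  The forward operator
integrates attenuation along each source→channel ray by sampled bilinear
interpolation at half-voxel steps; the same sampling builds an explicit
sparse matrix (float32 CSR) used by the iterative solver and for adjoint
tests.  Against analytic chords of an anti-aliased disk the projector is
accurate to <0.5% away from grazing incidence.

Dose is a frame-averaging surrogate: the detector records 15 frames per
one-degree view (60 Hz at 4 deg/s); a dose level averages n ∈ [1, 15]
frames, with air kerma exactly proportional to n (0.098 … 1.475 mGy) and
per-ray counts Poisson with mean i0·exp(−line integral) per frame.  Frame
averages of 15/2/1 define the low-/clinical-/high-noise protocols
(LNP/CNP/HNP).  A zero-count guard floors mean counts at 0.5 before the
log.

**Fluence calibration.**  i0 is solved so that the FBP *quantum* noise at
15 frame averages equals 7.4 HU — the LNP definition.  Quantum noise is the
SD of (noisy − noiseless) reconstruction over the homogeneous background;
the difference isolates what the fluence controls from grid-discretization
artifacts, and on the study grid it coincides with the plain ROI SD to a
few percent.  The calibration uses the fixed-point update i0 ← i0·(SD/7.4)²
and converges in a handful of FBP evaluations.  With this single anchor the
CNP and HNP noise levels (≈19/27.5 HU) emerge from the 1/√n law rather
than being set independently.

**Desk-scale study conditions.**  128×128 grid at 0.75 mm (slices 1.5 mm,
six slices covering the inserts), 180 views, 256 detector channels covering
a 110-mm fan.  The channel count was chosen so that the coarse-grid system
preserves the 1/√frames FBP noise law (finer desk detectors introduce a
fixed ramp-aliasing pedestal on this grid that distorts the law by ~15%)
while keeping the sparse operator small enough for the full study on one
CPU.  A configuration with the physical 0.1-mm/1547-channel panel and
0.32-mm pixels exists (`FULL_GRID`, `FanBeamGeometry` defaults scaled) but
is not exercised by the default study.

## Reconstruction

**FBP.**  Standard equispaced fan-beam weighting: cosine pre-weight
D/√(D²+s²), ramp filtering along channels, distance-weighted (1/U²)
backprojection with linear detector interpolation, full-scan 1/2 factor.
The kernel is ramp × Hann × |sinc(W·f)| with W = 3.8 detector pixels — the
frequency-domain realization of the fractional-length moving-average filter
combined with a Hann window.  The ramp is defined with response(0) = 0; the
DC term a finite filter loses this way is controlled by 8× FFT
zero-padding, leaving a ≈1 HU bias on a water cylinder (acceptance band
±5 HU).

**Iterative reconstruction.**  argmin‖Au−f‖² + λR(u), zero initialization,
slice-by-slice in 2D, with two regularizers:

* smoothed TV: R(u) = Σ√(gx²+gy²+ε), ε = 1e−8, forward differences with
  replicate boundaries;
* gamma prior: R(u) = Σ P(α, β·g) with P the regularized lower incomplete
  gamma function, α = 1.2, β = 0.6; each pixel's gradient magnitude is
  mapped through the Gamma CDF, so small gradients are penalized ~linearly
  while large (edge) gradients saturate — interpolating between L1- and
  L0-like behavior.  The same ε smooths g so that the analytic gradient is
  the exact derivative of the computed value.

Both gradients are assembled as the chain rule through the forward
differences (weight 1/g for TV, pdf(g)/g for the gamma prior) and match
central finite differences to ~1e−10 relative on random images.

**Solver.**  Gradient descent with Barzilai–Borwein (BB1) steps:
t = (sᵀs)/(sᵀy), falling back to half the previous step when sᵀy ≤ 0 or
the step is non-finite; the first step comes from an exact quadratic line
search plus backtracking.  Pure BB is non-monotone and can transiently
diverge on this ill-conditioned problem, so steps are safeguarded by a
nonmonotone (moving-max over the last 10 objectives) backtracking rule —
the standard globalization of BB — which in testing eliminated rare
blow-ups without affecting normal steps.  Several slices and/or λ values
sharing the operator are solved simultaneously as columns of one batch in
single precision, which makes the sparse products the only hot spot.
Traces record the objective, step, and ‖u_k−u_{k−1}‖₂ per iteration; on the
benchmark the delta-L2 trace falls by >10³ between iterations 10 and 500.
The study uses 100 iterations — at these problem sizes the delta-L2 trace
has plateaued well before that — while 500 remains the config default.

## Regularization-strength selection

Candidate λ grids are 12 log-spaced values spanning three decades, anchored
where the fidelity gradient at the FBP solution balances the regularizer
gradient (residuals at the noise scale).  Absolute λ values are specific to
the data scaling of a given system and do not transfer.

* **Adaptive policy:** per dose level, pick the candidate whose single-
  slice reconstruction noise is closest to the 7.4 HU target.  Noisier data
  then selects larger λ, keeping noise roughly constant across dose.  On
  the desk system this is meaningful at reduced dose; at the LNP itself
  even weak regularization already pushes IR noise below 7.4 HU, so the
  LNP "adaptive" row of the λ table is reported but degenerate.
* **Fixed policy:** one weak/medium/strong triple for all dose levels.
  Medium is the candidate whose air-gap MTF is closest (least squares up to
  the FBP 10%-modulation frequency) to the reference-dose FBP MTF — the
  quantitative version of "visually matched".  Weak ≈ medium/3 and strong ≈
  4×medium, snapped to the grid, mirroring the ratio pattern of the
  original λ tables.

## Scoring

Clinical Agatston convention: volumes are slab-averaged to 3.0-mm scoring
slices; voxels ≥130 HU inside the scoring ROI form 8-connected per-slice
lesions; each contributes area × density factor (1/2/3/4 for 130/200/300/
400 HU lesion maxima); totals map to CAD grades (0 No CAD, ≤10 Minimal,
≤100 Mild, ≤400 Moderate, else Severe).  Calcium volume is the
supra-threshold voxel volume on the same slices.  Lesions are attributed to
the nearest ground-truth insert center, giving per-insert tables; the
scoring ROI is the rod interior minus a 3-pixel dilation of the air gap.
No minimum lesion area is imposed (configurable).  The vectorized scorer is
tested exactly against a per-pixel flood-fill oracle.

Reclassification rate = percent of inserts whose CAD grade differs from the
seed-matched LNP/FBP reference grade.

## Statistics

Nine inserts are the paired observations.  Wilcoxon signed-rank (two-sided,
zeros discarded, exact null for small tie-free samples; all-zero
differences give p = 1), Friedman across the three fixed strengths with
Bonferroni-corrected pairwise Wilcoxon post hocs (threshold 0.05/3 ≈
0.017), Pearson correlation, and Bland–Altman bias with 1.96·SD limits of
agreement.  These delegate to SciPy; the exact-enumeration behavior at
n = 9 is verified against a 2⁹ sign-pattern oracle in the tests.

## Noise versus regularization strength — what the synthetic system shows

Two desk-scale effects deserve explicit statement because they shape which
assertions the tests make.

**Measurement phantom.**  On the cardiac rod, the ROI standard deviation of
a strongly TV-regularized reconstruction is dominated by *deterministic*
shrinkage streaks (rod edge, inserts, air gap), not by noise: the noiseless
reconstruction reproduces most of the measured SD.  Noise-versus-λ behavior
is therefore evaluated on the epoxy rod, the study's own noise-texture
instrument, where no such structures exist.

**Dose level.**  At the LNP the quantum noise (7.4 HU) is removed by even
weak regularization, so the epoxy noise at medium/strong λ sits at a small
regularization floor and is no longer ordered by λ.  Where quantum noise
dominates — the CNP and HNP levels — epoxy noise is monotone
non-increasing from weak to strong for both regularizers, which is the
premise the study needs (and matches where the original experiment probes
noise behavior).  Score and volume monotonicity in λ holds at the
reference dose itself.

**Scores versus volumes at the matched strength.**  The headline finding —
the MTF-matched medium strength best reproduces the reference
quantification — appears sharply in the calcium *volume* error of the
400 mg/cm³, 3-mm insert for both regularizers.  For the Agatston *score*
the density-factor bins intervene at desk scale: the weak (sharper)
reconstruction raises the lesion maximum into a higher factor bin, which
compensates its smaller area and lands its score on the reference by
cancellation.  The acceptance test therefore asserts medium-best on the
volume error and medium-better-than-strong on the score error.

**Reclassification across dose.**  In the physical experiment the
reclassification rate grows as dose falls because faint lesions that are
detectable at the reference and clinical dose levels drop below the 130 HU
threshold at the highest noise.  At the desk resolution (0.75-mm pixels,
kernel-limited FBP) the faint lesions — the 100 mg/cm³ inserts and the
1.2-mm diameters — are already at or below threshold at the *reference*
dose, so that mechanism has nothing to act on.  What remains are
dose-independent systematic flips (medium-strength IR erases those same
faint lesions at every dose) and occasional single-pixel threshold
crossings in either direction, roughly one to two flips per 27
insert-comparisons.  The clinical-versus-high-noise ordering of the
reclassification rate is therefore not resolvable in this synthetic
system, and the corresponding study-level test documents this by failing;
the per-insert flip listing in the study outputs makes the mechanism
inspectable.

## Reproducibility and problem sizes

Every random draw descends from one integer seed through
`numpy.random.SeedSequence` spawning (per stage, dose level, slice and
repetition), so a study run is bit-reproducible from its configuration and
seed.  The default study (three dose levels × three noise realizations ×
{FBP, TV, GAMMA}, with weak/medium/strong at the reference dose and epoxy
noise benchmarks at every level) runs in roughly 7–8 minutes on one CPU;
the test suite's small benchmark (64×64 grid, 120 views, 192 channels)
keeps module-level properties to seconds.

## Limitations

* Monoenergetic forward model: no spectrum, beam hardening, scatter,
  detector cross-talk, charge sharing, or tile artifacts; air kerma is a
  label proportional to frame count, not a dosimetric simulation.
* 2D fan-beam slices; no cone-beam effects, cardiac motion, or torso
  attenuation.
* Absolute HU of CaHA, and hence absolute scores/volumes, are calibration
  choices, not measurements; only directional and ordering statements are
  claimed.
* The desk-scale detector/grid combination reproduces the dose-noise law
  and the regularization orderings, but its MTF and blooming magnitudes
  differ from the physical bench; per-insert tables are structurally, not
  numerically, comparable to the published ones.
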