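# Methods

This note documents the models behind `zharmon`: what is simulated, which
parameters matter, the numerical choices, and what the synthetic study can
and cannot say about real scanners.

## Digital phantoms

All objects live on one common grid (default 64×64×64 voxels, 3.5 mm
isotropic) inside a shared ellipsoidal "head" support occupying ≈22% of the
grid. Generating every volume pre-aligned on this grid replaces the
anatomical-standardization step of a clinical pipeline; registration error
is therefore outside the scope of the simulation.

* **Hoffman-style phantom** — interleaved gray/white laminae, 2 voxels
  (7 mm) thick, stacked axially, with a central white core; gray activity is
  4× white (the conventional design contrast of layered brain phantoms).
  Uniform soft-tissue attenuation μ = 0.1 cm⁻¹ inside the support. The
  physical phantom's slice-plate anatomy is not reproduced; only the
  gray/white contrast, laminar structure and support geometry matter to the
  analyses downstream.
* **3D-brain-style phantom** — same laminar brain, plus a closed
  bone-equivalent skull shell (μ = 0.15 cm⁻¹ by default; the soft/bone
  excess is configurable) with zero activity, and — by default — no tracer
  in white matter, mirroring an anatomical phantom whose white compartment
  cannot be filled.
* **Pool phantom** — uniform fill over the same support; no internal
  structure.
* **Normal-brain base** (the subjects' ground truth) — the same laminar
  geometry at physiological 2:1 contrast, an outer cortical-shell weighting
  (+50% over the outer quarter of the support radius) that no plate phantom
  has, smoothed 4 mm. The construction encodes the premise of phantom-based
  harmonization: a real brain's count distribution lies closer to the
  layered phantom than to the structureless pool, while matching neither.
* **Cohorts** — subject *i* = base × (log-normal global scalar, CV 0.08) ×
  (smooth multiplicative field: Gaussian-smoothed log-noise, correlation
  length 20 mm, pointwise CV 0.05, unit mean). Log-space construction keeps
  activity positive; the two CVs are typical of inter-subject global-uptake
  and regional variability in perfusion SPECT. Every generator is a pure
  function of its parameters and seed.
* **Lesion operator** — multiplies activity/counts by (1 − f) inside a
  disease VOI; the dementia simulation uses f = 0.2 (a 20% count decrease)
  in a posterior VOI (the "occipital" sector of the synthetic atlas).

## Camera model

Acquisition is simulated directly in reconstruction domain:

```
activity × attenuation factor × sensitivity
  → Gaussian PSF blur → scale to count budget → Poisson
  → 3-D Butterworth post-filter → optional first-order Chang correction
```

No projection/FBP step is modelled: every evaluated quantity operates on
reconstructed, aligned volumes, so projection-domain fidelity would add cost
without touching any measured number. Consequences of this choice: noise is
Poisson in image space rather than projection space, and scatter, septal
penetration and energy-window effects are absent (they are abstracted, with
collimator/detector non-uniformity, into a smooth radial sensitivity field).

* **Attenuation factor** — per voxel, the mean over a direction set of
  exp(−∫μ dl) along rays to the volume boundary; default six axis-aligned
  rays (a cheap mean-path rule), computed by exact cumulative sums; oblique
  rays fall back to half-voxel-step marching with nearest sampling.
* **Chang correction** — division by the same factor computed from a
  uniform assumed μ (0.1 cm⁻¹) over the body contour, clamped below 1e−3.
  Attenuating and correcting with matching μ and directions cancels exactly.
* **Butterworth filter** — frequency-domain gain 1/√(1+(f/f_c)^(2n)),
  radial f in cycles/cm, DC gain exactly 1; order 8 by default (a typical
  clinical reconstruction order).
* **Two default cameras** — reference "ecam": 8 mm PSF, cut-off 0.45 ×
  Nyquist (0.643 cycles/cm at 3.5 mm voxels), flat sensitivity; target
  "irix": 10 mm PSF, cut-off 0.75 cycles/cm, radial sensitivity −5% centre
  to +5% periphery. The cut-offs approximately equalize the two chains' net
  resolution, as in a matched-resolution protocol; the exact achieved FWHMs
  are configuration values, not calibrated against any physical camera.
* **Count budgets** — 5×10⁶ expected counts per subject scan (typical for
  brain perfusion SPECT). Phantom calibration scans use 5×10⁷: a filled
  phantom (0.3 MBq/ml over the whole support) holds roughly an order of
  magnitude more in-field activity than the few-percent brain uptake of a
  patient injection, under the same acquisition protocol. `None` is the
  noise-free sentinel.

## Harmonization

A compensation map is reference-mean / target-mean over repeated scans of
one object (three per camera for phantoms; the whole cohort's scans for the
normal-subject source). Voxels where either mean falls below 5% of its
support mean are excluded and carry the neutral ratio 1 — this floor is the
totality guarantee against near-zero denominators. Optional Gaussian
smoothing of both means before the ratio exists but defaults to off, so the
correction multiplies every voxel as measured. A map is directional; the
inverse map (1/ratio on the valid mask) is a derived accessor.

## NDB and Z-scoring

Preprocessing is smoothing (12 mm FWHM, a conventional statistical-mapping
choice) followed by proportional scaling of the brain-mask mean to 50.
Cerebellar or reference-region normalization is not implemented. The NDB
stores the voxel-wise mean and sample SD (n−1); the SD is floored at 0.1 ×
its mask-wide mean so Z-scores stay finite at low-variance voxels, with an
absolute fallback floor for numerically degenerate cohorts. Z maps use
positive = count decrease; a display threshold (|z| < 1.5 zeroed) is
provided for map reading and does not enter the SVA indices, which use their
own z ≥ 2 threshold.

## Evaluation

* **Difference maps** — voxel-wise pooled-variance two-sample t between the
  reference-camera cohort and a corrected cohort (both preprocessed), one
  one-sided mask per direction at uncorrected p < 0.05, clusters below 50
  voxels removed at 26-connectivity (6/18/26 configurable). Pooled variance
  matches the equal-variance GLM behind conventional mapping software;
  connectivity and the height/extent values are configuration.
* **Central/marginal partition** — the brain mask split at the median
  radial distance from its centroid (quantile configurable). A reproducible
  geometric rule replaces the interactive image-tool partition such studies
  draw by hand; only the partition's role — deep vs peripheral summaries —
  is reproduced.
* **Region correlations** — Pearson r of corrected vs reference counts per
  region of a six-region lobe-level atlas. The packaged atlas is a
  deterministic concentric/sector partition (frontal, occipital, temporal,
  anterior, sub-lobar + whole brain) standing in for an anatomical labelling
  scheme; any integer label volume on the grid is accepted.
* **SVA indices** — Severity = mean z over VOI voxels with z ≥ 2 (0 if
  none); Extent = % of VOI voxels with z ≥ 2; Ratio = VOI suprathreshold
  fraction divided by whole-brain suprathreshold fraction (dimensionless;
  a percentage rendering is exposed as well), guarded to 0 when the
  whole-brain fraction is 0.

## The end-to-end experiment

`run_experiment` acquires every subject on the reference camera (AC+), the
target camera (AC+), and the target camera without attenuation correction
(AC− — the arm that deliberately exaggerates the camera difference); builds
AC+/AC− and AC+/AC+ compensation maps from all four sources; and evaluates
corrections by difference maps and Z summaries (AC− arm, against the
reference NDB), region correlations (AC+ arm, as in the clinical
comparison), and SVA indices of a lesioned held-out subject. All analysed
volumes pass through the same smooth-and-normalize chain as the NDB cohort.
One root seed drives a per-stage seed stream; reruns of one config write
byte-identical CSVs. The default problem size (64³, 20 subjects, 3 phantom
scans per camera) completes in tens of seconds.

## Numerical choices and degenerate inputs

Seeded `numpy.random.Generator` everywhere; FWHM→σ via 2.3548; attenuation
factors cached per (μ-grid, voxel, directions); acquisition output clipped
at 0 after filtering (the Butterworth can ring slightly negative); empty
lesion VOIs warn and return the input; empty region masks, sub-minimum
cohorts, non-overlapping supports and out-of-range parameters raise
`ValueError`.

## What passing tests do and do not show

The generator reproduces the *structure* of the study — two cameras
differing in PSF, filter and sensitivity; calibration objects of graded
similarity to the subjects; Poisson counting statistics; a cohort with
realistic global and regional variability. It omits scatter, septal
penetration, energy-window differences, projection-space noise, anatomical
standardization error and real cortical anatomy. Results therefore speak to
the linear reconstruction-domain mechanism of count-ratio harmonization:
the spatially matched normal-subject source corrects best, and a
structurally mismatched calibration object can make a matched-resolution
pair of cameras *worse* than no correction. One finding differs from what
object-distribution-dependent physics produces on real hardware: with only
linear blur/sensitivity differences, the structureless pool map is
near-neutral and can outperform the layered phantom's map, whose stronger
contrast over-corrects the smoother brain; on real cameras, scatter and
collimator response penalize the pool's unrepresentative count distribution.
This boundary of the model is deliberate (see the non-goals above) and is
visible in the experiment's ranking tables.
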