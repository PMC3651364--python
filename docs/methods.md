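# Methods

`spiralpvm` simulates and analyzes retrospectively gated, three-directional
myocardial phase velocity mapping (PVM) of short-axis left-ventricular (LV)
slices. Because no raw scans are distributed, a ground-truthed digital
phantom stands in for the volunteer acquisitions; every analysis stage then
operates exactly as it would on real data: phase-difference velocity
reconstruction, retrospective gating to 60 cardiac phases, stationary-phantom
background correction, cylindrical/regional decomposition, peak and
time-to-peak (TTP) quantification, cardiac-phase normalization for cohort
averaging, and inter-study reproducibility statistics.

## Acquisition model

The simulated sequence follows a 13-interleave spiral protocol: velocity
sensitivities (venc) of 30 cm/s through-plane and 20 cm/s in-plane, 21 ms
acquired temporal resolution, a 360 mm field of view on a 256×256 matrix
(1.4 mm pixels, zero-fillable to 0.7 mm), 8 mm slice thickness, and a 5 mm
navigator acceptance window. Reference and three velocity-encoded datasets
acquired on consecutive cycles plus one dummy cycle give 53 cardiac cycles
per slice. Velocity maps into image phase linearly, φ = π·v/venc (the
standard bipolar-gradient convention; φ = π at venc).

## The moving-annulus phantom

The myocardium is a circular annulus (endocardial radius 20 mm, epicardial
30 mm at end-diastole; ≥7 pixels across the wall at acquired resolution)
whose surfaces move with the integrated radial velocity of their layer. The
velocity field is separable, v(θ, d, t) = g(t) · m(θ) · h(d):

- **g(t)** — per-direction global profiles built from bump trains carrying
  the named peaks of healthy LV motion: systolic (S), early-diastolic (D)
  and atrial-systolic (AS) peaks longitudinally and radially; a biphasic
  early-systolic pair (C1, C2) and an early-diastolic peak (C3,
  sign-opposed between base and apex — ventricular untwisting)
  circumferentially. Default amplitudes and timings are the healthy-cohort
  means for the chosen slice level. The radial profile additionally carries
  an end-systolic notch (−0.75 cm/s, σ 20 ms) — the "first negative radial
  peak" that defines the length of systole — and a small positive
  isovolumic-relaxation rebound (+0.55 cm/s, σ 18 ms), together forming the
  biphasic early-diastolic radial pattern reported in healthy subjects.
- **m(θ)** — cosine regional modulation (±30% by default), phased so the
  lateral wall dominates longitudinal peaks and the inferolateral wall the
  radial atrial peak.
- **h(d)** — a linear transmural gradient for radial velocity
  (endo 1.16 → epi 0.88 of mid-wall), matching the reported ordering of
  endocardial > mid-wall > epicardial radial peaks.

### Waveform shape

Named peaks are generalized-Gaussian bumps `A·exp(−|Δt/w|³/2)` with
w = 42 ms. The exponent-3 shape is a deliberate compromise: the acquired
21 ms sampling followed by linear retrospective interpolation onto the 60
reconstructed phases applies two chained linear interpolations whose
worst-case amplitude loss for a peak of curvature scale σ is roughly
(Δt²_acq + Δt²_recon)/2σ² at adversarial grid alignment; a mildly
flat-topped bump keeps that loss below ~3% while retaining enough top
curvature to localize the peak time to a few ms. The radial E-wave alone is
exponent 4 (flat top, compact flanks, w = 36 ms) so that its early flank
cannot bury the end-systolic notch at short RR intervals. The systolic S
bumps are Gaussians whose widths are solved so each longitudinal/radial
profile integrates to zero over the cycle (periodic motion, and periodic
contours); the circumferential C2 plays the same balancing role with its
width clipped to 45–90 ms, leaving a small residual cycle mean (≤0.05 cm/s
at default amplitudes). Physiologic ordering constraints keep the waveform
analyzable at every heart rate: C1 ≥ 30 ms after the R-wave, the E-wave at
least ~95 ms (width-scaled) after end systole (isovolumic relaxation), and
the atrial peak within 87% of diastole (no fusion with the next beat's
ejection).

### Timing across heart rates

Canonical timings are expressed on a 1000 ms cycle with end systole at
349 ms. For a subject with RR interval R and end-systolic time T, systolic
times scale by T/349 and diastolic times map affinely onto [T, R] — i.e.
section-relative timing is preserved, which is exactly the physiology that
fixed-length TTP normalization exploits. Bump widths scale with their
section but never widen beyond canonical and never shrink below 85% (so
tails stay inside their sections at long RR and peaks remain resolvable at
short RR).

### Between-subject variability

Per subject (seeded): RR ~ N(994, 60) ms clipped to [813, 1226]; end
systole ~ N(349, 25) ms; one common amplitude factor per direction
(sd 10%) plus independent per-peak perturbations (sd 4%); systolic and
diastolic timing shifts shared across the three directions (the ejection,
E-wave and atrial events move coherently) plus small per-peak jitter. The
common-mode structure keeps the solved balancer widths stable and keeps
the marker windows derived from the radial curve valid for the other
directions.

### Encoding, background and noise

Phase sets (reference, x, y, z) each carry a distinct second-order 2-D
polynomial background field (coefficients ~ N(0, 0.08 rad), chosen so
*uncorrected* global mean velocities are of order 0.5 cm/s, the magnitude
reported for uncorrected in vivo data), plus independent Gaussian phase
noise (default sd 0.05 rad), wrapped to [−π, π). The magnitude image
emulates a black-blood acquisition (myocardium 1.0, blood pool 0.1,
air 0). A stationary-phantom series shares the background model with zero
velocity. A per-cycle diaphragm trace (slow sinusoid + drift + noise)
feeds the dual-navigator acceptance rule: a cycle is kept only when the
navigators immediately before and after it fall within the window; the
final cycle, lacking a following navigator, is rejected.

## Reconstruction

Velocities are recovered per component as venc·wrap(φ_enc − φ_ref)/π with
no phase unwrapping (healthy myocardial velocities stay below venc; a
near-venc value logs a warning). Retrospective gating interpolates
linearly, per pixel, onto 60 equally spaced phases t_k = k·RR/60, closing
the cycle across the R-wave. Background correction subtracts a
median-filtered stationary-phantom velocity map pixel by pixel; the median
filter is 5×5 spatially and, in the pipeline default, taken across the
whole time axis as well — the phantom is stationary, so its frames differ
only by noise, and a per-frame median leaves spatially correlated noise
that would otherwise dominate the regional curve noise budget (the
per-frame variant remains the function default and is configurable).

The spiral module provides the standalone reconstruction machinery the
acquisition model presumes: an idealized Archimedean interleaf set sampled
uniformly in arc length out to k_max = matrix/(2·FOV), with
matrix/(2·n_interleaves) turns per interleave so adjacent arms sit 1/FOV
apart (full sampling); an exact direct-DFT forward/adjoint oracle; and
Kaiser–Bessel convolution gridding (width 4, 2× oversampling, Beatty β)
with Pipe–Menon-style iterative density compensation. The gridding
operator is normalized against the analytic spiral samples of a constant
image rather than an impulse: the unsampled corners of k-space make the
point-spread peak ~π/4 of the DC gain, so impulse calibration would
overestimate extended objects by ~27%. Note that an ideal reconstruction
of a hard-edged disc from circular k-space support has NRMSE ≈ 0.10
against the discrete phantom (Gibbs ringing of the test object itself);
operator fidelity is therefore assessed on a raised-cosine-edged disc
(NRMSE 0.017 at 13 interleaves, degrading monotonically for 6 and 3).

## Geometry and regional decomposition

Contours are closed polygons rasterized by pixel-centre point-in-polygon
membership; the per-frame centre of mass is the unweighted mean of the
binary myocardial mask. The polar axis runs from the centre of mass to the
anterior LV–RV junction landmark, with θ increasing from anterior toward
the lateral wall. Velocities resolve into longitudinal (+vz, toward apex),
radial (positive toward the centre) and circumferential (positive
clockwise viewed from the apex). Angular segmentation uses half-open bins
from θ = 0: six 60° AHA segments at base and mid (anterior, anterolateral,
inferolateral, inferior, inferoseptal, anteroseptal), four 90° segments
apically, and a 24 × 15° scheme for colour maps. Transmural depth is
assigned by the nearest of 360 equally spaced endo→epi rays (radius as a
function of angle interpolated from the polygon vertices; valid for
star-shaped contours) and split into thirds. Region curves are unweighted
pixel means per frame.

The pipeline erodes the analysis mask by one pixel before averaging
(configurable). Reconstructed phases are blends of two acquired frames
whose myocardial masks differ by the wall motion (up to ~0.7 mm per frame
at peak filling), so un-guarded edge pixels mix in zero-velocity blood or
background and dilute peak amplitudes by ~3%; the guard removes this
partial-volume effect, as is common practice when sampling myocardial
velocities near contours.

## Curve analysis

End systole is the first local minimum of the (optionally smoothed) global
radial curve after the systolic maximum whose value reaches below 10% of
the curve's peak magnitude (the depth test rejects noise dips near the
zero crossing). Diastasis onset is the first time after the E-wave peak at
which |v_R| falls below 25% of the E-wave amplitude for two consecutive
phases; atrial-systole onset is the last local minimum of |v_R| before the
atrial peak (falling back to a configurable fraction of diastole, flagged,
when no atrial peak exists). Peaks are windowed extrema with the signs
above; a peak is absent when it fails to exceed a noise floor of 3× the
standard deviation of the linearly detrended second half of the diastasis
window (the first half may still carry the decaying E-wave tail). Apical
C2 may take either sign; C3 is not reported for global mid-slice curves.
Detected extrema are refined by a three-point parabolic fit, the standard
sub-sample peak estimator, which recovers most of the amplitude the
piecewise-linear reconstruction chain withholds at the grid extremum. The
pipeline detects markers and peaks on unsmoothed regional curves (their
noise after regional averaging is ~0.02–0.03 cm/s, while a 3-frame moving
average erases the end-systolic notch at reconstructed resolution); the
module-level default remains a 3-frame window.

TTP values are reported from the R-wave in ms, as a percentage of systole
(100·t/T) or diastole (100·(t−T)/(R−T)), and converted to a fixed-length
cycle using population-average section lengths of 350 ms (systole) and
650 ms (diastole); conversions are computed in decimal arithmetic and
rounded half-away-from-zero to one decimal so printed-precision inputs
reproduce printed tables. For paired differences the diastolic offset
cancels, leaving the affine slopes 3.5 and 6.5 ms per percentage point.
E/A is |D|/|AS| per subject, averaged as a mean of ratios.

## Cohort maps and reproducibility

Before averaging across subjects, each curve is warped onto a fixed phase
template in four sections — systole, early diastole, diastasis, atrial
systole (350/150/300/200 ms by default; the 350/650 split is the
population average, the split of diastole is a configurable choice) — with
a piecewise-linear monotone time map and shape-preserving cubic (PCHIP)
resampling; section-boundary values are preserved exactly and a plain
cubic spline is available via configuration. The 24-segment normalized
curves averaged over subjects form a segments × time colour grid (anterior
at top, proceeding to lateral, inferior and septal), with a symmetric
colour scale per direction and the three interior section boundaries
marked.

Inter-study reproducibility is the mean ± SD (n−1) of day2 − day1 signed
differences per parameter, with Bland–Altman bias ± 2 SD limits.
Fixed-length TTP differences derive from the percent differences through
the affine rule. On two-visit synthetic cohorts whose RR changes between
days while section-relative timing is fixed, the SD of fixed-length TTP
differences falls far below the raw-ms SD for the diastolic and atrial
peaks (e.g. ~140 → ~7 ms for the atrial-systolic longitudinal TTP at
±200 ms RR changes), reproducing the rationale for normalized timing.

## Problem sizes and defaults used in tests

The test suite and acceptance script run the mid-slice cohort: 10 subjects,
two visits, 128×128 grid at 1.40625 mm (90 mm half-FOV comfortably holds
the annulus; the wall still spans ≥7 acquired pixels), ~47 acquired frames
interpolated to 60 phases. Unit tests use 64×64 grids and 32×32 gridding
phantoms. All randomness flows from one root seed through spawned seed
sequences; reruns are bit-identical.

## What the phantom does and does not capture

Passing tests demonstrate that the analysis chain recovers prescribed
kinematics through a realistic encoding/reconstruction path: linear phase
encoding with smooth background fields and Gaussian phase noise, finite
temporal sampling with retrospective interpolation, moving contours,
regional and transmural heterogeneity, heart-rate variation within and
between visits. They do not certify performance against effects the
phantom omits: off-resonance blurring and other spiral artefacts, eddy
currents beyond a static polynomial phase, through-plane motion of the
imaged slice, trabeculated or non-circular anatomy, contouring error
(contours here are exact), flowing blood signal, or coil sensitivity
structure. Reported in vivo peak velocities and navigator efficiency are
used only to calibrate the generator; they are not reproducible from
simulation.

## Known limitations

- The annulus is circular and star-shaped by construction; the geometry
  code assumes star-shaped contours about the centre of mass.
- The end-systole detector needs a discernible notch; the generator
  guarantees one, but pathological curves without it raise an error by
  design ("curve not analyzable").
- Apical global C2 is small (0.39 cm/s prescribed); with default noise its
  detected amplitude is near the reliability limit, as in vivo.
- One further printed-table inconsistency exists in the source cohort data
  for the mid-slice atrial radial TTP reproducibility (the percent value
  −0.46 and the fixed-length value 3.0 ms disagree in sign under the
  affine rule, which gives −3.0 ms); the affine conversion implemented
  here is self-consistent and that entry is not used as a reference.
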