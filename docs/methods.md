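# Methods

This note records the models, parameter choices and numerical decisions
behind `cardiodic`, in the spirit of a methods appendix: enough detail to
reproduce or challenge any number the package computes.

## Subset correlation

**Criterion.** Matching minimizes the zero-normalized SSD (equivalent, at
the optimum, to maximizing ZNCC). The criterion is exactly invariant to
affine lighting changes — relevant under surgical lighting, where gain and
offset drift between frames. The reported quality is the ZNCC of the
converged warp, clipped to [−1, 1].

**Shape function.** First-order (affine) subset warps. At the default
step of 10 px and subset sizes of 31–79 px, the within-subset curvature of
cardiac surface motion is far below the matching noise floor, so a
second-order shape function would add parameters without accuracy.

**Optimizer.** Inverse-compositional Gauss–Newton: the Hessian is built
once per reference subset from the reference-image gradients, and each
iteration only re-samples the deformed image. Convergence is declared when
the parameter-update norm (gradient terms scaled by the subset half-width)
drops below 1e-4 px, with at most 50 iterations. When no seed is
available, an integer-pixel ZNCC template search (±10 px window,
`skimage.feature.match_template`) initializes the optimization.

**Interpolation.** Cubic B-splines for both intensities and gradients
(prefiltered once per image; exact at integer pixel coordinates). Bicubic
reproduces linear intensity ramps exactly away from the border; the
prefilter's mirror boundary leaves residuals of order 1e-7 within ~10 px
of an edge, far below the ~0.01 px tracking noise floor. Quintic
interpolation was rejected as unnecessary for 0.05 px accuracy targets.

**Sequence accumulation.** The default mode correlates each consecutive
frame pair directly, with the reference subset re-extracted at the
tracked (generally non-integer) position, and sums the increments. Errors
therefore accumulate as a random walk along the chain; the alternative
`to_reference` mode correlates every frame against frame 0 seeded by the
incremental estimate, and the two modes agreeing at the end of a sequence
is used as an internal consistency check. Per-beat analysis plus
stitching (each beat offset by the accumulated end displacement of its
predecessors) bounds the chain length when long recordings are processed.

**Robustness.** A converged match with ZNCC below 0.7 is treated as a
false optimum: with this pattern and noise model genuine matches score
above ~0.9, while locks onto a neighboring speckle cluster score 0.3–0.7.
Such points are re-seeded from the median increment of converged
neighbors within 3 grid steps, then, if still failing, rescued by an
integer search whose window grows with the seed magnitude (fast
early-diastolic recoil reaches ~20 px/frame at the ROI edge under the
benchmark's default intraoperative-scale kinematics). Points that remain unmatched are
masked invalid — never filled with numbers — and a frame pair losing more
than half its points aborts tracking loudly. Coordinates follow the image
convention: pixel centres at integers, origin top-left, x rightward,
y downward.

## Stereo geometry

Cameras are plain 3×4 pinhole projections without lens distortion: the
validation is synthetic and distortion-free, and a radial-distortion hook
can be applied to pixel coordinates before calibration if real optics
demand it. Calibration is a normalized DLT from ≥ 6 non-coplanar target
points followed by Levenberg–Marquardt refinement of the reprojection
error; a single rigid target does not warrant bundle adjustment. The
calibration error is the RMS of the per-point reprojection residual norms
— with isotropic noise σ per pixel axis this statistic concentrates near
σ·√2·√(1 − 11/2N), about 0.12 px for σ = 0.1 px and N = 20 points.
Triangulation is the homogeneous linear (DLT) intersection with the mean
two-view reprojection residual attached; near-parallel rays are detected
through the homogeneous solution's vanishing last coordinate and raised
as errors. Cross-camera correspondence runs once on the reference frames
(integer search plus subpixel refinement); temporal tracking stays
per-camera, which is cheaper and keeps the two image chains independent
until triangulation. The world frame is the calibration target's; all
millimetre outputs live in it.

## Synthetic benchmark

The generator emulates the intraoperative scene: a fronto-parallel or
stereo-viewed plane patch carrying dark marker dots on a light background
(dots ~0.3 mm radius, 2 per mm², 1 px anti-aliased edges, Gaussian blur
σ = 0.8 px, additive sensor noise σ = 2 grey levels at 8 bit). Frames are
rendered by inverse-mapping each pixel through the motion model and
sampling one reference raster bicubically, so the imposed displacement is
exact at every pixel centre and the ground truth carries no rendering
error of its own.

The motion model composes, per material point X:

* **contraction** — an affine scaling about a centre X_c with per-axis
  multipliers (a_x, a_y) on the amplitude a: in-plane stretch
  s_i(t) = 1 + a_i (c(t) − 1);
* **cardiac waveform** — c(t) = 1 − a·r(t) with a piecewise-cosine unit
  ramp r(t): systolic rise over a fraction f_s of the beat, early
  diastolic recovery of a fraction r_e of the amplitude over f_e, a
  diastasis plateau, and an atrial kick returning to baseline over the
  final fraction f_a. The phase structure yields the clinical E and A
  waves, so TVe/TVa and SRe/SRa detection is genuinely exercised. The
  atrial-kick duration f_a is an explicit parameter (default 0.15)
  because the plateau length is otherwise undefined;
* **rigid translation** — T·r(t) in-plane and out-of-plane (the
  out-of-plane term moves the whole plane along world Z, which the stereo
  rig sees as a magnification change); an optional rotation R(t) applied
  to the translation vector defaults to identity;
* **respiration** — the entire displacement amplitude is modulated by
  1 + d·sin(2π f_resp t) (default depth 0.05 at 12 breaths/min), which
  reproduces the beat-to-beat amplitude variation seen in vivo.

Since the in-plane map is affine, the Green–Lagrange tensor is spatially
constant and known in closed form, as is the extensometer length
(translation and uniform out-of-plane motion cancel in point
differences). Defaults are sized to the intraoperative regime: a
2055×1788 px frame at 0.1 mm/px, 15–20 Hz, ~5 beats at 60 bpm,
a = 0.2 with anisotropy (1.0, 0.8) and translation (16, −10, 10) mm,
which yields ROI-mean peak |u| ≈ 25 mm, component peaks of roughly
(17, −10, 10) mm, tissue velocities of about ±10 cm/s and 20% peak
extensometer shortening — the magnitudes reported for this kind of
measurement. Desk-scale validation uses 256–512 px crops of the same
model with translations scaled to the smaller field of view.

What the generator does **not** emulate: surface curvature (the patch is
a plane, so triangulated shape is trivial), specular wet-tissue
highlights and their motion, the epicardial fat layer's independent
mechanics, spatially heterogeneous (non-affine) myocardial strain, ECG
timing, and camera defects (distortion, rolling shutter, defocus).
Passing the benchmark therefore demonstrates the correctness and noise
behavior of the estimation chain, not robustness to every property of
real intraoperative footage.

## Cardiac metrics

**ROI statistics** average valid points only; V_l is the mean of
per-point vector lengths (not the length of the mean vector), and the
dispersion attached to every trace sample is the spatial standard
deviation across the ROI. A frame with fewer than 25% valid ROI points is
reported missing (NaN), never imputed.

**Beat segmentation** finds local minima of V_l — the maximally dilated
state, where the surface is nearest its reference configuration — with
prominence at least 30% of the trace range and separation at least 0.4 s.
Only intervals between two detected minima count, so partial first/last
beats are excluded. The method is deliberately parameter-light; manual
interval override is available through the analysis configuration.

**Derivatives** (tissue velocity, strain rate) apply local quadratic
(Savitzky–Golay) smoothing with a default window of 5 samples before
central differencing — the smallest window that stabilizes ±1-frame
extremum detection at 15–20 Hz sampling. Velocity is the signed d|V|/dt
in cm/s (positive while the surface moves away from its reference).

**Characteristic points.** Per beat, TVs is the positive velocity
extremum, TVe the negative extremum, and TVa the most negative interior
local minimum between TVe and the next TVs; local minima are detected on
the full trace so an atrial dip adjacent to a beat boundary is not lost.
SRs is the negative strain-rate extremum, SRe/SRa the first and second
positive maxima; a rising positive final sample counts as an SRa
candidate because the atrial ramp ends exactly at the beat boundary.
A missing point (e.g. no atrial kick when r_e = 1) is reported as absent,
never invented.

**Strain.** The displacement gradient comes from a least-squares plane
fit over a 5×5-point lattice window (rank-deficient neighborhoods are
flagged invalid); E = (FᵀF − I)/2; reported principal strains are
(√(1+2e_i) − 1)·100 — finite-strain correct at the 100%+ magnitudes a
beating surface reaches and exactly rotation-invariant. The reference
state defaults to the sequence's first frame; a per-beat end-systole
reference is a configuration switch. The extensometer interpolates
endpoint displacements by inverse-distance weighting of grid points
within 2.5 steps (at least 3 valid supports required), works in 3D when
the field is triangulated, and FS normalizes by the per-beat maximum
length so FS ∈ [0, 100) and touches 0 in every beat.

## Validation problem sizes

The test-suite and acceptance-script runs use: 256×256 images
(subset 31, step 10, ~200 points) for shift-recovery, lighting-invariance
and drift checks; a 100-frame 512×512 stereo pair at 17 Hz (subset 31,
step 16, 289 points per camera) for end-to-end parameter recovery; and a
150-frame 256×256 single-camera run (11+ beats at 75 bpm, 15 Hz) for
repeatability. These sizes hold the full validation to a few minutes on
one CPU while keeping every per-beat statistic estimable; the generator
renders the full 2055×1788 geometry with the same code when asked.

## Known limitations

* The affine ground-truth motion cannot probe spatially heterogeneous
  strain recovery; the strain window (5×5 points) trades noise for
  spatial resolution on real, non-affine fields.
* Commercial stereo-DIC packages use proprietary criteria, shape
  functions and seeding; numerical equivalence with them cannot be
  asserted — only agreement with analytic ground truth.
* Tissue velocity is defined as the signed rate of change of the
  displacement-vector length; a projected "toward-the-apex" component
  would need an anatomical axis the optical data alone does not define.
* Lens distortion is not estimated; with distorted real optics the
  pinhole model biases triangulation until a distortion correction is
  applied upstream.
* Beat segmentation assumes V_l returns near its reference level every
  diastole; strong baseline drift (surgical manipulation) would need the
  manual interval override.
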