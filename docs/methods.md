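# Methods

## The measurement model

A projector casts a vertical sinusoidal fringe field of period `p`
pixels onto the scene; a camera observes it from a different direction.
Surface height displaces the observed fringes, so the absolute fringe
phase at a camera pixel encodes the depth along that pixel's viewing
ray.  The simulator uses the crossed-optical-axes approximation

    phi(r, c) = 2*pi*c / p  +  z(r, c) / S

with `S` the sensitivity in mm of depth per radian.  This keeps the
ground-truth phase analytic for every rendered scene.  Full projective
geometry is exercised separately through the pinhole camera model used
for board rendering and metric reconstruction; the per-pixel
phase-to-depth relation there is exactly linear by construction, which
is what the polynomial phase calibration must (and does) recover.

A single frame cannot disambiguate the 2*pi fringe order, so the
pattern carries one *marker* fringe whose amplitude is modulated along
its length (transversely to the fringe direction) at a period distinct
from the carrier.  The marker's projector-side fringe index `N` is
known; locating the marker in the image anchors the unwrapped phase to
an absolute one.

### Marker waveform

The modulation is multiplicative on the fringe amplitude: depth 0.5,
modulation period `4*p` along the fringe, confined across the fringes
by a raised-cosine envelope of half-width 1.5 periods centred on the
intensity crest at column `N*p`.  Two properties motivated this design,
fixed before the validation experiments were frozen:

* the envelope centre at the crest makes the median marker phase equal
  `2*pi*N`, so the phase-shift rule
  `Phi_x = 2*pi*(N - floor((median + pi)/(2*pi)))` lands exactly on the
  fringe order;
* a C1-smooth, gradual roll-off (emulating projector defocus) keeps the
  spatial-carrier phase estimator essentially unbiased inside the
  marker band (residual ~4e-4 rad, versus ~6e-3 rad for a one-period
  hard-edged band), which matters once phase errors are multiplied by
  the mm-per-radian sensitivity.

## Per-pixel maps

* **Object mask `Om`** — overexposed pixels (>= 0.98 of the dynamic
  range by default) are removed, an Otsu threshold (or an explicit
  absolute threshold; needed when the object legitimately contains dark
  albedo, e.g. board markers) separates object from background,
  a morphological closing with radius 0.6 fringe periods bridges the
  dark fringe troughs into a solid region, and the largest connected
  segment is kept.
* **Period `Pm`** — per row, the intensity is binarized at its local
  median (window 1.5 periods); the span from the last threshold
  crossing at or before the pixel to the second one after it is one
  full above/below cycle.  Crossings are sub-pixel (linear
  interpolation).  Pixels whose neighbourhood lacks a full cycle, whose
  amplitude is below a floor, or whose estimate would rely on
  border-replicated samples are invalid.
* **Amplitude `Am`** — local max minus local min over the same window.
* **Stability `Sm`** — windowed variance of `Pm` along the fringe
  normal over one local period, mapped to [0, 1] as `1 - var/var_max`.
* **Wrapped phase `Wm`** — seven samples along the fringe normal at
  spacing `Pm/4` (nominal pi/2 steps), linearly interpolated, combined
  with the symmetric seven-sample estimator
  `tan(phi) = (-I_-3 + 7 I_-1 - 7 I_+1 + I_+3) /
  (-4 I_-2 + 8 I_0 - 4 I_+2)` — exact on an integer-period sinusoid and
  second-order insensitive to a misestimated period.  Linear
  interpolation is part of the method's definition and sets the
  noise-free accuracy floor (~1e-3 rad at non-integer local periods).
* **Verticality `Vm`** — windowed sums of absolute row-/column-wise
  intensity differences with window = local period;
  `Vm = gradH / (gradH + gradV)`, 0 when both vanish.  (The published
  description of this map contains a typeset duplication in its
  formula block; the quotient form above is the stated intent and is
  transpose-symmetric and bounded in [0, 1].)
* **Border `Bm`** — normalized box blur of the mask, width two fringe
  periods: 1 deep inside, ~0.5 on the boundary.
* **Quality `Qm`** — weighted arithmetic mean of powers of the four
  normalized maps with defaults `bw=1, aw=5, vw=3, sw=1` and
  `be=1, ae=2, ve=1, se=1` (amplitude dominates; its squaring steepens
  the quality gradient).  `Am` and `Sm` are min-max normalized per
  frame: scale-free, at the price of making `Qm` values comparable only
  within a frame — which is all the unwrapper needs.

## Unwrapping and absolute phase

The 4-connected valid-pixel graph is unwrapped along a maximum-quality
spanning tree grown Prim-style from a seed (deterministic argmax of
`Qm` by default; optionally a seeded random pixel from the top decile).
Edge weight is the minimum quality of the two endpoints; priority-queue
ties break in row-major order, so results are bit-reproducible.
4-connectivity prevents diagonal leakage across one-pixel background
gaps (armpit-like regions).  Disconnected components each get their own
seed.

The estimator's known second-order response to phase curvature — a
locally quadratic phase `phi''` biases the reading by exactly
`phi''*(Pm/4)^2` (first-order expansion of the seven-sample quotient) —
is removed analytically after unwrapping, where the continuous phase
makes `phi''` measurable (smoothed second difference along the fringe
normal).  This correction is what brings curved-surface reconstruction
(sphere caps) from ~0.4 mm systematic depth bias down to the ~0.01 mm
level; it is exactly zero on planes.

The marker is detected by a per-column FFT along the fringe direction
of the *demodulated local amplitude* (max-min filtered image) rather
than the raw intensity: on curved surfaces the geometry bends the
carrier into row-direction oscillations that sweep through the marker
band, whereas the local amplitude carries only the transverse
modulation.  The band around `1/(4p)` (half-width 20%) is kept, the
envelope is thresholded at 50% of its peak, and the largest connected
segment becomes the marker mask.  An absolute magnitude floor
distinguishes "no marker present" from a filtering failure.  The
narrow band limits localization *along* the fringe, so the mask is
validated through its centroid.  `Fm = Um + Phi_x` is emitted only on
unwrap components connected to the marker; the marker cannot anchor a
region it is not connected to, so the absolute phase there is NaN (and
counted).

## Calibration and reconstruction

Camera: pinhole with two radial distortion coefficients, initialised
from pose homographies (closed-form intrinsics from >= 3 independent
board poses) and refined jointly with all poses by Levenberg-Marquardt
on the reprojection error (reported as per-axis RMS).  Degenerate pose
sets are rejected at the closed-form stage.  The model is expanded to a
unit viewing ray per pixel (fixed-point undistortion).

Phase-to-depth: fringe views of a fronto-parallel plane at >= 3 known
depths are processed to absolute phase; per pixel, a cubic polynomial
(in a globally centred/scaled phase variable) maps phase to depth along
the ray.  Pixels with a singular or non-monotone fit on their
calibrated interval are invalid; evaluation outside the interval yields
NaN and such pixels are dropped with a count.  On the simulator's
linear phase-depth truth the cubic collapses to the linear law to
machine precision.

Clouds carry per-point intensity and a unit normal from central
differences of neighbouring pixels' (x, y, z), oriented toward the
camera; border pixels without enough neighbours fall back to the
reversed viewing direction.  Registration is closed-form SVD Procrustes
with a reflection guard; merging applies the transforms and
concatenates, nothing else.  The first head's camera frame is the
global frame.  Units are millimetres throughout; the board pitch
defines absolute scale.

## Synthetic study conditions

The default simulated head views a 2.5 m working distance with a
256 px camera of 600 px focal length (pixel footprint ~4.2 mm at the
object), carrier period 8 px, sensitivity 5 mm/rad, and a 7x9 marker
board of 100 mm pitch.  The calibrated depth volume is 2400-2600 mm:
the span is bounded by the marker fringe staying inside the frame
(±100 mm moves it by ±25 px here).  Fringe bias/amplitude are 0.5/0.45
so crests stay below the overexposure cut.  Scenes for the phase-domain
experiments (512 px sphere cap, body-like Gaussian blob fields) keep
surface slopes within the regime where the local fringe period stays
resolvable — the same constraint a physical scanner faces on steep
flanks.  Blob amplitudes scale with raster size so slopes are
size-independent.

Closed-loop camera calibration consumes exact synthetic marker
correspondences, isolating phase and reconstruction accuracy; the
image-based detector (darkness-weighted sub-pixel centroids, principal
axis grid association) is validated separately, where its accuracy is
limited by the rendered antialiasing and the projective ellipse-centroid
offset (~0.1% focal recovery).  The reconstructed sphere is a cap of an
R = 1600 mm sphere protruding 50 mm from a wall; a cap this shallow
keeps the junction slope resolvable, and points within ~16 mm depth of
the junction are excluded from the sphere fit because that band is the
phase estimator's support radius around the slope discontinuity.
Radius conditioning degrades as (R/h) for shallow caps, which is why
small-radius spheres cannot be metrologically tested at this pixel
footprint.

The board-validation scenario (flatness + outermost-marker diagonals)
uses a 384 px camera and the 2.0 x 1.5 m board with 120 mm markers.
Its reported flatness RMS (~1.3 mm) is dominated by phase artifacts at
the marker albedo edges; the per-pixel footprint here is roughly five
times coarser than a production scanner's, and these artifacts scale
with the sampling, so the value is a desk-scale analogue, not a
prediction of hardware accuracy.  The outer/inner edge averaging of the
diagonal measurement cancels symmetric edge-blur bias, which is why the
diagonals come back to ~0.02% even so.  Point intensities for this
scenario are one-period box means of the frame (the fringe ripple
integrates out, leaving the albedo contrast the edge localization
needs).

## What the synthetic data does not show

No camera noise model beyond additive Gaussian (optional), no gamma,
no defocus of the carrier, no interreflections or subsurface
scattering, no motion blur, no spectral crosstalk between heads.
Passing tests therefore demonstrate the correctness and internal
consistency of the algorithms under their stated assumptions, not the
hardware accuracy of any physical scanner.

## Numerical choices and degenerate inputs

Wrapped phases live in [-pi, pi); phase differences wrap through
`(x + pi) mod 2pi - pi`.  All-background frames yield an empty mask
with a warning, not an error; empty unwrap regions, empty marker masks,
collinear registration/plane inputs, and mismatched grids raise
`ValueError` with a diagnostic.  A frame without a marker raises a
dedicated `MarkerNotFoundError` carried out of the pipeline with its
stage name.  All randomness is seeded; identical configuration and seed
give bit-identical PLY output (coordinates are written as doubles,
normals and intensity as floats).

## Problem sizes

Defaults were chosen so the full test suite runs in well under a minute
and the acceptance script in ~20 s on one core: 512 px for the
phase-recovery scene, twenty 128 px scenes for the unwrapping-oracle
comparison, a 256 px head for the metric loop and 384 px for the board
procedure.  Accuracy improves monotonically with raster size (the
128/192/256 px closed-loop flatness is 0.014/0.009/0.007 mm), so these
sizes are floors, not sweet spots.
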