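# fringescan

Single-frame fringe-projection profilometry for dynamic surface
measurement, with a synthetic-scene simulator that makes every
processing stage verifiable against exact ground truth.

Full-body 4-D scanners (and structured-light scanners generally) that
must tolerate subject motion cannot project a time sequence of phase
shifted patterns: all of the shape information has to be recovered from
**one** camera frame of **one** projected pattern.  `fringescan`
implements that single-frame chain:

1. a projected sinusoidal pattern whose single distinguished fringe —
   the *marker* — is amplitude-modulated transversely so its projector
   fringe index `N` is recognisable in the camera image;
2. per-pixel maps derived from the frame: object mask `Om`, local
   fringe period `Pm`, amplitude `Am`, period stability `Sm`, wrapped
   phase `Wm` (7-sample spatial-carrier phase shifting, nominal π/2
   steps scaled by the local period), fringe verticality
   `Vm = gradH / (gradH + gradV)`, and border map `Bm`;
3. a quality map

   `Qm = (bw·Bm^be + aw·Am^ae + vw·Vm^ve + sw·Sm^se) / (bw+aw+vw+sw)`

   with default weights `bw=1, aw=5, vw=3, sw=1` and exponents
   `be=1, ae=2, ve=1, se=1`, which steers a maximum-quality spanning
   tree so that reliable regions unwrap first;
4. marker detection by 1-D FFT band filtering along the fringes and the
   absolute phase shift

   `Φx = 2π·(N − floor((median + π) / 2π))`,

   where `median` is the median unwrapped phase under the marker mask,
   giving the absolute phase map `Fm = Um + Φx`;
5. camera calibration (pinhole + radial distortion, expanded to a 3-D
   viewing ray per pixel), per-pixel polynomial phase-to-depth
   calibration, conversion of `Fm` into a point cloud in millimetres
   with intensities and normals, and SVD-Procrustes registration of
   multiple heads into one global frame;
6. the validation procedure for reconstructed calibration boards:
   total-least-squares plane flatness and the distance between the
   outermost marker centres along both board diagonals (mean of the
   outer-edge and inner-edge separations).

Everything is exercised against a simulator that renders fringe images
of parametric surfaces (planes, sphere caps, body-like Gaussian blobs,
marker boards) under a known phase-to-height model, so the true phase,
geometry and transforms are available analytically.

## Worked example

```python
import numpy as np
from fringescan import simulate as sim, workflows as wf
from fringescan.patterns import PatternSpec
from fringescan.pipeline import run_single_frame, PipelineConfig
from fringescan.validate import fit_plane

# one frame of a 40 mm sphere cap under a 16 px carrier, marker fringe N=8
spec = PatternSpec(width_px=256, height_px=256, period_px=16.0, marker_index=8)
z = sim.sphere_cap_height((256, 256), radius_mm=300.0, cap_height_mm=40.0)
image, truth = sim.render(sim.SyntheticScene(height_mm=z), spec)

frame = run_single_frame(image, PipelineConfig(pattern=spec))
err = frame.maps.Fm - truth.phase
valid = np.isfinite(err)
print(f"valid pixels        : {valid.sum()}")
print(f"phase shift Phi_x   : {frame.marker.phase_shift / (2*np.pi):+.0f} x 2pi")
print(f"|Fm - truth| RMS    : {np.sqrt(np.mean(err[valid]**2)):.4f} rad")

# metric closed loop: calibrate a synthetic head, reconstruct a plane
setup = wf.default_head(256)
model, cam_cal = wf.calibrate_head(setup, seed=0)
cloud, _ = wf.reconstruct_plane(setup, model)
print(f"reprojection RMS    : {cam_cal.reproj_rms_px:.2e} px")
print(f"plane flatness RMS  : {fit_plane(cloud.points)[2]:.4f} mm")
```

prints

```
valid pixels        : 44734
phase shift Phi_x   : +4 x 2pi
|Fm - truth| RMS    : 0.0071 rad
reprojection RMS    : 1.34e-14 px
plane flatness RMS  : 0.0068 mm
```

The absolute phase of the cap is recovered to well below a hundredth of
a fringe, and a plane pushed through the complete synthetic
calibration-and-reconstruction loop comes back flat to a few microns.

A command-line surface wraps the same library:

```sh
fringescan pattern --width 1280 --height 800 --period 16 --marker-index 40 -o pattern.png
fringescan simulate --scene sphere --size 256 --seed 1 -o demo/
fringescan process --in demo/frame.png --marker-index 8 -o out/
fringescan validate --seed 0 --report report.json
```

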