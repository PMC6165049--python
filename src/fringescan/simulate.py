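"""Synthetic fringe-projection scenes with exact ground truth.

Stands in for a physical directional measurement head (projector +
camera).  Two geometry models are provided:

* **Height-field (crossed-optical-axes) model** — a surface ``z(r, c)``
  in mm on the pixel grid adds a phase offset proportional to height::

      phi(r, c) = 2*pi*c / carrier_period_px + z(r, c) / sensitivity

  with ``sensitivity`` in mm of depth per radian.  This yields exact,
  analytically known ground truth for every single-frame processing
  stage (mask, period, phase, unwrapping, marker).

* **Pinhole-camera model** — calibration-board images and fringe views
  of metric surfaces rendered through a :class:`~fringescan.geometry.CameraModel`,
  used to exercise camera/phase calibration and metric reconstruction
  in a closed loop.

Identical (scene, seed) pairs render identical images.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .geometry import BoardSpec, CameraModel, RigidTransform
from .patterns import TWO_PI, PatternSpec, marker_amplitude_factor

__all__ = [
    "SyntheticScene", "GroundTruth", "render",
    "plane_height", "sphere_cap_height", "blob_height", "disk_support",
    "render_board", "plane_depth_map", "sphere_depth_map", "render_projection",
    "board_albedo", "board_support",
]


@dataclass
class GroundTruth:
    """Exact per-pixel truth accompanying a rendered frame.

    ``phase`` is the absolute fringe phase (radians), defined exactly on
    ``mask``; ``depth_mm`` (pinhole renders) is the depth along each
    pixel ray; ``points`` are surface points in mm; ``transform`` is the
    pose placing the surface in the world/camera frame.
    """

    phase: np.ndarray
    mask: np.ndarray
    depth_mm: np.ndarray | None = None
    points: np.ndarray | None = None
    transform: RigidTransform | None = None
    marker_centers_px: np.ndarray | None = None


# --------------------------------------------------------------------------
# height-field surfaces


def plane_height(shape: tuple[int, int], slope_row: float = 0.0,
                 slope_col: float = 0.0, offset_mm: float = 0.0) -> np.ndarray:
    """Planar height field ``z = offset + slope_row*r + slope_col*c`` (mm/px slopes)."""
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return offset_mm + slope_row * r + slope_col * c


def sphere_cap_height(shape: tuple[int, int], radius_mm: float = 300.0,
                      cap_height_mm: float = 40.0, px_size_mm: float = 1.0,
                      center: tuple[float, float] | None = None) -> np.ndarray:
    """Spherical cap of height ``cap_height_mm`` rising from the z=0 plane."""
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    rho2 = ((r - center[0]) ** 2 + (c - center[1]) ** 2) * px_size_mm**2
    z = np.sqrt(np.clip(radius_mm**2 - rho2, 0.0, None)) - (radius_mm - cap_height_mm)
    return np.clip(z, 0.0, None)


def blob_height(shape: tuple[int, int], seed: int = 0, n_bumps: tuple[int, int] = (2, 4),
                amplitude_mm: tuple[float, float] | None = None) -> np.ndarray:
    """Smooth body-like surface: a seeded sum of 2-4 anisotropic Gaussian
    bumps, giving regions of high curvature and concavity.

    Bump amplitudes default to (10, 40) mm at a 256 px raster and scale
    with the raster so the surface slopes (hence the fringe deformation)
    are size-independent.
    """
    rng = np.random.default_rng(seed)
    if amplitude_mm is None:
        s = min(shape) / 256.0
        amplitude_mm = (10.0 * s, 40.0 * s)
    n = int(rng.integers(n_bumps[0], n_bumps[1] + 1))
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    z = np.zeros(shape, dtype=float)
    for _ in range(n):
        cr = rng.uniform(0.2, 0.8) * shape[0]
        cc = rng.uniform(0.2, 0.8) * shape[1]
        sr = rng.uniform(0.10, 0.30) * shape[0]
        sc = rng.uniform(0.10, 0.30) * shape[1]
        theta = rng.uniform(0, np.pi)
        amp = rng.uniform(*amplitude_mm) * rng.choice([-0.4, 1.0])
        dr, dc = r - cr, c - cc
        u = np.cos(theta) * dr + np.sin(theta) * dc
        w = -np.sin(theta) * dr + np.cos(theta) * dc
        z += amp * np.exp(-0.5 * ((u / sr) ** 2 + (w / sc) ** 2))
    return z


def disk_support(shape: tuple[int, int], radius_px: float,
                 center: tuple[float, float] | None = None) -> np.ndarray:
    if center is None:
        center = ((shape[0] - 1) / 2.0, (shape[1] - 1) / 2.0)
    r, c = np.mgrid[0:shape[0], 0:shape[1]].astype(float)
    return (r - center[0]) ** 2 + (c - center[1]) ** 2 <= radius_px**2


# --------------------------------------------------------------------------
# height-field renderer


@dataclass
class SyntheticScene:
    """A height-field scene under the crossed-optical-axes phase model.

    Parameters
    ----------
    height_mm
        Surface height field z(r, c) in mm; must be finite on ``support``.
    support
        Boolean support mask; outside it the image shows only
        ``background_level`` (+ noise).  ``None`` means full frame.
    sensitivity_mm_per_rad
        Phase-to-height factor of the simulated triangulation pair.
    carrier_period_px
        Carrier fringe period in camera pixels.
    offset, amplitude
        Fringe bias a and amplitude b of ``a + b*cos(phi)``.
    noise_sigma
        Std of additive Gaussian intensity noise.
    phase_offset_rad
        Constant added to the absolute phase (for equivariance tests).
    """

    height_mm: np.ndarray
    support: np.ndarray | None = None
    sensitivity_mm_per_rad: float = 5.0
    carrier_period_px: float = 16.0
    offset: float = 0.5
    amplitude: float = 0.45
    background_level: float = 0.05
    noise_sigma: float = 0.0
    phase_offset_rad: float = 0.0
    seed: int = 0

    def __post_init__(self) -> None:
        self.height_mm = np.asarray(self.height_mm, dtype=float)
        if self.support is None:
            self.support = np.ones(self.height_mm.shape, dtype=bool)
        self.support = np.asarray(self.support, dtype=bool)
        if not self.sensitivity_mm_per_rad > 0:
            raise ValueError("sensitivity must be > 0")
        if not self.carrier_period_px > 0:
            raise ValueError("carrier period must be > 0")
        if self.noise_sigma < 0:
            raise ValueError("noise_sigma must be >= 0")
        if not (0.0 <= self.background_level < 1.0):
            raise ValueError("background_level must lie in [0, 1)")
        if not np.all(np.isfinite(self.height_mm[self.support])):
            raise ValueError("height field must be finite on its support")


def render(scene: SyntheticScene, spec: PatternSpec | None = None
           ) -> tuple[np.ndarray, GroundTruth]:
    """Render a fringe image of a height-field scene.

    Returns the intensity raster and the exact ground truth (absolute
    phase on the support, the support mask).  With ``spec`` given, the
    marker fringe of the projected pattern is composited in.
    """
    rows_n, cols_n = scene.height_mm.shape
    r, c = np.mgrid[0:rows_n, 0:cols_n].astype(float)
    phase = (TWO_PI * c / scene.carrier_period_px
             + scene.height_mm / scene.sensitivity_mm_per_rad
             + scene.phase_offset_rad)
    if spec is not None:
        amp_factor = marker_amplitude_factor(phase, r, spec)
    else:
        amp_factor = 1.0
    img = scene.offset + scene.amplitude * amp_factor * np.cos(phase)
    img = np.where(scene.support, img, scene.background_level)
    if scene.noise_sigma > 0:
        rng = np.random.default_rng(scene.seed)
        img = img + rng.normal(0.0, scene.noise_sigma, img.shape)
    truth_phase = np.where(scene.support, phase, np.nan)
    return img, GroundTruth(phase=truth_phase, mask=scene.support.copy())


# --------------------------------------------------------------------------
# pinhole-camera renders


def board_albedo(board: BoardSpec, pose: RigidTransform, camera: CameraModel,
                 supersample: int = 3, albedo_board: float = 0.9,
                 albedo_marker: float = 0.1, background: float = 0.02
                 ) -> np.ndarray:
    """Albedo map of the posed board as seen by ``camera``.

    Renders exact projective marker ellipses by inverse mapping: each
    (supersampled) pixel ray is intersected with the board plane and the
    board-frame point is classified against the marker grid.
    """
    rows, cols = camera.image_shape
    ss = int(supersample)
    off = (np.arange(ss) + 0.5) / ss - 0.5
    du, dv = np.meshgrid(off, off)
    v, u = np.mgrid[0:rows, 0:cols].astype(float)
    uu = u[..., None, None] + du
    vv = v[..., None, None] + dv
    xd = (uu - camera.cx) / camera.fx
    yd = (vv - camera.cy) / camera.fy
    x, y = camera.undistort_normalized(xd, yd)
    d = np.stack([x, y, np.ones_like(x)], axis=-1)

    n = pose.rotation[:, 2]
    p0 = pose.translation
    denom = d @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p0 @ n) / denom
    X = d * t[..., None]
    b = (X - p0) @ pose.rotation  # board-frame coordinates
    bx, by = b[..., 0], b[..., 1]

    half_w, half_h = np.asarray(board.size_mm) / 2.0
    on_board = (np.abs(bx) <= half_w) & (np.abs(by) <= half_h) & (t > 0)

    gx = np.clip(np.round(bx / board.pitch_mm + (board.cols - 1) / 2.0),
                 0, board.cols - 1)
    gy = np.clip(np.round(by / board.pitch_mm + (board.rows - 1) / 2.0),
                 0, board.rows - 1)
    cxn = (gx - (board.cols - 1) / 2.0) * board.pitch_mm
    cyn = (gy - (board.rows - 1) / 2.0) * board.pitch_mm
    dist = np.hypot(bx - cxn, by - cyn)
    in_marker = dist <= board.marker_diameter_mm / 2.0

    albedo = np.where(on_board,
                      np.where(in_marker, albedo_marker, albedo_board),
                      background)
    return albedo.mean(axis=(-1, -2))


def board_support(board: BoardSpec, pose: RigidTransform, camera: CameraModel
                  ) -> np.ndarray:
    """Boolean raster of pixels whose centre ray hits the board surface."""
    rays = camera.pixel_rays()
    n = pose.rotation[:, 2]
    p0 = pose.translation
    denom = rays @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (p0 @ n) / denom
    X = rays * t[..., None]
    b = (X - p0) @ pose.rotation
    half_w, half_h = np.asarray(board.size_mm) / 2.0
    return ((np.abs(b[..., 0]) <= half_w) & (np.abs(b[..., 1]) <= half_h)
            & (t > 0))


def render_board(board: BoardSpec, pose: RigidTransform, camera: CameraModel,
                 supersample: int = 3, noise_sigma: float = 0.0, seed: int = 0
                 ) -> tuple[np.ndarray, GroundTruth]:
    """Render an image of the calibration board under uniform illumination.

    Ground truth carries the projected marker centres (pinhole projection
    of the 3-D centres, (n, 2) as (u, v)) and the injected pose.  All
    markers must project inside the image.
    """
    centers3d = pose.apply(board.marker_centers())
    if np.any(centers3d[:, 2] <= 0):
        raise ValueError("board markers lie behind the camera")
    uv = camera.project(centers3d)
    rows, cols = camera.image_shape
    margin = 0.5 * board.marker_diameter_mm * camera.fx / centers3d[:, 2].max()
    if (np.any(uv[:, 0] < margin) or np.any(uv[:, 0] > cols - 1 - margin)
            or np.any(uv[:, 1] < margin) or np.any(uv[:, 1] > rows - 1 - margin)):
        raise ValueError("board markers must all project inside the image")
    img = board_albedo(board, pose, camera, supersample=supersample)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    truth = GroundTruth(phase=np.full(camera.image_shape, np.nan),
                        mask=np.zeros(camera.image_shape, dtype=bool),
                        points=centers3d, transform=pose,
                        marker_centers_px=uv)
    return img, truth


def plane_depth_map(camera: CameraModel, plane_point: np.ndarray,
                    plane_normal: np.ndarray) -> np.ndarray:
    """Along-ray depth of a plane for every pixel (mm); NaN where the ray
    misses (is parallel to or exits away from) the plane."""
    d = camera.pixel_rays()
    n = np.asarray(plane_normal, float)
    n = n / np.linalg.norm(n)
    denom = d @ n
    with np.errstate(divide="ignore", invalid="ignore"):
        t = (np.asarray(plane_point, float) @ n) / denom
    return np.where(t > 0, t, np.nan)


def sphere_depth_map(camera: CameraModel, center: np.ndarray, radius_mm: float
                     ) -> np.ndarray:
    """Along-ray depth of the near intersection with a sphere (mm); NaN
    where the ray misses."""
    d = camera.pixel_rays()
    c = np.asarray(center, dtype=float)
    b = d @ c
    disc = b * b - (c @ c - radius_mm**2)
    with np.errstate(invalid="ignore"):
        t = b - np.sqrt(disc)
    return np.where((disc >= 0) & (t > 0), t, np.nan)


def render_projection(camera: CameraModel, depth_map: np.ndarray,
                      spec: PatternSpec | None,
                      sensitivity_mm_per_rad: float,
                      z_ref_mm: float,
                      carrier_period_px: float = 16.0,
                      albedo: np.ndarray | float = 1.0,
                      offset: float = 0.5, amplitude: float = 0.45,
                      background_level: float = 0.05,
                      noise_sigma: float = 0.0, seed: int = 0,
                      ) -> tuple[np.ndarray, GroundTruth]:
    """Render a fringe view of a metric surface given per-pixel depths.

    ``depth_map`` holds along-ray depths in mm (NaN off the surface).
    The absolute phase follows the crossed-axes model on the axial depth
    ``z = t * dir_z``::

        phi(r, c) = 2*pi*c / carrier_period_px + (z - z_ref) / sensitivity

    so the per-pixel phase-to-depth relation is exactly linear — the
    analytic ground truth for phase calibration.
    """
    if not sensitivity_mm_per_rad > 0:
        raise ValueError("sensitivity must be > 0")
    if not carrier_period_px > 0:
        raise ValueError("carrier period must be > 0")
    rows_n, cols_n = camera.image_shape
    t = np.asarray(depth_map, dtype=float)
    rays = camera.pixel_rays()
    z = t * rays[..., 2]
    support = np.isfinite(z)
    r, c = np.mgrid[0:rows_n, 0:cols_n].astype(float)
    phase = TWO_PI * c / carrier_period_px + (z - z_ref_mm) / sensitivity_mm_per_rad
    amp_factor = marker_amplitude_factor(phase, r, spec) if spec is not None else 1.0
    img = np.asarray(albedo) * (offset + amplitude * amp_factor * np.cos(phase))
    img = np.where(support, img, background_level)
    if noise_sigma > 0:
        rng = np.random.default_rng(seed)
        img = img + rng.normal(0.0, noise_sigma, img.shape)
    truth_phase = np.where(support, phase, np.nan)
    pts = (rays * t[..., None])[support]
    return img, GroundTruth(phase=truth_phase, mask=support,
                            depth_mm=np.where(support, t, np.nan), points=pts)
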