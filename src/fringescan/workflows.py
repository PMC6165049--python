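"""Closed-loop measurement scenarios built from the synthetic head.

These functions wire the simulator, the single-frame chain and the
calibration stack into complete, self-verifying experiments:

* :func:`calibrate_head` — camera calibration from rendered board poses
  followed by phase calibration from fringe views of fronto-parallel
  planes at known depths;
* :func:`reconstruct_plane` / :func:`reconstruct_sphere` — metric
  reconstruction of known surfaces through the full pipeline;
* :func:`board_validation` — the flatness / outermost-marker-distance
  error analysis on a reconstructed board cloud.

The default numbers model one directional head of a body scanner at desk
scale: a 256 px camera of 300 px focal length viewing a 2.0 x 1.5 m
marker board around 2.5 m depth, fringe period 16 px and a phase
sensitivity of 5 mm per radian of phase.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from . import simulate as sim
from .calibrate import (CalibrationModel, CameraCalibration, PointCloud,
                        calibrate_camera, fit_phase_to_depth, phase_to_cloud)
from .geometry import BoardSpec, CameraModel, RigidTransform
from .patterns import PatternSpec
from .pipeline import PipelineConfig, run_single_frame
from .validate import ValidationReport, fit_plane, outermost_marker_distance

__all__ = ["HeadSetup", "default_head", "calibrate_head", "render_surface",
           "reconstruct_depth_map", "reconstruct_plane", "reconstruct_sphere",
           "board_validation"]


@dataclass(frozen=True)
class HeadSetup:
    """Geometry and pattern parameters of one simulated directional head."""

    camera: CameraModel
    board: BoardSpec
    carrier_period_px: float = 8.0
    sensitivity_mm_per_rad: float = 5.0
    z_ref_mm: float = 2500.0
    marker_index: int = 16
    # the working depth range is bounded by the marker fringe staying in
    # view: +/-100 mm at 5 mm/rad moves the marker by +/-51 px here
    calib_depths_mm: tuple[float, ...] = (2400.0, 2450.0, 2500.0, 2550.0, 2600.0)

    @property
    def pattern(self) -> PatternSpec:
        rows, cols = self.camera.image_shape
        return PatternSpec(width_px=cols, height_px=rows,
                           period_px=self.carrier_period_px,
                           marker_index=self.marker_index)

    def pipeline_config(self, **overrides) -> PipelineConfig:
        cfg = PipelineConfig(pattern=self.pattern)
        for k, v in overrides.items():
            setattr(cfg, k, v)
        return cfg


def default_head(image_px: int = 256) -> HeadSetup:
    cam = CameraModel(fx=600.0 * image_px / 256, fy=600.0 * image_px / 256,
                      cx=(image_px - 1) / 2.0, cy=(image_px - 1) / 2.0,
                      image_shape=(image_px, image_px))
    board = BoardSpec(rows=7, cols=9, pitch_mm=100.0, marker_diameter_mm=45.0,
                      board_size_mm=(900.0, 700.0))
    return HeadSetup(camera=cam, board=board,
                     marker_index=int(image_px / 8.0 / 2))


def _calibration_poses(n: int, seed: int, z_center_mm: float = 2500.0
                       ) -> list[RigidTransform]:
    """Depth-spanning, mildly rotated board poses for camera calibration."""
    rng = np.random.default_rng(seed)
    poses = []
    depths = np.linspace(0.94 * z_center_mm, 1.06 * z_center_mm, n)
    for i in range(n):
        rot = rng.uniform(-0.15, 0.15, size=3) * np.array([1.0, 1.0, 0.45])
        shift = rng.uniform(-0.016, 0.016, size=2) * z_center_mm
        poses.append(RigidTransform.from_rotvec(
            rot, [shift[0], shift[1], depths[i]]))
    return poses


def calibrate_head(setup: HeadSetup, n_camera_poses: int = 6, seed: int = 0,
                   centroid_noise_px: float = 0.0
                   ) -> tuple[CalibrationModel, CameraCalibration]:
    """Full local calibration of one head from synthetic observations."""
    rng = np.random.default_rng(seed + 1)
    poses = _calibration_poses(n_camera_poses, seed, setup.z_ref_mm)
    detections = []
    for pose in poses:
        _, truth = sim.render_board(setup.board, pose, setup.camera)
        uv = truth.marker_centers_px
        if centroid_noise_px > 0:
            uv = uv + rng.normal(0.0, centroid_noise_px, uv.shape)
        detections.append(uv)
    cam_cal = calibrate_camera(None, setup.board, detections=detections,
                               image_shape=setup.camera.image_shape)

    cfg = setup.pipeline_config()
    fm_stack, t_stack = [], []
    rays = cam_cal.camera.pixel_rays()
    for depth in setup.calib_depths_mm:
        t_true = sim.plane_depth_map(setup.camera, [0.0, 0.0, depth],
                                     [0.0, 0.0, 1.0])
        img, _ = sim.render_projection(
            setup.camera, t_true, setup.pattern, setup.sensitivity_mm_per_rad,
            setup.z_ref_mm, carrier_period_px=setup.carrier_period_px)
        frame = run_single_frame(img, cfg)
        fm_stack.append(frame.maps.Fm)
        t_stack.append(depth / rays[..., 2])
    phase_model = fit_phase_to_depth(np.stack(fm_stack), np.stack(t_stack))
    return CalibrationModel(camera=cam_cal.camera,
                            phase_model=phase_model), cam_cal


def reconstruct_depth_map(setup: HeadSetup, model: CalibrationModel,
                          depth_map: np.ndarray,
                          albedo: np.ndarray | float = 1.0,
                          support: np.ndarray | None = None,
                          noise_sigma: float = 0.0, seed: int = 0,
                          mask_overrides: dict | None = None,
                          intensity_mode: str = "raw",
                          ) -> tuple[PointCloud, sim.GroundTruth]:
    """Render a surface given by along-ray depths and reconstruct it."""
    t = np.asarray(depth_map, dtype=float)
    if support is not None:
        t = np.where(support, t, np.nan)
    img, truth = sim.render_projection(
        setup.camera, t, setup.pattern, setup.sensitivity_mm_per_rad,
        setup.z_ref_mm, carrier_period_px=setup.carrier_period_px,
        albedo=albedo, noise_sigma=noise_sigma, seed=seed)
    cfg = setup.pipeline_config(**(mask_overrides or {}))
    frame = run_single_frame(img, cfg)
    if intensity_mode == "mean":
        w = int(round(setup.carrier_period_px))
        intensity = ndi.uniform_filter(img, size=(1, w), mode="nearest")
    else:
        intensity = img
    cloud, _ = phase_to_cloud(frame.maps.Fm, intensity, model)
    return cloud, truth


render_surface = reconstruct_depth_map  # evocative alias for scripts


def reconstruct_plane(setup: HeadSetup, model: CalibrationModel,
                      depth_mm: float = 2500.0,
                      normal=(0.015, -0.010, -1.0),
                      noise_sigma: float = 0.0, seed: int = 0
                      ) -> tuple[PointCloud, sim.GroundTruth]:
    """Closed-loop reconstruction of a (slightly tilted) plane."""
    n = np.asarray(normal, dtype=float)
    t_true = sim.plane_depth_map(setup.camera, [0.0, 0.0, depth_mm], n)
    return reconstruct_depth_map(setup, model, t_true,
                                 noise_sigma=noise_sigma, seed=seed)


def reconstruct_sphere(setup: HeadSetup, model: CalibrationModel,
                       radius_mm: float = 1600.0, wall_depth_mm: float = 2500.0,
                       protrusion_mm: float = 50.0, noise_sigma: float = 0.0,
                       seed: int = 0):
    """Closed-loop reconstruction of a sphere cap protruding from a wall.

    Returns (cloud, ground truth, true sphere centre).  The cap keeps the
    junction slope gentle enough that the local fringe period stays
    resolvable everywhere.  When fitting a sphere to the result, exclude
    points within ~16 mm depth of the wall junction: that band is the
    phase estimator's support radius around the slope discontinuity.
    """
    center = np.array([0.0, 0.0, wall_depth_mm + radius_mm - protrusion_mm])
    t_sphere = sim.sphere_depth_map(setup.camera, center, radius_mm)
    t_wall = sim.plane_depth_map(setup.camera, [0.0, 0.0, wall_depth_mm],
                                 [0.0, 0.0, 1.0])
    rays = setup.camera.pixel_rays()
    z_sphere = t_sphere * rays[..., 2]
    use_sphere = np.isfinite(t_sphere) & (z_sphere <= wall_depth_mm)
    t = np.where(use_sphere, t_sphere, t_wall)
    cloud, truth = reconstruct_depth_map(setup, model, t,
                                         noise_sigma=noise_sigma, seed=seed)
    return cloud, truth, center


def board_validation(seed: int = 0, point_noise_mm: float = 0.0,
                     image_px: int = 384, board_depth_mm: float = 2500.0,
                     tilt=(0.0, 0.0, -1.0)) -> ValidationReport:
    """Simulate a fringe view of the marker board, reconstruct it through
    a calibrated head, and run the flatness / diagonal-distance analysis."""
    cam = CameraModel(fx=450.0 * image_px / 384, fy=450.0 * image_px / 384,
                      cx=(image_px - 1) / 2.0, cy=(image_px - 1) / 2.0,
                      image_shape=(image_px, image_px))
    board = BoardSpec(rows=7, cols=9, pitch_mm=200.0,
                      marker_diameter_mm=120.0, board_size_mm=(2000.0, 1500.0))
    setup = HeadSetup(camera=cam, board=board, carrier_period_px=12.0,
                      marker_index=int(image_px / 12.0 / 2),
                      calib_depths_mm=(2300.0, 2400.0, 2500.0, 2600.0, 2700.0))
    model, _ = calibrate_head(setup, seed=seed)

    n = np.asarray(tilt, dtype=float)
    pose = RigidTransform.identity()
    pose = RigidTransform(pose.rotation, np.array([0.0, 0.0, board_depth_mm]))
    t_plane = sim.plane_depth_map(setup.camera, pose.translation, n)
    albedo = sim.board_albedo(board, pose, cam)
    support = sim.board_support(board, pose, cam)
    cloud, _ = reconstruct_depth_map(
        setup, model, t_plane, albedo=albedo, support=support,
        mask_overrides={"mask_source": "contrast", "mask_threshold": 0.02},
        intensity_mode="mean")
    if point_noise_mm > 0:
        rng = np.random.default_rng(seed)
        cloud = PointCloud(
            points=cloud.points + rng.normal(0.0, point_noise_mm,
                                             cloud.points.shape),
            intensity=cloud.intensity, normals=cloud.normals,
            source_pixel=cloud.source_pixel, grid_shape=cloud.grid_shape)
    _, _, plane_rms = fit_plane(cloud.points)
    d1, d2, details = outermost_marker_distance(cloud, board)
    expected = board.pitch_mm * float(np.hypot(board.rows - 1, board.cols - 1))
    return ValidationReport(plane_rms_mm=plane_rms, diag_distance_1_mm=d1,
                            diag_distance_2_mm=d2, expected_diag_mm=expected,
                            details=details)
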