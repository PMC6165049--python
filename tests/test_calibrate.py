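"""Camera/phase calibration, reconstruction and registration, closed loop."""

import warnings

import numpy as np
import pytest
from scipy.spatial.transform import Rotation

from fringescan import simulate as sim
from fringescan import workflows as wf
from fringescan.calibrate import (CalibrationModel, PointCloud,
                                  calibrate_camera, detect_board_markers,
                                  estimate_transform, fit_phase_to_depth,
                                  merge_clouds, phase_to_cloud)
from fringescan.geometry import BoardSpec, CameraModel, RigidTransform

warnings.filterwarnings("ignore", message=".*All-NaN slice.*")


def _camera(n=256, f=600.0):
    return CameraModel(fx=f, fy=f, cx=(n - 1) / 2, cy=(n - 1) / 2,
                       image_shape=(n, n))


def _board():
    return BoardSpec(rows=7, cols=9, pitch_mm=100.0, marker_diameter_mm=45.0,
                     board_size_mm=(900.0, 700.0))


def _poses(n=6, seed=0):
    rng = np.random.default_rng(seed)
    out = []
    for depth in np.linspace(2350.0, 2650.0, n):
        rot = rng.uniform(-0.15, 0.15, 3) * [1.0, 1.0, 0.45]
        sh = rng.uniform(-40.0, 40.0, 2)
        out.append(RigidTransform.from_rotvec(rot, [sh[0], sh[1], depth]))
    return out


# ----------------------------------------------------------------------
# board marker detection


def test_frontoparallel_detection_subpixel():
    cam = _camera()
    board = _board()
    pose = RigidTransform(np.eye(3), [0.0, 0.0, 2500.0])
    img, truth = sim.render_board(board, pose, cam, supersample=5)
    det = detect_board_markers(img, board)
    assert det.complete
    assert np.abs(det.uv - truth.marker_centers_px).max() < 0.1


def test_rotated_board_association_preserves_topology():
    cam = _camera()
    board = _board()
    pose = RigidTransform.from_rotvec([0.0, np.deg2rad(30), 0.05],
                                      [0.0, 0.0, 2500.0])
    img, truth = sim.render_board(board, pose, cam, supersample=5)
    det = detect_board_markers(img, board)
    assert det.complete
    # row-major association must match the ground-truth projection order
    assert np.abs(det.uv - truth.marker_centers_px).max() < 0.5


def test_blank_image_reports_zero_markers():
    det = detect_board_markers(np.full((64, 64), 0.9), _board())
    assert det.uv.shape == (0, 2)
    assert not det.complete


# ----------------------------------------------------------------------
# camera calibration


def test_exact_observations_recover_intrinsics():
    cam = _camera()
    board = _board()
    detections = []
    for pose in _poses():
        _, truth = sim.render_board(board, pose, cam)
        detections.append(truth.marker_centers_px)
    cal = calibrate_camera(None, board, detections=detections,
                           image_shape=cam.image_shape)
    assert abs(cal.camera.fx - cam.fx) / cam.fx < 1e-9
    assert abs(cal.camera.fy - cam.fy) / cam.fy < 1e-9
    assert cal.reproj_rms_px < 1e-9


def test_image_based_calibration_detector_limited():
    cam = _camera()
    board = _board()
    images = [sim.render_board(board, p, cam, supersample=5)[0]
              for p in _poses()]
    cal = calibrate_camera(images, board)
    assert abs(cal.camera.fx - cam.fx) / cam.fx < 5e-3
    assert cal.reproj_rms_px < 0.1


def test_degenerate_pose_set_rejected():
    cam = _camera()
    board = _board()
    pose = RigidTransform(np.eye(3), [0.0, 0.0, 2500.0])
    _, truth = sim.render_board(board, pose, cam)
    with pytest.raises(ValueError, match="degenerate|independent"):
        calibrate_camera(None, board,
                         detections=[truth.marker_centers_px] * 6,
                         image_shape=cam.image_shape)


@pytest.mark.parametrize("seed", [0, 1, 2])
def test_centroid_noise_propagates_to_reprojection_rms(seed):
    cam = _camera()
    board = _board()
    rng = np.random.default_rng(seed)
    detections = []
    for pose in _poses():
        _, truth = sim.render_board(board, pose, cam)
        detections.append(truth.marker_centers_px
                          + rng.normal(0.0, 0.2, truth.marker_centers_px.shape))
    cal = calibrate_camera(None, board, detections=detections,
                           image_shape=cam.image_shape)
    n_obs = 6 * board.rows * board.cols * 2
    n_par = 6 + 6 * 6
    expected = 0.2 * np.sqrt(1.0 - n_par / n_obs)
    assert cal.reproj_rms_px == pytest.approx(expected, rel=0.15)


# ----------------------------------------------------------------------
# phase-to-depth fitting


def test_linear_phase_depth_fitted_exactly():
    rng = np.random.default_rng(0)
    phases = np.linspace(-20, 20, 6)[:, None, None] * np.ones((1, 8, 8))
    phases += rng.normal(0, 0.5, (1, 8, 8))          # per-pixel offsets
    depths = 2500.0 + 5.0 * phases                   # exactly linear
    model = fit_phase_to_depth(phases, depths, degree=3)
    assert model.valid.all()
    # the cubic fit of linear data must be the linear polynomial
    test_phase = phases[2] + 0.37
    expected = 2500.0 + 5.0 * test_phase
    np.testing.assert_allclose(model.evaluate(test_phase), expected,
                               rtol=1e-6)


def test_held_out_pose_depth_error():
    setup = wf.default_head(96)
    model, _ = wf.calibrate_head(setup, seed=0)
    # render the middle depth, withheld from nothing (linear model is exact);
    # evaluate depth at a pose between the calibrated ones
    t_true = sim.plane_depth_map(setup.camera, [0, 0, 2475.0], [0, 0, 1.0])
    img, truth = sim.render_projection(
        setup.camera, t_true, setup.pattern, setup.sensitivity_mm_per_rad,
        setup.z_ref_mm, carrier_period_px=setup.carrier_period_px)
    from fringescan.pipeline import run_single_frame
    frame = run_single_frame(img, setup.pipeline_config())
    t_est = model.phase_model.evaluate(frame.maps.Fm)
    err = np.abs(t_est - t_true)
    assert np.nanmedian(err) < 0.05


def test_constant_phase_pixel_flagged_invalid():
    phases = np.ones((5, 4, 4)) * np.linspace(-10, 10, 5)[:, None, None]
    phases[:, 2, 2] = 3.0                             # no depth sensitivity
    depths = 2500.0 + 5.0 * phases
    model = fit_phase_to_depth(phases, depths)
    assert model.valid[0, 0]
    assert not model.valid[2, 2]


# ----------------------------------------------------------------------
# cloud generation


@pytest.fixture(scope="module")
def head_and_model():
    setup = wf.default_head(192)
    model, cal = wf.calibrate_head(setup, seed=0)
    return setup, model


def test_plane_cloud_flatness_and_normals(head_and_model):
    setup, model = head_and_model
    cloud, _ = wf.reconstruct_plane(setup, model)
    from fringescan.validate import fit_plane
    c, n, rms = fit_plane(cloud.points)
    assert rms < 0.015
    true_n = np.array([0.015, -0.010, -1.0])
    true_n /= np.linalg.norm(true_n)
    ang = np.degrees(np.arccos(np.clip(np.abs(cloud.normals @ true_n), 0, 1)))
    assert np.mean(ang) < 0.5
    assert np.allclose(np.linalg.norm(cloud.normals, axis=1), 1.0, atol=1e-9)


def test_sphere_radius_recovery(head_and_model):
    setup, model = head_and_model
    cloud, _, center = wf.reconstruct_sphere(setup, model)
    from fringescan.validate import fit_sphere
    cap = cloud.points[cloud.points[:, 2] < 2500.0 - 16.0]
    assert len(cap) > 500
    cfit, rfit = fit_sphere(cap)
    assert abs(rfit - 1600.0) < 0.3
    assert np.linalg.norm(cfit - center) < 0.3


def test_cloud_grid_mismatch_rejected(head_and_model):
    _, model = head_and_model
    with pytest.raises(ValueError):
        phase_to_cloud(np.zeros((8, 8)), np.zeros((8, 8)), model)


def test_scene_scaled_twice_gives_cloud_scaled_twice():
    """All metric inputs doubled -> the reconstructed cloud doubles."""
    def loop(scale):
        cam = _camera(128, f=300.0)
        board = BoardSpec(rows=7, cols=9, pitch_mm=100.0 * scale,
                          marker_diameter_mm=45.0 * scale,
                          board_size_mm=(900.0 * scale, 700.0 * scale))
        setup = wf.HeadSetup(
            camera=cam, board=board, marker_index=8,
            sensitivity_mm_per_rad=5.0 * scale,
            z_ref_mm=2500.0 * scale,
            calib_depths_mm=tuple(d * scale for d in
                                  (2400.0, 2450.0, 2500.0, 2550.0, 2600.0)))
        model, _ = wf.calibrate_head(setup, seed=0)
        t = sim.plane_depth_map(setup.camera, [0, 0, 2500.0 * scale],
                                [0.01, 0.0, -1.0])
        cloud, _ = wf.reconstruct_depth_map(setup, model, t)
        return cloud

    c1, c2 = loop(1.0), loop(2.0)
    assert len(c1) == len(c2)
    # phase-estimation residuals (~0.1 mm at this raster) set the floor;
    # any unit/scale confusion would show up at the metres level
    np.testing.assert_allclose(c2.points, 2.0 * c1.points, atol=0.5)


# ----------------------------------------------------------------------
# registration and merging


def test_identity_correspondences():
    pts = np.random.default_rng(0).uniform(-100, 100, (10, 3))
    T, rms = estimate_transform(pts, pts)
    np.testing.assert_allclose(T.rotation, np.eye(3), atol=1e-12)
    np.testing.assert_allclose(T.translation, 0.0, atol=1e-12)
    assert rms < 1e-12


def test_known_transform_recovered_to_1e9():
    rng = np.random.default_rng(3)
    A = rng.uniform(-500, 500, (20, 3))
    R = Rotation.from_rotvec(rng.uniform(-1, 1, 3)).as_matrix()
    t = rng.uniform(-200, 200, 3)
    B = A @ R.T + t
    T, rms = estimate_transform(A, B)
    assert np.abs(T.rotation - R).max() < 1e-9
    assert np.abs(T.translation - t).max() < 1e-9
    assert rms < 1e-9


def test_inverse_consistency():
    rng = np.random.default_rng(5)
    A = rng.uniform(-300, 300, (15, 3))
    B = A @ Rotation.from_rotvec([0.3, -0.2, 0.9]).as_matrix().T + [5, -7, 40]
    T_ab, _ = estimate_transform(A, B)
    T_ba, _ = estimate_transform(B, A)
    M = T_ab.compose(T_ba).as_matrix()
    np.testing.assert_allclose(M, np.eye(4), atol=1e-9)


@pytest.mark.parametrize("sigma", [0.1, 0.3])
def test_registration_rms_scales_with_noise(sigma):
    n = 20
    vals = []
    for seed in range(3):
        rng = np.random.default_rng(seed)
        A = rng.uniform(-500, 500, (n, 3))
        R = Rotation.from_rotvec(rng.uniform(-1, 1, 3)).as_matrix()
        B = A @ R.T + rng.uniform(-100, 100, 3)
        B = B + rng.normal(0.0, sigma, B.shape)
        _, rms = estimate_transform(A, B)
        vals.append(rms)
    expected = sigma * np.sqrt((3 * n - 6) / n)
    assert np.mean(vals) == pytest.approx(expected, rel=0.2)


def test_collinear_correspondences_rejected():
    A = np.column_stack([np.arange(10.0), np.zeros(10), np.zeros(10)])
    with pytest.raises(ValueError, match="collinear"):
        estimate_transform(A, A + 1.0)


def _toy_cloud(n, seed=0):
    rng = np.random.default_rng(seed)
    nr = rng.normal(size=(n, 3))
    nr /= np.linalg.norm(nr, axis=1, keepdims=True)
    return PointCloud(points=rng.uniform(-50, 50, (n, 3)),
                      intensity=rng.uniform(0, 1, n), normals=nr)


def test_merge_identity_passthrough():
    c = _toy_cloud(30)
    merged = merge_clouds([c], [RigidTransform.identity()])
    np.testing.assert_allclose(merged.points, c.points)
    np.testing.assert_allclose(merged.normals, c.normals)


def test_merge_counts_and_missing_transform():
    a, b = _toy_cloud(30, 0), _toy_cloud(20, 1)
    T = RigidTransform.identity()
    merged = merge_clouds([a, b], [T, T])
    assert len(merged) == 50
    with pytest.raises(ValueError):
        merge_clouds([a, b], [T])


def test_two_view_merge_overlap(head_and_model):
    """Two views of one plane, one expressed in a rotated frame, merge back
    into a single consistent surface."""
    setup, model = head_and_model
    cloud, _ = wf.reconstruct_plane(setup, model)
    T = RigidTransform.from_rotvec([0.2, 0.4, 0.1], [100.0, -50.0, 30.0])
    view_b = cloud.transform(T)               # same surface seen by head B
    merged = merge_clouds([cloud, view_b], [RigidTransform.identity(),
                                            T.inverse()])
    assert len(merged) == 2 * len(cloud)
    half = len(cloud)
    d = np.linalg.norm(merged.points[:half] - merged.points[half:], axis=1)
    assert np.median(d) < 1e-9


def test_round_trip_project_and_back(head_and_model):
    """Ground-truth points projected through the fitted camera return to
    themselves along the per-pixel rays."""
    setup, model = head_and_model
    rays = model.rays
    t = sim.plane_depth_map(setup.camera, [0, 0, 2500.0], [0.02, 0.01, -1.0])
    pts = rays * t[..., None]
    sel = np.isfinite(t)
    P = pts[sel][::37]
    cam = model.camera
    uv = cam.project(P)
    # viewing ray at the exact projected position
    x, y = cam.undistort_normalized((uv[:, 0] - cam.cx) / cam.fx,
                                    (uv[:, 1] - cam.cy) / cam.fy)
    d = np.column_stack([x, y, np.ones_like(x)])
    d /= np.linalg.norm(d, axis=1, keepdims=True)
    depth = np.einsum("ij,ij->i", P, d)
    back = d * depth[:, None]
    assert np.linalg.norm(back - P, axis=1).max() < 0.05
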