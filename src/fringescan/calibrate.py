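"""Camera and phase calibration, metric reconstruction, registration.

A directional head is calibrated in two local stages plus one global one:

1. **Camera calibration** — from images of a planar board with circular
   markers at several poses, a pinhole model with two radial distortion
   coefficients is fitted (homography/Zhang-style initialisation, joint
   nonlinear refinement) and expanded into a 3-D viewing ray per pixel.
2. **Phase calibration** — fringe images of the board at known depths
   give, per pixel, pairs (absolute phase, depth along the ray); a
   low-order polynomial (default cubic) maps phase to depth.  The
   mapping must be strictly monotone on the calibrated interval;
   non-monotone pixels are flagged invalid.
3. **Global registration** — corresponding 3-D marker centres seen by
   two heads give the rigid transform between them (closed-form SVD
   Procrustes with a reflection guard); clouds are merged into the
   global frame by applying the transforms only.

Units are millimetres throughout; the board pitch defines absolute scale.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from pathlib import Path

import numpy as np
from scipy.optimize import least_squares
from scipy.spatial.transform import Rotation
from skimage.filters import threshold_otsu
from skimage.measure import label

from .geometry import BoardSpec, CameraModel, RigidTransform

__all__ = [
    "BoardDetection", "detect_board_markers",
    "CameraCalibration", "calibrate_camera",
    "PhaseDepthModel", "fit_phase_to_depth", "calibrate_phase",
    "CalibrationModel", "PointCloud", "phase_to_cloud",
    "estimate_transform", "merge_clouds",
]


# --------------------------------------------------------------------------
# board marker detection


@dataclass
class BoardDetection:
    """Sub-pixel marker centroids; ``grid_indices`` is (n, 2) as
    (row, col) when association succeeded, else None."""

    uv: np.ndarray
    grid_indices: np.ndarray | None
    n_expected: int | None = None

    @property
    def complete(self) -> bool:
        return (self.n_expected is not None
                and self.uv.shape[0] == self.n_expected
                and self.grid_indices is not None)


def detect_board_markers(image: np.ndarray, board: BoardSpec | None = None,
                         min_area_px: int = 5) -> BoardDetection:
    """Detect dark circular markers and associate them to grid indices.

    Markers are segmented by Otsu thresholding; each blob's centre is the
    intensity-weighted (darkness-weighted) centroid, sub-pixel.  Blobs
    touching the image border (the background) are discarded.  With a
    ``board`` given and a complete detection, markers are ordered
    row-major by projecting centroids onto the grid's principal axes.
    """
    img = np.asarray(image, dtype=float)
    if np.ptp(img) == 0:
        return BoardDetection(uv=np.empty((0, 2)), grid_indices=None,
                              n_expected=None if board is None else board.rows * board.cols)
    thr = threshold_otsu(img)
    dark = img < thr
    labels, n = label(dark, return_num=True, connectivity=1)
    border_labels = np.unique(np.concatenate([
        labels[0, :], labels[-1, :], labels[:, 0], labels[:, -1]]))
    centers = []
    for lbl in range(1, n + 1):
        if lbl in border_labels:
            continue
        rr, cc = np.nonzero(labels == lbl)
        if rr.size < min_area_px:
            continue
        w = np.clip(thr - img[rr, cc], 0.0, None)
        if w.sum() == 0:
            continue
        u = float((cc * w).sum() / w.sum())
        v = float((rr * w).sum() / w.sum())
        centers.append((u, v))
    uv = np.asarray(centers, dtype=float).reshape(-1, 2)
    n_expected = None if board is None else board.rows * board.cols
    if board is None or uv.shape[0] != n_expected:
        return BoardDetection(uv=uv, grid_indices=None, n_expected=n_expected)

    # associate by ordering along the grid's principal axes
    X = uv - uv.mean(axis=0)
    cov = X.T @ X
    evals, evecs = np.linalg.eigh(cov)
    e_major, e_minor = evecs[:, 1], evecs[:, 0]
    # major axis spans the dimension with more markers
    if board.cols >= board.rows:
        e_col, e_row = e_major, e_minor
    else:
        e_col, e_row = e_minor, e_major
    if e_col[0] < 0:  # canonical: col index grows with u, row index with v
        e_col = -e_col
    e_row = np.array([-e_col[1], e_col[0]])
    if e_row[1] < 0:
        e_row = -e_row
    a = X @ e_col
    b = X @ e_row
    order = np.argsort(b, kind="stable")
    grid = np.empty((uv.shape[0], 2), dtype=int)
    out_order = []
    for i in range(board.rows):
        chunk = order[i * board.cols:(i + 1) * board.cols]
        chunk = chunk[np.argsort(a[chunk], kind="stable")]
        for j, k in enumerate(chunk):
            grid[len(out_order), 0] = i
            grid[len(out_order), 1] = j
            out_order.append(k)
    uv_sorted = uv[np.asarray(out_order)]
    return BoardDetection(uv=uv_sorted, grid_indices=grid, n_expected=n_expected)


# --------------------------------------------------------------------------
# camera calibration (homography init + nonlinear refinement)


def _homography_dlt(obj_xy: np.ndarray, uv: np.ndarray) -> np.ndarray:
    """Planar homography by normalized DLT."""
    def normalizer(p):
        m = p.mean(axis=0)
        s = np.sqrt(2.0) / np.mean(np.linalg.norm(p - m, axis=1))
        T = np.array([[s, 0, -s * m[0]], [0, s, -s * m[1]], [0, 0, 1.0]])
        return T

    Ta, Tb = normalizer(obj_xy), normalizer(uv)
    pa = (np.column_stack([obj_xy, np.ones(len(obj_xy))]) @ Ta.T)
    pb = (np.column_stack([uv, np.ones(len(uv))]) @ Tb.T)
    rows = []
    for (x, y, _), (u, v, _) in zip(pa, pb):
        rows.append([-x, -y, -1, 0, 0, 0, u * x, u * y, u])
        rows.append([0, 0, 0, -x, -y, -1, v * x, v * y, v])
    A = np.asarray(rows)
    _, _, Vt = np.linalg.svd(A)
    Hn = Vt[-1].reshape(3, 3)
    H = np.linalg.inv(Tb) @ Hn @ Ta
    return H / H[2, 2]


def _zhang_v(H: np.ndarray, i: int, j: int) -> np.ndarray:
    h = H
    return np.array([
        h[0, i] * h[0, j],
        h[0, i] * h[1, j] + h[1, i] * h[0, j],
        h[1, i] * h[1, j],
        h[2, i] * h[0, j] + h[0, i] * h[2, j],
        h[2, i] * h[1, j] + h[1, i] * h[2, j],
        h[2, i] * h[2, j],
    ])


def _zhang_intrinsics(homographies: list[np.ndarray]) -> tuple[float, float, float, float]:
    V = []
    for H in homographies:
        V.append(_zhang_v(H, 0, 1))
        V.append(_zhang_v(H, 0, 0) - _zhang_v(H, 1, 1))
    V = np.asarray(V)
    _, s, Vt = np.linalg.svd(V)
    if s[-1] > 1e-8 * s[0] and len(homographies) < 3:
        raise ValueError("not enough independent poses for intrinsics")
    if s[-2] < 1e-10 * s[0]:
        raise ValueError("degenerate pose set: homographies are not independent")
    b11, b12, b22, b13, b23, b33 = Vt[-1]
    denom = b11 * b22 - b12 * b12
    if abs(denom) < 1e-18 or abs(b11) < 1e-18:
        raise ValueError("degenerate pose set (singular intrinsic system)")
    v0 = (b12 * b13 - b11 * b23) / denom
    lam = b33 - (b13 * b13 + v0 * (b12 * b13 - b11 * b23)) / b11
    if lam / b11 <= 0 or lam * b11 / denom <= 0:
        raise ValueError("degenerate pose set (non-positive-definite intrinsics)")
    fx = float(np.sqrt(lam / b11))
    fy = float(np.sqrt(lam * b11 / denom))
    cy = float(v0)
    cx = float(-b13 * fx * fx / lam)
    return fx, fy, cx, cy


def _pose_from_homography(H: np.ndarray, K: np.ndarray) -> RigidTransform:
    Kinv = np.linalg.inv(K)
    h1, h2, h3 = H[:, 0], H[:, 1], H[:, 2]
    lam = 1.0 / np.linalg.norm(Kinv @ h1)
    r1 = lam * (Kinv @ h1)
    r2 = lam * (Kinv @ h2)
    t = lam * (Kinv @ h3)
    if t[2] < 0:
        r1, r2, t = -r1, -r2, -t
    r3 = np.cross(r1, r2)
    R = np.column_stack([r1, r2, r3])
    U, _, Vt = np.linalg.svd(R)
    R = U @ np.diag([1.0, 1.0, np.sign(np.linalg.det(U @ Vt))]) @ Vt
    return RigidTransform(R, t)


@dataclass
class CameraCalibration:
    camera: CameraModel
    poses: list[RigidTransform]
    reproj_rms_px: float
    per_pose_rms_px: np.ndarray = field(default_factory=lambda: np.empty(0))


def calibrate_camera(images: list[np.ndarray] | None, board: BoardSpec,
                     detections: list[np.ndarray] | None = None,
                     image_shape: tuple[int, int] | None = None,
                     fit_distortion: bool = True) -> CameraCalibration:
    """Fit a pinhole+radial camera to board observations at >= 3 poses.

    Either ``images`` (board photographs; markers are detected and
    associated here) or precomputed ``detections`` (list of (n, 2) pixel
    centres in board row-major order, with ``image_shape``) may be given.
    Intrinsics are initialised from the pose homographies and all
    parameters (fx, fy, cx, cy, k1, k2 and per-pose rotation/translation)
    are refined jointly by least squares on the reprojection error.

    Degenerate pose sets (e.g. repeated identical poses) are rejected.
    """
    obj = board.marker_centers()
    obj_xy = obj[:, :2]
    if detections is None:
        if not images:
            raise ValueError("no observations supplied")
        detections = []
        image_shape = images[0].shape
        for img in images:
            det = detect_board_markers(img, board)
            if not det.complete:
                raise ValueError(
                    f"incomplete marker detection ({det.uv.shape[0]} of "
                    f"{board.rows * board.cols})")
            detections.append(det.uv)
    if image_shape is None:
        raise ValueError("image_shape must be given with precomputed detections")
    if len(detections) < 3:
        raise ValueError("camera calibration needs at least 3 poses")

    homographies = [_homography_dlt(obj_xy, uv) for uv in detections]
    fx, fy, cx, cy = _zhang_intrinsics(homographies)
    K = np.array([[fx, 0, cx], [0, fy, cy], [0, 0, 1.0]])
    poses0 = [_pose_from_homography(H, K) for H in homographies]

    n_pose = len(detections)
    x0 = np.concatenate(
        [[fx, fy, cx, cy, 0.0, 0.0]]
        + [np.concatenate([Rotation.from_matrix(p.rotation).as_rotvec(),
                           p.translation]) for p in poses0])
    uv_all = np.concatenate(detections, axis=0)

    def unpack(x):
        cam = CameraModel(fx=x[0], fy=x[1], cx=x[2], cy=x[3],
                          k1=x[4] if fit_distortion else 0.0,
                          k2=x[5] if fit_distortion else 0.0,
                          image_shape=tuple(image_shape))
        poses = []
        for p in range(n_pose):
            seg = x[6 + 6 * p: 12 + 6 * p]
            poses.append((Rotation.from_rotvec(seg[:3]).as_matrix(), seg[3:]))
        return cam, poses

    def residuals(x):
        cam, poses = unpack(x)
        proj = []
        for R, t in poses:
            proj.append(cam.project(obj @ R.T + t))
        return (np.concatenate(proj, axis=0) - uv_all).ravel()

    sol = least_squares(residuals, x0, method="lm", xtol=1e-14, ftol=1e-14)
    cam, poses_rt = unpack(sol.x)
    res = residuals(sol.x).reshape(-1, 2)
    # per-axis RMS (u and v residual components pooled)
    per_pose = np.sqrt((res.reshape(n_pose, -1, 2) ** 2).mean(axis=(1, 2)))
    rms = float(np.sqrt((res ** 2).mean()))
    poses = []
    for R, t in poses_rt:
        U, _, Vt = np.linalg.svd(R)
        poses.append(RigidTransform(U @ np.diag([1, 1, np.sign(np.linalg.det(U @ Vt))]) @ Vt, t))
    return CameraCalibration(camera=cam, poses=poses, reproj_rms_px=rms,
                             per_pose_rms_px=per_pose)


# --------------------------------------------------------------------------
# phase-to-depth calibration


@dataclass
class PhaseDepthModel:
    """Per-pixel polynomial mapping absolute phase -> depth along the ray.

    Fitted in the scaled variable ``psi = (phi - phi_mid)/phi_scale`` for
    conditioning.  ``valid`` flags pixels whose mapping is well defined
    and strictly monotone on the calibrated interval [phi_lo, phi_hi].
    """

    coef: np.ndarray        # (rows, cols, degree+1), ascending powers of psi
    phi_mid: float
    phi_scale: float
    phi_lo: np.ndarray
    phi_hi: np.ndarray
    valid: np.ndarray

    @property
    def degree(self) -> int:
        return self.coef.shape[-1] - 1

    def evaluate(self, phase: np.ndarray, extrapolation_tol: float = 1e-6
                 ) -> np.ndarray:
        """Depth (mm) for an absolute phase map; NaN for invalid pixels
        and phases outside the calibrated interval."""
        phase = np.asarray(phase, dtype=float)
        if phase.shape != self.valid.shape:
            raise ValueError("phase raster does not match the calibrated grid")
        psi = (phase - self.phi_mid) / self.phi_scale
        depth = np.zeros_like(psi)
        for m in range(self.coef.shape[-1] - 1, -1, -1):
            depth = depth * psi + self.coef[..., m]
        ok = (self.valid & np.isfinite(phase)
              & (phase >= self.phi_lo - extrapolation_tol)
              & (phase <= self.phi_hi + extrapolation_tol))
        return np.where(ok, depth, np.nan)


def fit_phase_to_depth(phases: np.ndarray, depths: np.ndarray, degree: int = 3,
                       monotone_samples: int = 9) -> PhaseDepthModel:
    """Fit the per-pixel phase->depth polynomial from stacked observations.

    ``phases``/``depths`` have shape (n_poses, rows, cols): the absolute
    phase and the known depth along the pixel ray at each pose.  Pixels
    with fewer than ``degree+1`` finite observations, a singular fit, or
    a non-monotone fitted mapping on their phase interval are invalid.
    """
    phases = np.asarray(phases, dtype=float)
    depths = np.asarray(depths, dtype=float)
    if phases.shape != depths.shape or phases.ndim != 3:
        raise ValueError("phases and depths must share shape (poses, rows, cols)")
    n_pose = phases.shape[0]
    if n_pose < 3:
        raise ValueError("phase calibration needs >= 3 depth-separated poses")
    degree = min(degree, n_pose - 1)

    finite = np.isfinite(phases) & np.isfinite(depths)
    all_finite = phases[finite]
    if all_finite.size == 0:
        raise ValueError("no valid (phase, depth) observations")
    phi_mid = float(all_finite.mean())
    phi_scale = float(max(np.abs(all_finite - phi_mid).max(), 1.0))
    psi = np.where(finite, (phases - phi_mid) / phi_scale, 0.0)
    t = np.where(finite, depths, 0.0)
    w = finite.astype(float)

    nterm = degree + 1
    powers = np.stack([psi**m for m in range(nterm)])        # (nterm, P, R, C)
    M = np.einsum("ik...,jk...->...ij", powers * w, powers)   # (R, C, nterm, nterm)
    b = np.einsum("ik...,k...->...i", powers * w, t)          # (R, C, nterm)

    count = finite.sum(axis=0)
    enough = count >= nterm
    det = np.linalg.det(M)
    solvable = enough & (np.abs(det) > 1e-12)
    coef = np.zeros(M.shape[:-1])
    if solvable.any():
        coef_s = np.linalg.solve(M[solvable], b[solvable][..., None])
        coef[solvable] = coef_s[..., 0]

    import warnings as _warnings

    with np.errstate(all="ignore"), _warnings.catch_warnings():
        _warnings.filterwarnings("ignore", message="All-NaN slice")
        phi_lo = np.where(enough, np.nanmin(np.where(finite, phases, np.nan), axis=0), np.nan)
        phi_hi = np.where(enough, np.nanmax(np.where(finite, phases, np.nan), axis=0), np.nan)
    span_ok = solvable & ((phi_hi - phi_lo) > 1e-9)

    # strict monotonicity of the fitted polynomial on [phi_lo, phi_hi]
    psi_lo = (phi_lo - phi_mid) / phi_scale
    psi_hi = (phi_hi - phi_mid) / phi_scale
    deriv_sign_pos = np.ones(span_ok.shape, dtype=bool)
    deriv_sign_neg = np.ones(span_ok.shape, dtype=bool)
    for s in np.linspace(0.0, 1.0, monotone_samples):
        ps = psi_lo + s * (psi_hi - psi_lo)
        d = np.zeros_like(ps)
        for m in range(nterm - 1, 0, -1):
            d = d * ps + m * coef[..., m]
        deriv_sign_pos &= d > 0
        deriv_sign_neg &= d < 0
    monotone = deriv_sign_pos | deriv_sign_neg
    valid = span_ok & monotone
    return PhaseDepthModel(coef=coef, phi_mid=phi_mid, phi_scale=phi_scale,
                           phi_lo=phi_lo, phi_hi=phi_hi, valid=valid)


def calibrate_phase(images: list[np.ndarray], plane_depths_mm: list[float],
                    camera: CameraModel, config=None, degree: int = 3
                    ) -> PhaseDepthModel:
    """Phase calibration from fringe images of a fronto-parallel plane at
    known axial depths.

    Each image is run through the single-frame chain to an absolute phase
    map; the known plane depth is converted to depth along each pixel ray
    and the per-pixel polynomial is fitted.
    """
    from .pipeline import PipelineConfig, run_single_frame  # local: avoid cycle

    if len(images) != len(plane_depths_mm):
        raise ValueError("one plane depth per image required")
    if config is None:
        config = PipelineConfig()
    rays = camera.pixel_rays()
    fm_stack, t_stack = [], []
    for img, depth in zip(images, plane_depths_mm):
        frame = run_single_frame(img, config)
        fm_stack.append(frame.maps.Fm)
        t_stack.append(np.full(camera.image_shape, float(depth)) / rays[..., 2])
    return fit_phase_to_depth(np.stack(fm_stack), np.stack(t_stack), degree=degree)


# --------------------------------------------------------------------------
# point clouds


@dataclass
class CalibrationModel:
    """Complete single-head calibration: per-pixel rays + phase-to-depth."""

    camera: CameraModel
    phase_model: PhaseDepthModel

    @property
    def rays(self) -> np.ndarray:
        return self.camera.pixel_rays()

    @property
    def valid_region(self) -> np.ndarray:
        return self.phase_model.valid

    def save(self, path: str | Path) -> None:
        """Serialize as JSON (camera + scalars) plus an .npz coefficient
        container next to it."""
        import json

        path = Path(path)
        cam = self.camera
        meta = {
            "camera": {"fx": cam.fx, "fy": cam.fy, "cx": cam.cx, "cy": cam.cy,
                       "k1": cam.k1, "k2": cam.k2,
                       "image_shape": list(cam.image_shape)},
            "phase_model": {"phi_mid": self.phase_model.phi_mid,
                            "phi_scale": self.phase_model.phi_scale,
                            "degree": self.phase_model.degree},
            "arrays": path.stem + "_arrays.npz",
        }
        path.write_text(json.dumps(meta, indent=2))
        np.savez(path.with_name(meta["arrays"]),
                 coef=self.phase_model.coef, phi_lo=self.phase_model.phi_lo,
                 phi_hi=self.phase_model.phi_hi, valid=self.phase_model.valid)

    @classmethod
    def load(cls, path: str | Path) -> "CalibrationModel":
        import json

        path = Path(path)
        meta = json.loads(path.read_text())
        c = meta["camera"]
        cam = CameraModel(fx=c["fx"], fy=c["fy"], cx=c["cx"], cy=c["cy"],
                          k1=c["k1"], k2=c["k2"],
                          image_shape=tuple(c["image_shape"]))
        arrays = np.load(path.with_name(meta["arrays"]))
        pm = PhaseDepthModel(coef=arrays["coef"],
                             phi_mid=meta["phase_model"]["phi_mid"],
                             phi_scale=meta["phase_model"]["phi_scale"],
                             phi_lo=arrays["phi_lo"], phi_hi=arrays["phi_hi"],
                             valid=arrays["valid"])
        return cls(camera=cam, phase_model=pm)


@dataclass
class PointCloud:
    """Measured points in mm with per-point intensity and unit normal."""

    points: np.ndarray
    intensity: np.ndarray
    normals: np.ndarray
    source_pixel: np.ndarray | None = None   # (n, 2) as (row, col)
    grid_shape: tuple[int, int] | None = None

    def __post_init__(self) -> None:
        self.points = np.asarray(self.points, dtype=float).reshape(-1, 3)
        self.intensity = np.asarray(self.intensity, dtype=float).reshape(-1)
        self.normals = np.asarray(self.normals, dtype=float).reshape(-1, 3)
        if not np.all(np.isfinite(self.points)):
            raise ValueError("cloud points must be finite")

    def __len__(self) -> int:
        return self.points.shape[0]

    def transform(self, T: RigidTransform) -> "PointCloud":
        return PointCloud(points=T.apply(self.points),
                          intensity=self.intensity.copy(),
                          normals=T.rotate(self.normals),
                          source_pixel=None if self.source_pixel is None
                          else self.source_pixel.copy(),
                          grid_shape=self.grid_shape)


def phase_to_cloud(Fm: np.ndarray, intensity: np.ndarray,
                   model: CalibrationModel) -> tuple[PointCloud, int]:
    """Convert an absolute phase map to a metric point cloud.

    Per valid pixel the calibrated polynomial gives the depth along the
    pixel's ray; the point sits at ``depth * ray``.  Normals come from
    central differences of neighbouring pixels' (x, y, z), oriented
    toward the camera; pixels without enough neighbours fall back to the
    reversed viewing direction.  Returns the cloud and the number of
    pixels dropped for falling outside the calibrated phase interval.
    """
    Fm = np.asarray(Fm, dtype=float)
    if Fm.shape != tuple(model.camera.image_shape):
        raise ValueError("phase raster does not match the calibration grid")
    intensity = np.asarray(intensity, dtype=float)
    if intensity.shape != Fm.shape:
        raise ValueError("intensity raster does not match the phase raster")

    t = model.phase_model.evaluate(Fm)
    in_model = model.valid_region & np.isfinite(Fm)
    valid = np.isfinite(t)
    dropped = int(np.count_nonzero(in_model & ~valid))

    rays = model.rays
    pts_map = rays * t[..., None]
    dr = np.gradient(pts_map, axis=0)
    dc = np.gradient(pts_map, axis=1)
    n = np.cross(dc, dr)
    norm = np.linalg.norm(n, axis=-1, keepdims=True)
    with np.errstate(invalid="ignore"):
        n = n / norm
    bad_n = ~np.all(np.isfinite(n), axis=-1) | (norm[..., 0] == 0)
    n[bad_n] = -rays[bad_n]
    flip = np.einsum("...i,...i->...", n, rays) > 0
    n[flip] *= -1.0

    rr, cc = np.nonzero(valid)
    cloud = PointCloud(points=pts_map[rr, cc], intensity=intensity[rr, cc],
                       normals=n[rr, cc],
                       source_pixel=np.column_stack([rr, cc]),
                       grid_shape=Fm.shape)
    return cloud, dropped


# --------------------------------------------------------------------------
# registration and merging


def estimate_transform(points_a: np.ndarray, points_b: np.ndarray
                       ) -> tuple[RigidTransform, float]:
    """Least-squares rigid transform T with ``T(a) ~= b`` (SVD Procrustes).

    Proper rotation enforced (reflection guard).  Returns the transform
    and the RMS correspondence distance after alignment.  Requires >= 3
    non-collinear correspondences.
    """
    A = np.asarray(points_a, dtype=float).reshape(-1, 3)
    B = np.asarray(points_b, dtype=float).reshape(-1, 3)
    if A.shape != B.shape or A.shape[0] < 3:
        raise ValueError("need >= 3 corresponding 3-D points")
    Am, Bm = A.mean(axis=0), B.mean(axis=0)
    Ac, Bc = A - Am, B - Bm
    s = np.linalg.svd(Ac, compute_uv=False)
    if s[1] < 1e-8 * max(s[0], 1.0):
        raise ValueError("correspondences are collinear; transform is ambiguous")
    H = Ac.T @ Bc
    U, _, Vt = np.linalg.svd(H)
    d = np.sign(np.linalg.det(Vt.T @ U.T))
    R = Vt.T @ np.diag([1.0, 1.0, d]) @ U.T
    t = Bm - R @ Am
    T = RigidTransform(R, t)
    rms = float(np.sqrt(np.mean(np.sum((T.apply(A) - B) ** 2, axis=1))))
    return T, rms


def merge_clouds(clouds: list[PointCloud], transforms: list[RigidTransform]
                 ) -> PointCloud:
    """Concatenate clouds after mapping each into the global frame.

    No resampling and no deduplication — the transforms are applied,
    normals rotated, points concatenated.
    """
    if len(clouds) != len(transforms):
        raise ValueError("one transform per cloud is required")
    if not clouds:
        raise ValueError("no clouds to merge")
    moved = [c.transform(T) for c, T in zip(clouds, transforms)]
    return PointCloud(points=np.concatenate([c.points for c in moved]),
                      intensity=np.concatenate([c.intensity for c in moved]),
                      normals=np.concatenate([c.normals for c in moved]))
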