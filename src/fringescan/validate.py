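"""Error-analysis procedures for reconstructed board clouds.

Two measurements quantify the accuracy of a head's reconstruction of the
planar calibration artefact:

1. a total-least-squares plane is fitted to the cloud and the RMS of the
   orthogonal point-plane distances is reported (flatness error);
2. the distance between the two outermost marker centres on each board
   diagonal is measured as the mean of the outer-edge and inner-edge
   separations of those markers — for circular markers this average
   equals the centre distance and cancels any symmetric edge-blur bias.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import scipy.ndimage as ndi

from .calibrate import PointCloud, detect_board_markers
from .geometry import BoardSpec

__all__ = ["ValidationReport", "fit_plane", "fit_plane_rms", "fit_sphere",
           "outermost_marker_distance"]


@dataclass
class ValidationReport:
    plane_rms_mm: float
    diag_distance_1_mm: float
    diag_distance_2_mm: float
    expected_diag_mm: float
    details: dict = field(default_factory=dict)


def fit_plane(points: np.ndarray) -> tuple[np.ndarray, np.ndarray, float]:
    """Total-least-squares plane fit.

    Returns (centroid, unit normal, rms of orthogonal distances).
    Rejects degenerate (collinear or < 3 point) inputs.
    """
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if P.shape[0] < 3:
        raise ValueError("plane fit needs at least 3 points")
    c = P.mean(axis=0)
    Q = P - c
    _, s, Vt = np.linalg.svd(Q, full_matrices=False)
    if s[1] < 1e-10 * max(s[0], 1.0):
        raise ValueError("points are collinear; plane is not determined")
    n = Vt[2]
    rms = float(np.sqrt(np.mean((Q @ n) ** 2)))
    return c, n, rms


def fit_plane_rms(points: np.ndarray) -> float:
    """RMS orthogonal distance of the cloud to its best-fit plane, mm."""
    return fit_plane(points)[2]


def fit_sphere(points: np.ndarray) -> tuple[np.ndarray, float]:
    """Algebraic least-squares sphere fit: returns (centre, radius) in mm."""
    P = np.asarray(points, dtype=float).reshape(-1, 3)
    if P.shape[0] < 4:
        raise ValueError("sphere fit needs at least 4 points")
    A = np.column_stack([2.0 * P, np.ones(P.shape[0])])
    b = (P ** 2).sum(axis=1)
    sol, *_ = np.linalg.lstsq(A, b, rcond=None)
    center = sol[:3]
    radius = float(np.sqrt(sol[3] + center @ center))
    return center, radius


def _rasterize(cloud: PointCloud) -> tuple[np.ndarray, np.ndarray]:
    if cloud.source_pixel is None or cloud.grid_shape is None:
        raise ValueError("cloud must retain its source-pixel grid for "
                         "marker-edge measurements")
    shape = cloud.grid_shape
    intensity = np.full(shape, np.nan)
    xyz = np.full(shape + (3,), np.nan)
    rr, cc = cloud.source_pixel[:, 0], cloud.source_pixel[:, 1]
    intensity[rr, cc] = cloud.intensity
    xyz[rr, cc] = cloud.points
    return intensity, xyz


def _profile(values: np.ndarray, p0: np.ndarray, p1: np.ndarray, step: float = 0.25
             ) -> tuple[np.ndarray, np.ndarray]:
    """Bilinear profile along the pixel-space segment p0 -> p1 (as (u, v))."""
    length = float(np.hypot(*(p1 - p0)))
    n = max(int(np.ceil(length / step)) + 1, 2)
    s = np.linspace(0.0, length, n)
    d = (p1 - p0) / length
    u = p0[0] + s * d[0]
    v = p0[1] + s * d[1]
    vals = ndi.map_coordinates(values, np.vstack([v, u]), order=1,
                               mode="constant", cval=np.nan)
    return s, vals


def _edge_crossings(s: np.ndarray, vals: np.ndarray, level: float,
                    center_s: float) -> tuple[float, float]:
    """Sub-sample positions where the profile crosses ``level`` on either
    side of the marker dip at ``center_s`` (outer side first)."""
    below = vals < level
    ci = int(np.argmin(np.abs(s - center_s)))
    if not below[ci]:
        raise ValueError("marker dip not resolvable at the expected position")
    i = ci
    while i > 0 and below[i]:
        i -= 1
    if below[i]:
        raise ValueError("marker edge exits the profile")
    f = (level - vals[i]) / (vals[i + 1] - vals[i])
    s_left = s[i] + f * (s[i + 1] - s[i])
    j = ci
    while j < len(s) - 1 and below[j]:
        j += 1
    if below[j]:
        raise ValueError("marker edge exits the profile")
    f = (level - vals[j]) / (vals[j] - vals[j - 1])
    s_right = s[j] - f * (s[j] - s[j - 1])
    return s_left, s_right


def outermost_marker_distance(cloud: PointCloud, board: BoardSpec
                              ) -> tuple[float, float, dict]:
    """Diagonal lengths between the outermost marker centres, in mm.

    The marker grid is detected on the cloud's intensity raster; for each
    board diagonal, the intensity profile along the line joining the two
    outermost markers is thresholded at the half-contrast level, the
    outer- and inner-edge crossings of each marker are located to
    sub-sample precision, their 3-D positions are interpolated from the
    cloud grid, and the outer-edge and inner-edge separations are
    averaged into one diagonal length.
    """
    intensity, xyz = _rasterize(cloud)
    work = np.where(np.isfinite(intensity), intensity,
                    np.nanmax(intensity))
    det = detect_board_markers(work, board)
    if not det.complete:
        raise ValueError(
            f"markers not resolvable on the cloud intensity ({det.uv.shape[0]}"
            f" of {board.rows * board.cols} found)")
    uv = det.uv.reshape(board.rows, board.cols, 2)

    diag_pairs = [
        (uv[0, 0], uv[board.rows - 1, board.cols - 1]),
        (uv[0, board.cols - 1], uv[board.rows - 1, 0]),
    ]
    details: dict = {"diagonals": []}
    results = []
    for p0, p1 in diag_pairs:
        center_dist_px = float(np.hypot(*(p1 - p0)))
        # extend the profile beyond both marker centres
        marker_r_px = 0.75 * center_dist_px / np.hypot(board.rows - 1,
                                                       board.cols - 1)
        d = (p1 - p0) / center_dist_px
        a = p0 - d * 2 * marker_r_px
        b = p1 + d * 2 * marker_r_px
        s, vals = _profile(work, a, b, step=0.2)
        finite = np.isfinite(vals)
        hi = float(np.nanmedian(vals[finite]))
        lo = float(np.nanmin(vals[finite]))
        level = 0.5 * (hi + lo)
        s0 = 2 * marker_r_px
        s1 = 2 * marker_r_px + center_dist_px
        l0_out, l0_in = _edge_crossings(s, vals, level, s0)
        l1_in, l1_out = _edge_crossings(s, vals, level, s1)

        def point_at(si: float) -> np.ndarray:
            u = a[0] + d[0] * si
            v = a[1] + d[1] * si
            return np.array([
                ndi.map_coordinates(xyz[..., k], [[v], [u]], order=1)[0]
                for k in range(3)])

        outer = float(np.linalg.norm(point_at(l1_out) - point_at(l0_out)))
        inner = float(np.linalg.norm(point_at(l1_in) - point_at(l0_in)))
        results.append(0.5 * (outer + inner))
        details["diagonals"].append({"outer_mm": outer, "inner_mm": inner})
    return results[0], results[1], details
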