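"""Rigid transforms, the pinhole camera model, and the calibration board.

Shared geometric primitives.  All lengths are millimetres; pixel
coordinates are ``(u, v) = (column, row)`` with the origin at the centre
of pixel ``(0, 0)``.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

__all__ = ["RigidTransform", "CameraModel", "BoardSpec"]


@dataclass(frozen=True)
class RigidTransform:
    """Proper rigid motion ``X -> R @ X + t`` (rotation + translation, mm)."""

    rotation: np.ndarray
    translation: np.ndarray

    def __post_init__(self) -> None:
        R = np.asarray(self.rotation, dtype=float).reshape(3, 3)
        t = np.asarray(self.translation, dtype=float).reshape(3)
        object.__setattr__(self, "rotation", R)
        object.__setattr__(self, "translation", t)
        if not np.allclose(R.T @ R, np.eye(3), atol=1e-9):
            raise ValueError("rotation must be orthonormal (R^T R = I within 1e-9)")
        if np.linalg.det(R) < 0:
            raise ValueError("rotation must be proper (det = +1), not a reflection")

    @classmethod
    def identity(cls) -> "RigidTransform":
        return cls(np.eye(3), np.zeros(3))

    @classmethod
    def from_rotvec(cls, rotvec, translation) -> "RigidTransform":
        from scipy.spatial.transform import Rotation

        return cls(Rotation.from_rotvec(np.asarray(rotvec, float)).as_matrix(),
                   np.asarray(translation, float))

    def apply(self, points: np.ndarray) -> np.ndarray:
        pts = np.asarray(points, dtype=float)
        return pts @ self.rotation.T + self.translation

    def rotate(self, vectors: np.ndarray) -> np.ndarray:
        """Apply the rotation only (for directions and normals)."""
        return np.asarray(vectors, dtype=float) @ self.rotation.T

    def compose(self, other: "RigidTransform") -> "RigidTransform":
        """Return the transform applying ``other`` first, then ``self``."""
        return RigidTransform(self.rotation @ other.rotation,
                              self.rotation @ other.translation + self.translation)

    def inverse(self) -> "RigidTransform":
        return RigidTransform(self.rotation.T, -self.rotation.T @ self.translation)

    def as_matrix(self) -> np.ndarray:
        M = np.eye(4)
        M[:3, :3] = self.rotation
        M[:3, 3] = self.translation
        return M


@dataclass
class CameraModel:
    """Pinhole camera with two radial distortion coefficients.

    Projection of a camera-frame point ``(X, Y, Z)``::

        x = X/Z, y = Y/Z, r2 = x^2 + y^2
        d = 1 + k1*r2 + k2*r2^2
        u = fx * x * d + cx,  v = fy * y * d + cy
    """

    fx: float
    fy: float
    cx: float
    cy: float
    k1: float = 0.0
    k2: float = 0.0
    image_shape: tuple[int, int] = (0, 0)  # (rows, cols)
    _rays_cache: np.ndarray | None = field(default=None, repr=False, compare=False)

    def project(self, points: np.ndarray) -> np.ndarray:
        """Project camera-frame points (N, 3) to pixel coords (N, 2) as (u, v)."""
        P = np.asarray(points, dtype=float).reshape(-1, 3)
        if np.any(P[:, 2] <= 0):
            raise ValueError("points must be in front of the camera (Z > 0)")
        x = P[:, 0] / P[:, 2]
        y = P[:, 1] / P[:, 2]
        r2 = x * x + y * y
        d = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
        return np.column_stack([self.fx * x * d + self.cx, self.fy * y * d + self.cy])

    def undistort_normalized(self, xd: np.ndarray, yd: np.ndarray,
                             iterations: int = 25) -> tuple[np.ndarray, np.ndarray]:
        """Invert the radial distortion by fixed-point iteration."""
        x, y = np.array(xd, dtype=float), np.array(yd, dtype=float)
        for _ in range(iterations):
            r2 = x * x + y * y
            d = 1.0 + self.k1 * r2 + self.k2 * r2 * r2
            x = xd / d
            y = yd / d
        return x, y

    def pixel_rays(self) -> np.ndarray:
        """Unit viewing directions, shape (rows, cols, 3), camera frame.

        The ray of pixel (r, c) is ``origin 0 + t * dir``; ``t`` is the
        depth along the ray in mm.
        """
        if self._rays_cache is not None:
            return self._rays_cache
        rows, cols = self.image_shape
        if rows < 1 or cols < 1:
            raise ValueError("camera image_shape is not set")
        v, u = np.mgrid[0:rows, 0:cols].astype(float)
        xd = (u - self.cx) / self.fx
        yd = (v - self.cy) / self.fy
        x, y = self.undistort_normalized(xd, yd)
        dirs = np.stack([x, y, np.ones_like(x)], axis=-1)
        dirs /= np.linalg.norm(dirs, axis=-1, keepdims=True)
        self._rays_cache = dirs
        return dirs


@dataclass(frozen=True)
class BoardSpec:
    """Planar calibration artefact: white board, dark circular markers
    aligned in ``rows`` x ``cols`` with grid spacing ``pitch_mm``."""

    rows: int
    cols: int
    pitch_mm: float
    marker_diameter_mm: float
    board_size_mm: tuple[float, float] | None = None  # (width, height)

    def __post_init__(self) -> None:
        if self.rows * self.cols < 4:
            raise ValueError("board must carry at least 4 markers (rows*cols >= 4)")
        if not self.pitch_mm > self.marker_diameter_mm:
            raise ValueError("pitch must exceed the marker diameter")

    @property
    def size_mm(self) -> tuple[float, float]:
        if self.board_size_mm is not None:
            return self.board_size_mm
        return ((self.cols - 1) * self.pitch_mm + 2 * self.pitch_mm,
                (self.rows - 1) * self.pitch_mm + 2 * self.pitch_mm)

    def marker_centers(self) -> np.ndarray:
        """Marker centres (rows*cols, 3) in the board frame (z = 0), row-major,
        grid centred on the board origin; x runs along columns, y along rows."""
        j = np.arange(self.cols) - (self.cols - 1) / 2.0
        i = np.arange(self.rows) - (self.rows - 1) / 2.0
        jj, ii = np.meshgrid(j, i)
        x = (jj * self.pitch_mm).ravel()
        y = (ii * self.pitch_mm).ravel()
        return np.column_stack([x, y, np.zeros_like(x)])
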