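"""File I/O: grayscale images (PNG/TIFF, 8/16-bit), float maps, PLY clouds.

Intensity images are normalized to float in [0, 1] on read (dividing by
the dtype's full scale), so 8- and 16-bit captures of the same scene
process identically.  Point clouds are written as binary little-endian
PLY with per-vertex ``x y z nx ny nz intensity`` (float32), plus an
ASCII XYZ fallback.
"""

from __future__ import annotations

from pathlib import Path

import imageio.v3 as iio
import numpy as np
import tifffile

from .calibrate import PointCloud

__all__ = ["read_image", "write_image", "write_map", "read_map",
           "write_cloud_ply", "read_cloud_ply", "write_cloud_xyz"]

_PNG_EXT = {".png"}
_TIFF_EXT = {".tif", ".tiff"}


def read_image(path: str | Path) -> np.ndarray:
    """Read a grayscale image as float in [0, 1] (integer inputs are
    scaled by their dtype's full range; float TIFFs pass through)."""
    path = Path(path)
    ext = path.suffix.lower()
    if ext in _TIFF_EXT:
        arr = tifffile.imread(path)
    elif ext in _PNG_EXT:
        arr = iio.imread(path)
    else:
        raise ValueError(f"unsupported image format {ext!r} (use PNG or TIFF)")
    arr = np.asarray(arr)
    if arr.ndim == 3:
        arr = arr[..., 0]
    if arr.ndim != 2:
        raise ValueError(f"expected a 2-D grayscale image, got shape {arr.shape}")
    if np.issubdtype(arr.dtype, np.integer):
        return arr.astype(float) / float(np.iinfo(arr.dtype).max)
    return arr.astype(float)


def write_image(path: str | Path, image: np.ndarray, bits: int = 8) -> None:
    """Quantize a float [0, 1] raster to 8- or 16-bit grayscale."""
    path = Path(path)
    img = np.clip(np.asarray(image, dtype=float), 0.0, 1.0)
    if bits == 8:
        data = np.round(img * 255).astype(np.uint8)
    elif bits == 16:
        data = np.round(img * 65535).astype(np.uint16)
    else:
        raise ValueError("bits must be 8 or 16")
    ext = path.suffix.lower()
    if ext in _PNG_EXT:
        iio.imwrite(path, data)
    elif ext in _TIFF_EXT:
        tifffile.imwrite(path, data)
    else:
        raise ValueError(f"unsupported image format {ext!r} (use PNG or TIFF)")


def write_map(path: str | Path, values: np.ndarray) -> None:
    """Write a float map (phase, period, quality ...) as 32-bit TIFF."""
    tifffile.imwrite(Path(path), np.asarray(values, dtype=np.float32))


def read_map(path: str | Path) -> np.ndarray:
    return tifffile.imread(Path(path)).astype(float)


_PLY_PROPS = ["x", "y", "z", "nx", "ny", "nz", "intensity"]
# double for coordinates (mm-scale values round-trip below 1e-6),
# float for unit-scale normals and intensity
_PLY_TYPES = {"x": "double", "y": "double", "z": "double",
              "nx": "float", "ny": "float", "nz": "float",
              "intensity": "float"}
_NP_TYPES = {"double": "<f8", "float": "<f4"}


def write_cloud_ply(path: str | Path, cloud: PointCloud) -> None:
    """Binary little-endian PLY with x, y, z, nx, ny, nz, intensity."""
    n = len(cloud)
    header = "\n".join(
        ["ply", "format binary_little_endian 1.0",
         f"element vertex {n}"]
        + [f"property {_PLY_TYPES[p]} {p}" for p in _PLY_PROPS]
        + ["end_header", ""])
    rec = np.empty(n, dtype=np.dtype(
        [(p, _NP_TYPES[_PLY_TYPES[p]]) for p in _PLY_PROPS]))
    rec["x"], rec["y"], rec["z"] = cloud.points.T
    rec["nx"], rec["ny"], rec["nz"] = cloud.normals.T.astype(np.float32)
    rec["intensity"] = cloud.intensity.astype(np.float32)
    with open(path, "wb") as fh:
        fh.write(header.encode("ascii"))
        fh.write(rec.tobytes())


def read_cloud_ply(path: str | Path) -> PointCloud:
    with open(path, "rb") as fh:
        data = fh.read()
    end = data.find(b"end_header\n")
    if not data.startswith(b"ply") or end < 0:
        raise ValueError("not a PLY file")
    header = data[:end].decode("ascii").splitlines()
    n = None
    props = []
    types = []
    fmt = None
    for line in header:
        parts = line.split()
        if not parts:
            continue
        if parts[0] == "format":
            fmt = parts[1]
        elif parts[0] == "element" and parts[1] == "vertex":
            n = int(parts[2])
        elif parts[0] == "property":
            types.append(parts[1])
            props.append(parts[2])
    if fmt != "binary_little_endian":
        raise ValueError(f"unsupported PLY format {fmt!r}")
    if n is None or props != _PLY_PROPS:
        raise ValueError("unexpected PLY layout")
    body = data[end + len(b"end_header\n"):]
    rec = np.frombuffer(body, dtype=np.dtype(
        [(p, _NP_TYPES[t]) for p, t in zip(props, types)]), count=n)
    pts = np.column_stack([rec["x"], rec["y"], rec["z"]]).astype(float)
    nrm = np.column_stack([rec["nx"], rec["ny"], rec["nz"]]).astype(float)
    return PointCloud(points=pts, intensity=rec["intensity"].astype(float),
                      normals=nrm)


def write_cloud_xyz(path: str | Path, cloud: PointCloud) -> None:
    """ASCII fallback: one ``x y z`` line per point."""
    np.savetxt(Path(path), cloud.points, fmt="%.6f")
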