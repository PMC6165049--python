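"""Marker fringe detection and absolute phase recovery.

The projected pattern carries one transversely modulated fringe (the
*marker*) at a known projector-side fringe index ``N``.  Locating it in
the camera image anchors the relative unwrapped phase ``Um`` to an
absolute phase map ``Fm``:

    median  = median of Um under the marker pixels
    Phi_x   = 2*pi * (N - floor((median + pi) / (2*pi)))
    Fm      = Um + Phi_x

``Phi_x`` is by construction an exact integer multiple of 2*pi, so the
global 2*pi*k ambiguity left by unwrapping cancels regardless of the
unwrapping seed.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np
from skimage.measure import label

from .patterns import TWO_PI, PatternSpec

__all__ = ["MarkerResult", "MarkerNotFoundError", "detect_marker",
           "compute_phase_shift", "recover_absolute_phase"]


class MarkerNotFoundError(RuntimeError):
    """No marker modulation found in the expected frequency band."""


@dataclass
class MarkerResult:
    Mm: np.ndarray                # boolean marker-pixel raster
    median_phase: float           # median of Um under Mm, radians
    phase_shift: float            # Phi_x, an exact multiple of 2*pi
    Fm: np.ndarray                # absolute phase, radians


def detect_marker(image: np.ndarray, Om: np.ndarray, spec: PatternSpec,
                  band_halfwidth_frac: float = 0.2,
                  rel_threshold: float = 0.5,
                  min_magnitude: float = 0.02) -> np.ndarray:
    """Locate the marker fringe by 1-D FFT band filtering along the fringes.

    Each image line along the fringe direction is Fourier transformed;
    only the band around the marker modulation frequency
    ``1/marker_mod_period_px`` (half-width ``band_halfwidth_frac`` of it)
    is kept, and the inverse transform's magnitude (the modulation
    envelope) is thresholded at ``rel_threshold`` of its peak.  The
    largest connected segment is returned as the marker mask ``Mm``.

    The transform is applied to the *local fringe amplitude* (max - min
    over a window along the fringe normal) rather than the raw image: on
    a curved surface the geometry bends the carrier into row-direction
    oscillations that sweep through the marker band, whereas the
    demodulated amplitude carries only the marker's transverse
    modulation.

    Raises :class:`MarkerNotFoundError` when the envelope peak stays
    below ``min_magnitude`` (intensity units) — distinguishing a scene
    without a marker from a filtering failure.
    """
    if spec.marker_index is None:
        raise ValueError("pattern spec carries no marker fringe")
    img = np.asarray(image, dtype=float)
    Om = np.asarray(Om, dtype=bool)
    if spec.orientation == "horizontal":
        img, Om = img.T, Om.T

    import scipy.ndimage as ndi

    n = img.shape[0]  # fringe direction = rows for vertical fringes
    w = int(round(1.5 * spec.period_px)) | 1
    amp = (ndi.maximum_filter(img, size=(1, w), mode="nearest")
           - ndi.minimum_filter(img, size=(1, w), mode="nearest"))
    cnt = Om.sum(axis=0)
    masked = np.where(Om, amp, 0.0)
    with np.errstate(invalid="ignore", divide="ignore"):
        col_mean = np.where(cnt > 0, masked.sum(axis=0) / np.maximum(cnt, 1), 0.0)
    x = np.where(Om, amp - col_mean[None, :], 0.0)

    f0 = 1.0 / spec.mod_period_px
    freqs = np.fft.fftfreq(n)
    band = np.abs(freqs - f0) <= band_halfwidth_frac * f0  # positive band only
    F = np.fft.fft(x, axis=0)
    F[~band, :] = 0.0
    envelope = 2.0 * np.abs(np.fft.ifft(F, axis=0))

    envelope = np.where(Om, envelope, 0.0)
    peak = envelope.max()
    if peak < min_magnitude:
        raise MarkerNotFoundError(
            f"marker modulation envelope peak {peak:.4g} below {min_magnitude:.4g}")
    mm = envelope >= rel_threshold * peak
    labels, nseg = label(mm, return_num=True, connectivity=1)
    if nseg == 0:
        raise MarkerNotFoundError("no segment above threshold")
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    Mm = labels == counts.argmax()
    return Mm.T if spec.orientation == "horizontal" else Mm


def compute_phase_shift(Um: np.ndarray, Mm: np.ndarray, N: int
                        ) -> tuple[float, float]:
    """Absolute phase shift from the marker pixels.

    Returns ``(Phi_x, median)`` where ``median`` is the median of the
    unwrapped phase under the marker mask and
    ``Phi_x = 2*pi*(N - floor((median + pi)/(2*pi)))``.
    """
    Um = np.asarray(Um, dtype=float)
    Mm = np.asarray(Mm, dtype=bool)
    vals = Um[Mm & np.isfinite(Um)]
    if vals.size == 0:
        raise ValueError("marker mask is empty or has no valid unwrapped phase")
    med = float(np.median(vals))
    phi_x = TWO_PI * (N - math.floor((med + math.pi) / TWO_PI))
    return phi_x, med


def recover_absolute_phase(image: np.ndarray, Om: np.ndarray, Um: np.ndarray,
                           spec: PatternSpec,
                           component_map: np.ndarray | None = None,
                           **detect_kwargs) -> MarkerResult:
    """Detect the marker and emit the absolute phase map ``Fm = Um + Phi_x``.

    When the unwrapper's ``component_map`` is given, ``Fm`` is restricted
    to the connected components that intersect the marker mask: the
    marker cannot anchor a region it is not connected to, so the
    absolute phase is undefined (NaN) there.
    """
    Mm = detect_marker(image, Om, spec, **detect_kwargs)
    phi_x, med = compute_phase_shift(Um, Mm, spec.marker_index)
    Fm = Um + phi_x
    if component_map is not None:
        anchored = np.unique(component_map[Mm & (component_map >= 0)])
        Fm = np.where(np.isin(component_map, anchored), Fm, np.nan)
    return MarkerResult(Mm=Mm, median_phase=med, phase_shift=phi_x, Fm=Fm)
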