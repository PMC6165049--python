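"""Projected fringe patterns.

A sinusoidal fringe field with one distinguished *marker* fringe whose
amplitude is modulated transversely (i.e. along the fringe direction).
The marker anchors the absolute phase of a single-frame measurement:
after unwrapping, the known projector-side fringe index ``N`` of the
marker converts the relative phase map into an absolute one.

Conventions
-----------
Rasters are row-major, 0-based, indexed ``(row, col)``.  Fringes are
nominally vertical: for ``orientation="vertical"`` the carrier phase
varies along columns, ``phi(c) = 2*pi*c / period_px``, and the marker
modulation runs along rows.  ``orientation="horizontal"`` is the exact
transpose.  The marker fringe ``N`` is the fringe whose intensity crest
sits at column ``N * period_px``.
"""

from __future__ import annotations

import math
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * math.pi

__all__ = ["PatternSpec", "generate_pattern", "marker_amplitude_factor"]


@dataclass(frozen=True)
class PatternSpec:
    """Parameters of the projected pattern.

    Parameters
    ----------
    width_px, height_px
        Raster size of the projected pattern.
    period_px
        Fringe period on the projector raster, pixels.
    marker_index
        Index ``N`` of the marker fringe (crest at column ``N*period_px``),
        or ``None`` for a plain, marker-free sine pattern.
    marker_mod_period_px
        Period of the transverse amplitude modulation along the marker
        fringe.  Defaults to ``4 * period_px``; must differ from
        ``period_px`` so the marker is separable by 1-D FFT filtering.
    marker_depth
        Peak relative amplitude reduction of the marker modulation,
        in (0, 1].
    marker_envelope_halfwidth_periods
        Half-width, in fringe periods, of the raised-cosine envelope that
        confines the modulation around the marker crest.  A smooth,
        gradual roll-off (default 1.5 periods, emulating projector
        defocus) keeps the spatial-carrier phase estimate unbiased
        through the marker band.
    orientation
        ``"vertical"`` (phase varies along columns) or ``"horizontal"``.
    """

    width_px: int
    height_px: int
    period_px: float = 16.0
    marker_index: int | None = None
    marker_mod_period_px: float | None = None
    marker_depth: float = 0.5
    marker_envelope_halfwidth_periods: float = 1.5
    orientation: str = "vertical"

    def __post_init__(self) -> None:
        if self.width_px < 1 or self.height_px < 1:
            raise ValueError("pattern size must be at least 1x1")
        if not self.period_px > 0:
            raise ValueError("period_px must be > 0")
        if self.orientation not in ("vertical", "horizontal"):
            raise ValueError(
                f"orientation must be 'vertical' or 'horizontal', got {self.orientation!r}"
            )
        if self.marker_index is not None:
            extent = self.width_px if self.orientation == "vertical" else self.height_px
            n_fringes = math.floor(extent / self.period_px)
            if not 0 <= self.marker_index < n_fringes:
                raise ValueError(
                    f"marker_index must satisfy 0 <= N < floor(extent/period) = {n_fringes}, "
                    f"got {self.marker_index}"
                )
            if math.isclose(self.mod_period_px, self.period_px):
                raise ValueError(
                    "marker_mod_period_px must differ from period_px so the marker "
                    "band is separable in frequency"
                )
            if not 0.0 < self.marker_depth <= 1.0:
                raise ValueError("marker_depth must lie in (0, 1]")
            if not self.marker_envelope_halfwidth_periods > 0:
                raise ValueError("marker envelope half-width must be > 0")

    @property
    def mod_period_px(self) -> float:
        """Effective transverse modulation period (default ``4*period_px``)."""
        if self.marker_mod_period_px is not None:
            return float(self.marker_mod_period_px)
        return 4.0 * float(self.period_px)


def marker_amplitude_factor(
    phase: np.ndarray, along: np.ndarray, spec: PatternSpec
) -> np.ndarray:
    """Multiplicative fringe-amplitude factor encoding the marker.

    ``phase`` is the absolute carrier phase in radians; ``along`` is the
    coordinate along the fringe direction in pixels.  Outside the marker
    band the factor is 1.  Inside (|phase - 2*pi*N| within the envelope
    half-width) the amplitude is reduced by up to ``marker_depth``, with
    a raised-cosine envelope across the fringes, centred on the marker
    crest, and a sinusoidal modulation of period ``mod_period_px`` along
    the fringe.
    """
    if spec.marker_index is None:
        return np.ones(np.broadcast(phase, along).shape)
    delta = np.asarray(phase, dtype=float) - TWO_PI * spec.marker_index
    width = TWO_PI * spec.marker_envelope_halfwidth_periods
    envelope = np.where(np.abs(delta) <= width,
                        0.5 * (1.0 + np.cos(np.pi * delta / width)), 0.0)
    transverse = 0.5 * (1.0 + np.cos(TWO_PI * np.asarray(along, dtype=float) / spec.mod_period_px))
    return 1.0 - spec.marker_depth * envelope * transverse


def generate_pattern(spec: PatternSpec) -> np.ndarray:
    """Render the pattern as a float raster in [0, 1].

    Non-marker fringes follow ``I = 0.5 + 0.5*cos(2*pi*c/period_px)``
    (vertical orientation); the marker fringe's amplitude is additionally
    modulated along its length.  Bit-exactly reproducible from ``spec``.
    """
    if spec.orientation == "horizontal":
        transposed = PatternSpec(
            width_px=spec.height_px,
            height_px=spec.width_px,
            period_px=spec.period_px,
            marker_index=spec.marker_index,
            marker_mod_period_px=spec.marker_mod_period_px,
            marker_depth=spec.marker_depth,
            orientation="vertical",
        )
        return generate_pattern(transposed).T

    rows = np.arange(spec.height_px, dtype=float)[:, None]
    cols = np.arange(spec.width_px, dtype=float)[None, :]
    phase = TWO_PI * cols / spec.period_px
    amp = marker_amplitude_factor(phase, rows, spec)
    return 0.5 + 0.5 * amp * np.cos(phase)
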