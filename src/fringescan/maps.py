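"""Per-pixel maps of the single-frame processing chain.

From one fringe image the following rasters are derived, all sharing the
input grid (invalid/off-object pixels are NaN, the object mask is bool):

==== =======================================================================
Om   object mask (overexposure cut, Otsu threshold, closing, largest blob)
Pm   local fringe period, px, from median-threshold crossings
Am   local fringe amplitude (max - min of the local intensity)
Sm   period stability, 1 - normalized windowed variance of Pm
Wm   wrapped phase in [-pi, pi) from 7-sample spatial-carrier phase shifting
Vm   fringe verticality, gradH / (gradH + gradV) on windowed gradient sums
Bm   border map, normalized blur of Om (1 deep inside, ~0.5 on the edge)
Qm   quality, weighted arithmetic mean of powers of Bm, Am, Vm, Sm
==== =======================================================================

Fringes are nominally vertical: the fringe-normal direction is along
columns (axis 1).  Transpose the image first for horizontal fringes.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass

import numpy as np
import scipy.ndimage as ndi
from skimage.filters import threshold_otsu
from skimage.measure import label
from skimage.morphology import dilation, disk, erosion

__all__ = [
    "MapStack", "QualityWeights",
    "compute_object_mask", "compute_period_amplitude", "compute_stability",
    "compute_wrapped_phase", "compute_verticality", "compute_border",
    "compute_quality", "normalize_map",
]

TWO_PI = 2.0 * np.pi


@dataclass
class MapStack:
    """Container for the per-pixel maps of one frame (filled progressively)."""

    image: np.ndarray
    Om: np.ndarray | None = None
    Pm: np.ndarray | None = None
    Am: np.ndarray | None = None
    Sm: np.ndarray | None = None
    Wm: np.ndarray | None = None
    Vm: np.ndarray | None = None
    Bm: np.ndarray | None = None
    Qm: np.ndarray | None = None
    Mm: np.ndarray | None = None
    Um: np.ndarray | None = None
    Fm: np.ndarray | None = None


@dataclass(frozen=True)
class QualityWeights:
    """Weights and exponents of the quality map combination.

    Defaults are the values established for human-body measurement:
    bw=1, aw=5, vw=3, sw=1 and be=1, ae=2, ve=1, se=1 — the amplitude map
    dominates, and its squaring steepens the quality gradient so that
    low-contrast regions are unwrapped last.
    """

    bw: float = 1.0
    aw: float = 5.0
    vw: float = 3.0
    sw: float = 1.0
    be: float = 1.0
    ae: float = 2.0
    ve: float = 1.0
    se: float = 1.0

    def __post_init__(self) -> None:
        if min(self.bw, self.aw, self.vw, self.sw) < 0:
            raise ValueError("map weights must be >= 0")
        if not self.bw + self.aw + self.vw + self.sw > 0:
            raise ValueError("at least one map weight must be positive")
        if min(self.be, self.ae, self.ve, self.se) <= 0:
            raise ValueError("map exponents must be > 0")


def _odd(n: int) -> int:
    n = max(int(n), 1)
    return n if n % 2 == 1 else n + 1


# --------------------------------------------------------------------------
# object mask


def compute_object_mask(image: np.ndarray,
                        overexposure_level: float = 0.98,
                        closing_radius: int | None = None,
                        nominal_period_px: float = 16.0,
                        mask_source: str = "intensity",
                        mask_threshold: float | None = None) -> np.ndarray:
    """Separate the fringe-covered object from the background.

    Overexposed pixels (``>= overexposure_level``) are removed, an Otsu
    threshold (or the explicit ``mask_threshold``) is applied, a
    morphological closing (dilation then erosion; default radius
    0.6x the fringe period, enough to bridge dark fringe troughs) smooths
    the contour, and only the largest connected segment is kept.

    An all-background image yields an empty mask with a warning, never a
    crash.
    """
    img = np.asarray(image, dtype=float)
    if img.size == 0:
        raise ValueError("image is empty")
    not_over = img < overexposure_level
    if mask_source == "contrast":
        w = _odd(round(1.5 * nominal_period_px))
        src = (ndi.maximum_filter(img, size=(1, w), mode="nearest")
               - ndi.minimum_filter(img, size=(1, w), mode="nearest"))
    elif mask_source == "intensity":
        src = img
    else:
        raise ValueError("mask_source must be 'intensity' or 'contrast'")

    candidates = src[not_over]
    if mask_threshold is not None:
        thr = float(mask_threshold)
    else:
        if candidates.size == 0 or np.ptp(candidates) == 0:
            warnings.warn("object mask is empty: image has no contrast")
            return np.zeros(img.shape, dtype=bool)
        thr = threshold_otsu(candidates)
    fg = (src > thr) & not_over
    if not fg.any():
        warnings.warn("object mask is empty: nothing above threshold")
        return fg

    if closing_radius is None:
        closing_radius = max(1, int(round(0.6 * nominal_period_px)))
    if closing_radius > 0:
        selem = disk(closing_radius)
        fg = erosion(dilation(fg, selem), selem)
    labels, n = label(fg, return_num=True, connectivity=1)
    if n == 0:
        warnings.warn("object mask is empty after morphology")
        return np.zeros(img.shape, dtype=bool)
    counts = np.bincount(labels.ravel())
    counts[0] = 0
    return labels == counts.argmax()


# --------------------------------------------------------------------------
# period and amplitude


def compute_period_amplitude(image: np.ndarray, Om: np.ndarray,
                             nominal_period_px: float = 16.0,
                             window_px: int | None = None,
                             min_amplitude: float = 0.05
                             ) -> tuple[np.ndarray, np.ndarray]:
    """Local fringe period ``Pm`` and amplitude ``Am`` along the fringe normal.

    Per object pixel a 1-D profile perpendicular to the fringes is
    binarized at the local median intensity; the distance spanned by the
    above/below cycle around the pixel (second crossing to the right of
    the last crossing at or left of the pixel, sub-pixel by linear
    interpolation) gives the period.  ``Am`` is local max - local min.
    Pixels whose neighbourhood has no full cycle, or whose amplitude is
    below ``min_amplitude``, are invalid (NaN) in ``Pm``.
    """
    img = np.asarray(image, dtype=float)
    Om = np.asarray(Om, dtype=bool)
    if not Om.any():
        raise ValueError("object mask is empty")
    if window_px is None:
        window_px = _odd(round(1.5 * nominal_period_px))

    med = ndi.median_filter(img, size=(1, window_px), mode="nearest")
    mx = ndi.maximum_filter(img, size=(1, window_px), mode="nearest")
    mn = ndi.minimum_filter(img, size=(1, window_px), mode="nearest")
    Am = np.where(Om, mx - mn, np.nan)

    g = img - med
    Pm = np.full(img.shape, np.nan)
    n_rows, n_cols = img.shape
    cols = np.arange(n_cols)
    for r in range(n_rows):
        if not Om[r].any():
            continue
        gr = g[r]
        sign = gr >= 0
        idx = np.nonzero(sign[:-1] != sign[1:])[0]
        if idx.size < 3:
            continue
        denom = gr[idx] - gr[idx + 1]
        frac = np.where(denom != 0, gr[idx] / denom, 0.5)
        crossings = idx + frac
        pos = np.searchsorted(crossings, cols, side="right")
        ok = (pos >= 1) & (pos + 1 < crossings.size)
        pos_c = np.clip(pos, 1, crossings.size - 2)
        period = crossings[pos_c + 1] - crossings[pos_c - 1]
        row_vals = np.where(ok & Om[r], period, np.nan)
        Pm[r] = row_vals

    with np.errstate(invalid="ignore"):
        Pm[(Am < min_amplitude) | (Pm < 2.0) | (Pm > 2.0 * window_px)] = np.nan
    # the local-median estimate needs real data across its whole window;
    # border replication biases crossings within half a window of the edge,
    # and any pixel within one period of those uses a biased crossing
    margin = window_px // 2 + int(np.ceil(nominal_period_px))
    Pm[:, :margin] = np.nan
    Pm[:, n_cols - margin:] = np.nan
    return Pm, Am


# --------------------------------------------------------------------------
# masked windowed statistics helper


def _masked_window_moments(values: np.ndarray, valid: np.ndarray, size: int,
                           axis: int) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Windowed mean and variance of ``values`` over ``valid`` pixels."""
    v = np.where(valid, values, 0.0)
    cnt = ndi.uniform_filter1d(valid.astype(float), size, axis=axis, mode="constant") * size
    s1 = ndi.uniform_filter1d(v, size, axis=axis, mode="constant") * size
    s2 = ndi.uniform_filter1d(v * v, size, axis=axis, mode="constant") * size
    with np.errstate(invalid="ignore", divide="ignore"):
        mean = s1 / cnt
        var = np.clip(s2 / cnt - mean * mean, 0.0, None)
    return mean, var, cnt


def compute_stability(Pm: np.ndarray, window_px: np.ndarray | int | None = None
                      ) -> np.ndarray:
    """Period-stability map from the windowed variance of ``Pm``.

    The variance of the period is taken along the fringe-normal direction
    over a window of one local fringe period (rounded), then mapped to
    [0, 1] as ``Sm = 1 - var / var_max`` so that zero variance is maximal
    stability.  Invalid ``Pm`` pixels stay invalid.
    """
    Pm = np.asarray(Pm, dtype=float)
    valid = np.isfinite(Pm)
    if not valid.any():
        raise ValueError("Pm has no valid pixels")
    if window_px is None:
        w_map = np.round(np.where(valid, Pm, 3.0)).astype(int)
    elif np.isscalar(window_px):
        w_map = np.full(Pm.shape, int(window_px))
    else:
        w_map = np.round(np.asarray(window_px)).astype(int)
    w_map = np.clip(w_map, 2, max(3, min(Pm.shape[1], 128)))

    var = np.full(Pm.shape, np.nan)
    for w in np.unique(w_map[valid]):
        _, v_w, cnt = _masked_window_moments(Pm, valid, int(w), axis=1)
        sel = valid & (w_map == w) & (cnt >= max(2.0, 0.5 * w))
        var[sel] = v_w[sel]
    ok = np.isfinite(var)
    if not ok.any():
        return np.where(valid, 1.0, np.nan)
    vmax = var[ok].max()
    if vmax == 0:
        Sm = np.where(ok, 1.0, np.nan)
    else:
        Sm = np.where(ok, 1.0 - var / vmax, np.nan)
    return Sm


# --------------------------------------------------------------------------
# wrapped phase (7-sample spatial-carrier phase shifting)

_SCPS_OFFSETS = np.arange(-3, 4)  # nominal pi/2 steps


def compute_wrapped_phase(image: np.ndarray, Om: np.ndarray, Pm: np.ndarray
                          ) -> np.ndarray:
    """Wrapped phase ``Wm`` in [-pi, pi) by 7-sample SCPS.

    Seven intensity samples are taken along the fringe normal through
    each pixel, spaced a quarter of the *local* period ``Pm`` (nominal
    pi/2 phase steps), linearly interpolated at non-integer coordinates.
    The symmetric seven-sample estimator::

        tan(phi) = (-I-3 + 7 I-1 - 7 I+1 + I+3) / (-4 I-2 + 8 I0 - 4 I+2)

    is exact on a pure sinusoid sampled at the correct period and is
    second-order insensitive to a misestimated period.  Pixels whose
    sampling window leaves the object mask (or the image) are invalid.
    """
    img = np.asarray(image, dtype=float)
    Om = np.asarray(Om, dtype=bool)
    Pm = np.asarray(Pm, dtype=float)
    valid = Om & np.isfinite(Pm)
    Wm = np.full(img.shape, np.nan)
    if not valid.any():
        return Wm

    rr, cc = np.nonzero(valid)
    step = Pm[rr, cc] / 4.0
    om_f = Om.astype(float)
    samples = np.empty((7, rr.size))
    inside = np.ones(rr.size, dtype=bool)
    for i, k in enumerate(_SCPS_OFFSETS):
        coords = np.vstack([rr.astype(float), cc + k * step])
        samples[i] = ndi.map_coordinates(img, coords, order=1, mode="constant",
                                         cval=np.nan)
        cover = ndi.map_coordinates(om_f, coords, order=1, mode="constant",
                                    cval=0.0)
        inside &= cover >= 0.999
    inside &= np.all(np.isfinite(samples), axis=0)

    num = -samples[0] + 7.0 * samples[2] - 7.0 * samples[4] + samples[6]
    den = -4.0 * samples[1] + 8.0 * samples[3] - 4.0 * samples[5]
    phi = np.arctan2(num, den)
    phi = np.where(phi >= np.pi, phi - TWO_PI, phi)  # [-pi, pi)
    Wm[rr[inside], cc[inside]] = phi[inside]
    return Wm


# --------------------------------------------------------------------------
# verticality


def _window_sum_of_diffs(absdiff: np.ndarray, w: int, axis: int) -> np.ndarray:
    """Sum of 2w consecutive absolute differences centred on each pixel.

    For axis=0 this realizes
    ``gradV(r,c) = sum_{i=r+1}^{r+w}|I(i,c)-I(i-1,c)| + sum_{i=r-w}^{r-1}|I(i,c)-I(i+1,c)|``
    which reduces to the sum of the difference terms D[j] = |I[j+1]-I[j]|
    for j in [r-w, r+w-1].  NaN where the window leaves the image.
    """
    n = absdiff.shape[axis]
    csum = np.cumsum(absdiff, axis=axis)
    pad = [(0, 0), (0, 0)]
    pad[axis] = (1, 0)
    csum = np.pad(csum, pad)  # csum[k] = sum of first k diffs
    out_len = n + 1  # number of pixels along the axis
    out = np.full((out_len if axis == 0 else absdiff.shape[0],
                   out_len if axis == 1 else absdiff.shape[1]), np.nan)
    lo = w
    hi = out_len - 1 - w  # inclusive pixel index range with a full window
    if hi < lo:
        return out
    sl_out = [slice(None), slice(None)]
    sl_a = [slice(None), slice(None)]
    sl_b = [slice(None), slice(None)]
    sl_out[axis] = slice(lo, hi + 1)
    sl_a[axis] = slice(2 * w, n + 1)
    sl_b[axis] = slice(0, n + 1 - 2 * w)
    out[tuple(sl_out)] = csum[tuple(sl_a)] - csum[tuple(sl_b)]
    return out


def compute_verticality(image: np.ndarray, Om: np.ndarray, Pm: np.ndarray
                        ) -> np.ndarray:
    """Fringe-verticality map ``Vm = gradH / (gradH + gradV)`` in [0, 1].

    ``gradV``/``gradH`` are windowed sums of absolute row-/column-wise
    intensity differences with window ``w = round(Pm)`` (the local fringe
    period).  Perfectly vertical fringes give 1, horizontal 0; both
    gradients zero gives 0.  Pixels with ``w < 1`` or a window leaving
    the image are invalid.
    """
    img = np.asarray(image, dtype=float)
    Om = np.asarray(Om, dtype=bool)
    Pm = np.asarray(Pm, dtype=float)
    valid = Om & np.isfinite(Pm)
    Vm = np.full(img.shape, np.nan)
    if not valid.any():
        return Vm
    dv = np.abs(np.diff(img, axis=0))
    dh = np.abs(np.diff(img, axis=1))
    ws = np.unique(np.round(Pm[valid]).astype(int))
    for w in ws:
        if w < 1:
            continue
        gv = _window_sum_of_diffs(dv, int(w), axis=0)
        gh = _window_sum_of_diffs(dh, int(w), axis=1)
        sel = valid & (np.round(Pm) == w)
        with np.errstate(invalid="ignore", divide="ignore"):
            v = np.where(gh + gv > 0, gh / (gh + gv), 0.0)
        v = np.where(np.isfinite(gh) & np.isfinite(gv), v, np.nan)
        Vm[sel] = v[sel]
    return Vm


# --------------------------------------------------------------------------
# border map and quality


def compute_border(Om: np.ndarray, blur_px: int | None = None,
                   nominal_period_px: float = 16.0) -> np.ndarray:
    """Border map: normalized box blur of the object mask.

    Interior pixels far from any edge approach 1; values decay to ~0.5 on
    the mask boundary.  Default blur width is twice the fringe period.
    """
    Om = np.asarray(Om, dtype=bool)
    if blur_px is None:
        blur_px = _odd(round(2.0 * nominal_period_px))
    Bm = ndi.uniform_filter(Om.astype(float), size=blur_px, mode="constant")
    return np.where(Om, np.clip(Bm, 0.0, 1.0), np.nan)


def normalize_map(values: np.ndarray, valid: np.ndarray | None = None
                  ) -> np.ndarray:
    """Per-frame min-max normalization to [0, 1] over valid pixels."""
    v = np.asarray(values, dtype=float)
    if valid is None:
        valid = np.isfinite(v)
    else:
        valid = np.asarray(valid, dtype=bool) & np.isfinite(v)
    if not valid.any():
        return np.full(v.shape, np.nan)
    lo, hi = v[valid].min(), v[valid].max()
    if hi == lo:
        return np.where(valid, 1.0, np.nan)
    out = (v - lo) / (hi - lo)
    return np.where(valid, out, np.nan)


def compute_quality(Bm: np.ndarray, Am: np.ndarray, Vm: np.ndarray,
                    Sm: np.ndarray, weights: QualityWeights | None = None
                    ) -> np.ndarray:
    """Quality map: weighted arithmetic mean of powers of the four maps.

    ``Qm = (bw*Bm^be + aw*Am^ae + vw*Vm^ve + sw*Sm^se) / (bw+aw+vw+sw)``.
    All inputs must already be normalized to [0, 1]; the result is in
    [0, 1] and monotonically non-decreasing in each input.
    """
    if weights is None:
        weights = QualityWeights()
    w = weights
    total = w.bw + w.aw + w.vw + w.sw
    with np.errstate(invalid="ignore"):
        q = (w.bw * np.power(Bm, w.be) + w.aw * np.power(Am, w.ae)
             + w.vw * np.power(Vm, w.ve) + w.sw * np.power(Sm, w.se)) / total
    return q
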