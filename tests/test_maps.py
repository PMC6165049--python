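"""Per-pixel maps: masking, period/amplitude, stability, wrapped phase,
verticality, border and quality — including direct per-pixel loop oracles."""

import warnings

import numpy as np
import pytest
from hypothesis import given, settings
from hypothesis import strategies as st

from fringescan import simulate as sim
from fringescan.maps import (QualityWeights, compute_border,
                             compute_object_mask, compute_period_amplitude,
                             compute_quality, compute_stability,
                             compute_verticality, compute_wrapped_phase,
                             normalize_map)
from fringescan.patterns import TWO_PI, PatternSpec
from fringescan.unwrap import wrap_to_pi


def _sinusoid(shape=(64, 64), period=16.0, phase0=0.0, offset=0.5, amp=0.45):
    c = np.arange(shape[1], dtype=float)[None, :]
    return offset + amp * np.cos(TWO_PI * c / period + phase0) * np.ones((shape[0], 1))


# ----------------------------------------------------------------------
# object mask


def test_uniform_image_gives_empty_mask_with_warning():
    with pytest.warns(UserWarning, match="empty"):
        mask = compute_object_mask(np.zeros((32, 32)))
    assert not mask.any()


def test_disk_scene_mask_covers_support():
    support = sim.disk_support((192, 192), 70)
    z = np.zeros((192, 192))
    img, _ = sim.render(sim.SyntheticScene(height_mm=z, support=support,
                                           background_level=0.03))
    mask = compute_object_mask(img, nominal_period_px=16.0)
    # one component, matching the support up to a narrow boundary band
    from scipy.ndimage import binary_dilation, binary_erosion
    band = 4
    inner = binary_erosion(support, iterations=band)
    outer = binary_dilation(support, iterations=band)
    assert mask[inner].all()
    assert not mask[~outer].any()


def test_largest_segment_only_survives():
    img = np.zeros((128, 128))
    rr, cc = np.mgrid[0:128, 0:128]
    small = (rr - 30) ** 2 + (cc - 30) ** 2 < 10 ** 2
    big = (rr - 85) ** 2 + (cc - 85) ** 2 < 25 ** 2
    carrier = 0.5 + 0.45 * np.cos(TWO_PI * cc / 8.0)
    img[small] = carrier[small]
    img[big] = carrier[big]
    mask = compute_object_mask(img, nominal_period_px=8.0)
    assert mask[big].mean() > 0.9
    assert not mask[small].any()


def test_overexposed_pixels_removed():
    img = _sinusoid((64, 64), offset=0.5, amp=0.4)
    img[10:20, :] = 1.0
    mask = compute_object_mask(img, overexposure_level=0.98, closing_radius=0,
                               nominal_period_px=16.0)
    assert not mask[12:18, 20:40].any()


# ----------------------------------------------------------------------
# period and amplitude


def test_period_and_amplitude_on_pure_sinusoid():
    img = _sinusoid((64, 256), period=16.0, offset=0.5, amp=0.5)
    Om = np.ones(img.shape, bool)
    Pm, Am = compute_period_amplitude(img, Om, nominal_period_px=16.0)
    valid = np.isfinite(Pm)
    interior = valid.copy()
    assert np.mean(np.abs(Pm[valid] - 16.0) <= 1.0) >= 0.99
    assert Am[valid] == pytest.approx(1.0, abs=0.02)


def test_constant_region_has_invalid_period():
    img = _sinusoid((64, 128), period=16.0)
    img[:, 48:80] = 0.5
    Om = np.ones(img.shape, bool)
    Pm, _ = compute_period_amplitude(img, Om, nominal_period_px=16.0)
    assert np.isnan(Pm[:, 60:68]).all()


def _oracle_period_amplitude(img, window):
    """Direct per-pixel re-implementation of the period/amplitude rule."""
    half = window // 2
    n_rows, n_cols = img.shape
    Pm = np.full(img.shape, np.nan)
    Am = np.full(img.shape, np.nan)
    for r in range(n_rows):
        row = img[r]
        padded = np.pad(row, half, mode="edge")
        med = np.array([np.median(padded[c:c + window]) for c in range(n_cols)])
        Am[r] = np.array([padded[c:c + window].max() - padded[c:c + window].min()
                          for c in range(n_cols)])
        g = row - med
        sign = g >= 0
        cross = []
        for c in range(n_cols - 1):
            if sign[c] != sign[c + 1]:
                denom = g[c] - g[c + 1]
                f = g[c] / denom if denom != 0 else 0.5
                cross.append(c + f)
        cross = np.asarray(cross)
        for c in range(n_cols):
            k = np.searchsorted(cross, c, side="right")
            if 1 <= k and k + 1 < cross.size:
                Pm[r, c] = cross[k + 1] - cross[k - 1]
    return Pm, Am


def test_period_amplitude_match_loop_oracle():
    z = sim.blob_height((64, 64), seed=2, amplitude_mm=(5.0, 15.0))
    img, _ = sim.render(sim.SyntheticScene(height_mm=z))
    Om = np.ones(img.shape, bool)
    window = 25
    Pm, Am = compute_period_amplitude(img, Om, nominal_period_px=16.0,
                                      window_px=window, min_amplitude=0.0)
    Pm_o, Am_o = _oracle_period_amplitude(img, window)
    np.testing.assert_allclose(Am, Am_o, atol=1e-12)
    margin = window // 2 + 16
    sl = slice(margin, 64 - margin)
    both = np.isfinite(Pm[:, sl]) & np.isfinite(Pm_o[:, sl])
    assert both.mean() > 0.9
    np.testing.assert_allclose(Pm[:, sl][both], Pm_o[:, sl][both], atol=1e-9)


# ----------------------------------------------------------------------
# stability


def test_constant_period_is_maximally_stable():
    Pm = np.full((32, 64), 16.0)
    Sm = compute_stability(Pm)
    np.testing.assert_allclose(Sm, 1.0)


def test_step_in_period_is_a_stability_minimum():
    Pm = np.full((32, 64), 16.0)
    Pm[:, 32:] = 20.0
    Sm = compute_stability(Pm)
    assert np.nanargmin(Sm[16]) in range(28, 37)
    assert np.nanmin(Sm[16]) < 0.2
    assert Sm[16, 5] == pytest.approx(1.0)


def _oracle_stability(Pm):
    valid = np.isfinite(Pm)
    n_rows, n_cols = Pm.shape
    var = np.full(Pm.shape, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            if not valid[r, c]:
                continue
            w = int(np.clip(round(Pm[r, c]), 2, 128))
            lo = c - w // 2
            hi = lo + w  # exclusive
            sel = Pm[r, max(lo, 0):min(hi, n_cols)]
            sel = sel[np.isfinite(sel)]
            if sel.size >= max(2.0, 0.5 * w):
                var[r, c] = np.mean(sel ** 2) - np.mean(sel) ** 2
    ok = np.isfinite(var)
    vmax = var[ok].max()
    return np.where(ok, 1.0 - var / vmax if vmax > 0 else 1.0, np.nan)


def test_stability_matches_loop_oracle():
    rng = np.random.default_rng(0)
    Pm = 16.0 + rng.normal(0, 0.8, (48, 48))
    Pm[rng.random((48, 48)) < 0.05] = np.nan
    Sm = compute_stability(Pm)
    Sm_o = _oracle_stability(Pm)
    np.testing.assert_allclose(Sm, Sm_o, atol=1e-9, equal_nan=True)


# ----------------------------------------------------------------------
# wrapped phase


def test_scps_exact_on_integer_period():
    img, truth = sim.render(sim.SyntheticScene(height_mm=np.zeros((64, 128))))
    Om = np.ones(img.shape, bool)
    Pm = np.full(img.shape, 16.0)
    Wm = compute_wrapped_phase(img, Om, Pm)
    err = wrap_to_pi(Wm - truth.phase)
    assert np.nanmax(np.abs(err)) < 1e-6
    assert np.nanmin(Wm) >= -np.pi and np.nanmax(Wm) < np.pi


def test_scps_shift_equivariance():
    base = sim.SyntheticScene(height_mm=np.zeros((32, 128)))
    shifted = sim.SyntheticScene(height_mm=np.zeros((32, 128)),
                                 phase_offset_rad=np.pi / 3)
    Om = np.ones((32, 128), bool)
    Pm = np.full((32, 128), 16.0)
    w0 = compute_wrapped_phase(sim.render(base)[0], Om, Pm)
    w1 = compute_wrapped_phase(sim.render(shifted)[0], Om, Pm)
    d = wrap_to_pi(w1 - w0)
    assert np.nanmax(np.abs(wrap_to_pi(d - np.pi / 3))) < 1e-9


def test_seven_sample_beats_four_sample_under_period_error():
    """A 5% misestimated period hurts the naive 4-sample arctangent more."""
    img, truth = sim.render(sim.SyntheticScene(height_mm=np.zeros((16, 160))))
    Om = np.ones(img.shape, bool)
    Pm = np.full(img.shape, 16.0 * 1.05)
    Wm7 = compute_wrapped_phase(img, Om, Pm)
    err7 = np.nanmax(np.abs(wrap_to_pi(Wm7 - truth.phase)))

    # independent naive 4-sample estimator at the same wrong period
    import scipy.ndimage as ndi
    rr, cc = np.mgrid[0:16, 0:160].astype(float)
    step = 16.0 * 1.05 / 4
    s = [ndi.map_coordinates(img, np.vstack([rr.ravel(), (cc + k * step).ravel()]),
                             order=1, mode="constant", cval=np.nan).reshape(img.shape)
         for k in range(4)]
    w4 = np.arctan2(s[3] - s[1], s[0] - s[2])
    err4 = np.nanmax(np.abs(wrap_to_pi(w4 - truth.phase)))
    assert err7 < err4


def test_sampling_window_leaving_mask_is_invalid():
    img = _sinusoid((32, 96))
    Om = np.zeros(img.shape, bool)
    Om[:, 20:70] = True
    Pm = np.full(img.shape, 16.0)
    Wm = compute_wrapped_phase(img, Om, Pm)
    assert np.isnan(Wm[:, 20:25]).all()     # window reaches outside Om
    assert np.isfinite(Wm[:, 40:50]).all()


# ----------------------------------------------------------------------
# verticality


def _oracle_verticality(img, Om, Pm):
    n_rows, n_cols = img.shape
    Vm = np.full(img.shape, np.nan)
    for r in range(n_rows):
        for c in range(n_cols):
            if not (Om[r, c] and np.isfinite(Pm[r, c])):
                continue
            w = int(round(Pm[r, c]))
            if w < 1 or r - w < 0 or r + w > n_rows - 1 \
                    or c - w < 0 or c + w > n_cols - 1:
                continue
            gv = sum(abs(img[i, c] - img[i - 1, c]) for i in range(r + 1, r + w + 1))
            gv += sum(abs(img[i, c] - img[i + 1, c]) for i in range(r - w, r))
            gh = sum(abs(img[r, j] - img[r, j - 1]) for j in range(c + 1, c + w + 1))
            gh += sum(abs(img[r, j] - img[r, j + 1]) for j in range(c - w, c))
            Vm[r, c] = gh / (gh + gv) if gh + gv > 0 else 0.0
    return Vm


def test_verticality_symmetries_and_oracle():
    c = np.arange(64, dtype=float)[None, :]
    r = np.arange(64, dtype=float)[:, None]
    vertical = 0.5 + 0.45 * np.cos(TWO_PI * c / 8.0) * np.ones((64, 1))
    Om = np.ones((64, 64), bool)
    Pm = np.full((64, 64), 8.0)
    Vv = compute_verticality(vertical, Om, Pm)
    assert np.nanmin(Vv) == pytest.approx(1.0)
    Vh = compute_verticality(vertical.T, Om, Pm)
    assert np.nanmax(Vh) == pytest.approx(0.0)
    diagonal = 0.5 + 0.45 * np.cos(TWO_PI * (c + r) / 11.3)
    Vd = compute_verticality(diagonal, Om, Pm)
    inner = Vd[16:48, 16:48]
    assert np.nanmean(inner) == pytest.approx(0.5, abs=0.05)
    np.testing.assert_allclose(Vd, _oracle_verticality(diagonal, Om, Pm),
                               atol=1e-9, equal_nan=True)


# ----------------------------------------------------------------------
# border map


def test_border_map_interior_edge_and_monotonicity():
    Om = np.zeros((96, 96), bool)
    Om[8:88, 8:88] = True
    Bm = compute_border(Om, blur_px=15)
    assert Bm[48, 48] == pytest.approx(1.0)
    assert Bm[8, 48] == pytest.approx(0.5, abs=0.05)   # boxcar at a straight edge

    disk = sim.disk_support((128, 128), 50)
    Bd = compute_border(disk, blur_px=21)
    from scipy.ndimage import distance_transform_edt
    dist = distance_transform_edt(disk)
    order = np.argsort(dist[disk])
    vals = Bd[disk][order]
    bins = np.array_split(vals, 16)
    means = [b.mean() for b in bins]
    assert all(b >= a - 1e-6 for a, b in zip(means, means[1:]))


# ----------------------------------------------------------------------
# quality


def test_quality_weighted_mean_examples():
    w = QualityWeights()
    one = np.ones((2, 2))
    assert compute_quality(one, one, one, one, w)[0, 0] == pytest.approx(1.0, abs=1e-12)
    q = compute_quality(one, 0 * one, one, one, w)
    assert q[0, 0] == pytest.approx(0.5, abs=1e-12)
    q = compute_quality(one, 0.5 * one, one, one, w)
    assert q[0, 0] == pytest.approx(0.625, abs=1e-12)


def test_all_zero_weights_rejected():
    with pytest.raises(ValueError):
        QualityWeights(bw=0, aw=0, vw=0, sw=0)


@settings(deadline=None, max_examples=50, derandomize=True)
@given(st.lists(st.floats(0, 1), min_size=4, max_size=4),
       st.integers(0, 3), st.floats(0.001, 1.0))
def test_quality_monotone_in_each_map(vals, which, bump):
    w = QualityWeights()
    maps = [np.array([[v]]) for v in vals]
    q0 = compute_quality(*maps, w)[0, 0]
    maps[which] = np.minimum(maps[which] + bump, 1.0)
    q1 = compute_quality(*maps, w)[0, 0]
    assert q1 >= q0 - 1e-12


def test_normalize_map_is_minmax():
    vals = np.array([[2.0, 4.0], [6.0, np.nan]])
    out = normalize_map(vals)
    np.testing.assert_allclose(out[:1], [[0.0, 0.5]])
    assert np.isnan(out[1, 1])


def test_maps_undefined_off_object(cap_frame):
    _, _, frame = cap_frame
    m = frame.maps
    off = ~m.Om
    for name in ("Pm", "Am", "Sm", "Wm", "Vm", "Bm"):
        arr = getattr(m, name)
        assert np.isnan(arr[off]).all(), f"{name} leaks off the mask"
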