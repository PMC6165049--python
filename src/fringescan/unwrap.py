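"""Quality-guided spatial phase unwrapping.

The wrapped phase ``Wm`` is unwrapped along a maximum-quality spanning
tree of the 4-connected valid-pixel graph: a Prim-style priority-queue
flood fill grows from a high-quality seed, always crossing the
highest-quality available edge (edge weight = min quality of its two
endpoints), so reliable regions are unwrapped first and error-prone ones
(borders, low contrast, curved fringes) last.  Each child pixel receives

    Um[child] = Um[parent] + wrap(Wm[child] - Wm[parent])

with ``wrap`` mapping into [-pi, pi).  The result is relative: it equals
the true phase up to one global multiple of 2*pi per connected
component (fixed later by the marker).
"""

from __future__ import annotations

import heapq
from dataclasses import dataclass

import numpy as np

TWO_PI = 2.0 * np.pi

__all__ = ["UnwrapResult", "unwrap", "itoh_unwrap", "wrap_to_pi",
           "curvature_correction"]


def wrap_to_pi(x: np.ndarray | float) -> np.ndarray | float:
    """Map phase differences into [-pi, pi)."""
    return (x + np.pi) % TWO_PI - np.pi


@dataclass
class UnwrapResult:
    """Unwrapped phase plus bookkeeping.

    ``Um`` is continuous phase in radians, defined exactly where ``Wm``
    and the mask are; ``(Um - Wm)/2pi`` is integral at every valid pixel.
    """

    Um: np.ndarray
    seed_pixel: tuple[int, int]
    tree_edges: int
    n_components: int = 1
    component_map: np.ndarray | None = None  # int raster, -1 where invalid


def _pick_seed(Q: np.ndarray, candidates: np.ndarray,
               rng: np.random.Generator | None) -> int:
    """Seed pixel (flat index): argmax quality, or a random pixel from the
    top 10% of the quality distribution when an rng is supplied."""
    q = Q[candidates]
    if rng is None:
        return int(candidates[int(np.argmax(q))])
    thr = np.quantile(q, 0.9)
    top = candidates[q >= thr]
    return int(rng.choice(top))


def unwrap(Wm: np.ndarray, Qm: np.ndarray, Om: np.ndarray,
           seed_pixel: tuple[int, int] | None = None,
           rng_seed: int | None = None) -> UnwrapResult:
    """Unwrap ``Wm`` guided by ``Qm`` over the mask ``Om``.

    Disconnected mask components are each unwrapped from their own seed.
    With ``rng_seed`` the seed is drawn from the top 10% of the quality
    map (the randomized variant); otherwise the deterministic argmax is
    used.  Ties in the priority queue break in row-major pixel order, so
    the result is bit-reproducible.
    """
    Wm = np.asarray(Wm, dtype=float)
    Qm = np.asarray(Qm, dtype=float)
    Om = np.asarray(Om, dtype=bool)
    if not (Wm.shape == Qm.shape == Om.shape):
        raise ValueError("Wm, Qm and Om must share one grid")
    valid = Om & np.isfinite(Wm) & np.isfinite(Qm)
    if not valid.any():
        raise ValueError("no valid pixels to unwrap")

    n_rows, n_cols = Wm.shape
    W = Wm.ravel()
    Q = Qm.ravel()
    visited = ~valid.ravel()
    Um_flat = np.full(W.size, np.nan)
    comp_flat = np.full(W.size, -1, dtype=int)
    rng = np.random.default_rng(rng_seed) if rng_seed is not None else None

    first_seed: tuple[int, int] | None = None
    tree_edges = 0
    n_components = 0

    if seed_pixel is not None:
        if not valid[seed_pixel]:
            raise ValueError("requested seed pixel is not a valid pixel")
        seed_flat: int | None = int(np.ravel_multi_index(seed_pixel, Wm.shape))
    else:
        seed_flat = None

    while True:
        remaining = np.nonzero(~visited)[0]
        if remaining.size == 0:
            break
        if seed_flat is not None:
            seed = seed_flat
            seed_flat = None
        else:
            seed = _pick_seed(Q, remaining, rng)
        n_components += 1
        if first_seed is None:
            first_seed = tuple(int(v) for v in np.unravel_index(seed, Wm.shape))
        Um_flat[seed] = W[seed]
        visited[seed] = True
        comp_flat[seed] = n_components - 1
        heap: list[tuple[float, int, int]] = []

        def push_neighbours(p: int) -> None:
            r, c = divmod(p, n_cols)
            if r > 0:
                _push(p - n_cols, p)
            if r < n_rows - 1:
                _push(p + n_cols, p)
            if c > 0:
                _push(p - 1, p)
            if c < n_cols - 1:
                _push(p + 1, p)

        def _push(child: int, parent: int) -> None:
            if not visited[child]:
                w = min(Q[child], Q[parent])
                heapq.heappush(heap, (-w, child, parent))

        push_neighbours(seed)
        while heap:
            _, child, parent = heapq.heappop(heap)
            if visited[child]:
                continue
            visited[child] = True
            Um_flat[child] = Um_flat[parent] + wrap_to_pi(W[child] - W[parent])
            comp_flat[child] = n_components - 1
            tree_edges += 1
            push_neighbours(child)

    assert first_seed is not None
    return UnwrapResult(Um=Um_flat.reshape(Wm.shape), seed_pixel=first_seed,
                        tree_edges=tree_edges, n_components=n_components,
                        component_map=comp_flat.reshape(Wm.shape))


def curvature_correction(Um: np.ndarray, Pm: np.ndarray,
                         smooth_px: int | None = None) -> np.ndarray:
    """Analytic second-order bias of the 7-sample phase estimator.

    On a locally quadratic phase profile, samples at ``k * P/4`` see
    phase offsets ``k*pi/2 + chi*k^2`` with ``chi = phi'' (P/4)^2 / 2``;
    a first-order expansion of the estimator gives a measured phase of
    ``phi + 2*chi``, i.e. a bias of ``phi'' * (P/4)^2``.  The returned
    raster is that bias (0 where it cannot be estimated); subtract it
    from the unwrapped phase.  ``phi''`` is the smoothed second
    difference of ``Um`` along the fringe normal.
    """
    Um = np.asarray(Um, dtype=float)
    Pm = np.asarray(Pm, dtype=float)
    g1 = np.gradient(Um, axis=1)
    g2 = np.gradient(g1, axis=1)
    valid = np.isfinite(g2)
    if smooth_px is None:
        med = np.nanmedian(Pm)
        smooth_px = max(3, int(round(med)) | 1) if np.isfinite(med) else 9
    import scipy.ndimage as ndi

    v = np.where(valid, g2, 0.0)
    cnt = ndi.uniform_filter(valid.astype(float), size=smooth_px,
                             mode="constant") * smooth_px**2
    s = ndi.uniform_filter(v, size=smooth_px, mode="constant") * smooth_px**2
    with np.errstate(invalid="ignore", divide="ignore"):
        g2s = np.where(cnt >= 1, s / cnt, np.nan)
    corr = (Pm / 4.0) ** 2 * g2s
    return np.where(np.isfinite(corr), corr, 0.0)


def itoh_unwrap(Wm: np.ndarray) -> np.ndarray:
    """Reference path-following unwrapper (Itoh): unwrap the first row,
    then every column.  Valid only for full-frame smooth phase fields;
    used as an independent oracle for the spanning-tree unwrapper."""
    Wm = np.asarray(Wm, dtype=float)
    first_row = np.unwrap(Wm[0])
    cols = np.unwrap(Wm, axis=0)
    return cols + (first_row - Wm[0])[None, :]
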