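"""Greedy, background-free initialization of footprints and traces.

Seed pixels are local maxima of the correlation-times-PNR image that pass
both thresholds.  Each accepted seed initializes one neuron: the neuron
trace is read out from the spatially filtered movie near the seed, the
local background trace from weakly correlated surrounding pixels, and the
footprint from a per-pixel regression of the raw movie onto
``[trace, local background, constant]``.  The neuron's rank-1 activity is
then peeled off the working movie and the summary images are refreshed
locally before the next seed is drawn.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy import ndimage

from .summary import SummaryImages, correlation_image, pnr_image, spatial_filter

__all__ = [
    "SeedCandidate",
    "InitResult",
    "screen_seed_pixels",
    "init_neuron_from_seed",
    "greedy_initialize",
    "refine_traces_given_background",
    "decorrelate_initial_spikes",
]


@dataclass
class SeedCandidate:
    """A pixel passing both seeding thresholds at a local max of P*L."""

    pixel: int               # flat row-major index
    row: int
    col: int
    L_value: float
    P_value: float
    R_value: float


@dataclass
class InitResult:
    """Output of the greedy initialization."""

    A: np.ndarray            # (d, K) nonnegative footprints
    C_raw: np.ndarray        # (K, T) raw (pre-deconvolution) traces
    seeds: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.A.shape[1]


def screen_seed_pixels(L, P, Lmin, Pmin, l, fov_shape, blocked=None):
    """Rank candidate seed pixels.

    Pixels must exceed both thresholds and be local maxima of ``R = P * L``
    within an ``(l/4) x (l/4)`` neighbourhood; candidates are ordered by R
    descending with row-major ties-first ordering.
    """
    H, W = fov_shape
    R = (P * L).reshape(H, W)
    win = max(3, int(round(l / 4.0)))
    if win % 2 == 0:
        win += 1
    local_max = R >= ndimage.maximum_filter(R, size=win, mode="nearest")
    mask = (L > Lmin).reshape(H, W) & (P > Pmin).reshape(H, W) & local_max
    if blocked is not None:
        mask &= ~blocked.reshape(H, W)
    idx = np.flatnonzero(mask.ravel())
    if len(idx) == 0:
        return []
    order = np.lexsort((idx, -R.ravel()[idx]))  # R desc, row-major tie-break
    return [
        SeedCandidate(pixel=int(i), row=int(i // W), col=int(i % W),
                      L_value=float(L[i]), P_value=float(P[i]),
                      R_value=float(R.ravel()[i]))
        for i in idx[order]
    ]


def _box_indices(row, col, half, fov_shape):
    H, W = fov_shape
    r0, r1 = max(0, row - half), min(H, row + half + 1)
    c0, c1 = max(0, col - half), min(W, col + half + 1)
    rr, cc = np.mgrid[r0:r1, c0:c1]
    return (rr * W + cc).ravel(), (r0, r1, c0, c1)


def init_neuron_from_seed(Y, Z, seed: SeedCandidate, l, fov_shape,
                          bg_corr_cut=0.3, neuron_corr_cut=0.7,
                          min_pixels=5, bg_stat="median", raw_corr_min=0.15):
    """Initialize one neuron from a seed pixel.

    Returns ``(a, c_raw)`` with ``a`` zero outside the ``(2l+1)``-box around
    the seed, or ``None`` if the seed is rejected (no usable footprint).

    Rejection combines three checks: the footprint must have at least
    ``min_pixels`` above half its peak; the seed pixel's loading on the
    neuron trace must stand far above the regression residual; and the
    seed's *raw* trace must correlate with its 4 nearest raw neighbours
    (``raw_corr_min``) — spatial filtering correlates neighbouring noise,
    but only a real soma correlates neighbouring raw pixels once the
    background is gone.
    """
    d, T = Y.shape
    H, W = fov_shape
    if raw_corr_min > 0:
        nbr = []
        for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
            r, c = seed.row + dy, seed.col + dx
            if 0 <= r < H and 0 <= c < W:
                nbr.append(r * W + c)
        ys = Y[seed.pixel] - Y[seed.pixel].mean()
        ns = np.linalg.norm(ys)
        corrs = []
        for j in nbr:
            yn = Y[j] - Y[j].mean()
            nn = np.linalg.norm(yn)
            corrs.append(ys @ yn / (ns * nn) if ns > 0 and nn > 0 else 0.0)
        if corrs and float(np.mean(corrs)) < raw_corr_min:
            return None
    box, _ = _box_indices(seed.row, seed.col, l, fov_shape)
    Zbox = Z[box]
    zs = Z[seed.pixel]
    zc = Zbox - Zbox.mean(axis=1, keepdims=True)
    ss = zs - zs.mean()
    denom = np.linalg.norm(zc, axis=1) * np.linalg.norm(ss)
    with np.errstate(invalid="ignore", divide="ignore"):
        r = np.where(denom > 0, zc @ ss / np.where(denom > 0, denom, 1.0), 0.0)

    in_cell = r >= neuron_corr_cut
    if in_cell.sum() <= 1:
        c_raw = zs.astype(np.float64)
    else:
        c_raw = Zbox[in_cell].mean(axis=0).astype(np.float64)

    out_cell = r <= bg_corr_cut
    regs = [c_raw]
    if out_cell.any():
        Ybg = Y[box][out_cell]
        y_bg = np.median(Ybg, axis=0) if bg_stat == "median" else Ybg.mean(axis=0)
        regs.append(y_bg.astype(np.float64))
    regs.append(np.ones(T))
    D = np.column_stack(regs)          # (T, 2 or 3)
    # per-pixel LS of raw traces on [c_raw, y_bg, 1]
    DtD = D.T @ D
    try:
        coef = np.linalg.solve(DtD, D.T @ Y[box].T.astype(np.float64))
    except np.linalg.LinAlgError:
        return None
    a_box = np.maximum(coef[0], 0.0)
    if a_box.max() <= 0:
        return None
    if int((a_box >= a_box.max() / 2).sum()) < min_pixels:
        return None
    # statistical check at the seed pixel: its loading on the neuron trace
    # must stand far above the regression residual (rejects noise seeds)
    seed_local = int(np.flatnonzero(box == seed.pixel)[0])
    resid_seed = Y[seed.pixel].astype(np.float64) - D @ coef[:, seed_local]
    c_norm = float(np.linalg.norm(c_raw - c_raw.mean()))
    resid_sd = float(resid_seed.std())
    if resid_sd > 0 and coef[0, seed_local] * c_norm / resid_sd < 5.0:
        return None
    a = np.zeros(d, dtype=np.float32)
    a[box] = a_box
    return a, c_raw


def greedy_initialize(movie, summaries: SummaryImages, min_corr=0.8,
                      min_pnr=10.0, max_neurons=None, bg_corr_cut=0.3,
                      neuron_corr_cut=0.7, min_pixels=5, bg_stat="median",
                      clip_n_sigma=3.0, copy=True, raw_corr_min=0.15) -> InitResult:
    """Greedy seed-and-peel initialization of all neurons.

    Works on copies of the movie and its filtered version: after each
    accepted neuron its rank-1 activity is subtracted from both, and the
    correlation and PNR images are recomputed inside the affected window
    only.  Stops when no candidate passes the thresholds (or
    ``max_neurons`` is reached).  ``copy=False`` lets the peeling consume
    the provided arrays in place (large movies).
    """
    fov = movie.fov_shape
    H, W = fov
    l = summaries.kernel.width
    Yw = movie.data.astype(np.float32)
    Z = summaries.Z
    if copy:
        Yw = Yw.copy()
        Z = Z.copy()
    sigma = summaries.sigma
    L = summaries.L.copy()
    P = summaries.P.copy()
    blocked = np.zeros(H * W, dtype=bool)
    kernel = summaries.kernel

    A_cols, C_rows, seeds = [], [], []
    while max_neurons is None or len(A_cols) < max_neurons:
        cands = screen_seed_pixels(L, P, min_corr, min_pnr, l, fov, blocked)
        if not cands:
            break
        seed = cands[0]
        res = init_neuron_from_seed(Yw, Z, seed, l, fov, bg_corr_cut,
                                    neuron_corr_cut, min_pixels, bg_stat,
                                    raw_corr_min=raw_corr_min)
        if res is None:
            blocked[seed.pixel] = True
            continue
        a, c_raw = res
        A_cols.append(a)
        C_rows.append(c_raw)
        seeds.append(seed)
        blocked[seed.pixel] = True  # guards against re-seeding a peeled neuron

        # peel the neuron's activity from the raw working copy
        supp = np.flatnonzero(a > 0)
        Yw[supp] -= np.outer(a[supp], c_raw).astype(np.float32)
        # same linear operation on the filtered movie
        da = spatial_filter(a.reshape(1, H, W), kernel)[0].ravel()
        r = kernel.radius
        win, (r0, r1, c0, c1) = _box_indices(seed.row, seed.col, l + r, fov)
        Z[win] -= np.outer(da[win], c_raw).astype(np.float32)
        # refresh P and L inside the affected window
        P[win] = pnr_image(Z[win], sigma[win])
        er0, er1 = max(0, r0 - 1), min(H, r1 + 1)
        ec0, ec1 = max(0, c0 - 1), min(W, c1 + 1)
        sub = (np.mgrid[er0:er1, ec0:ec1][0] * W
               + np.mgrid[er0:er1, ec0:ec1][1]).ravel()
        Lsub = correlation_image(Z[sub], sigma[sub], (er1 - er0, ec1 - ec0),
                                 n_sigma=clip_n_sigma)
        Lfull = L.reshape(H, W)
        Lfull[er0:er1, ec0:ec1] = Lsub.reshape(er1 - er0, ec1 - ec0)
        L = Lfull.ravel()

    d, T = movie.data.shape
    if A_cols:
        A = np.column_stack(A_cols).astype(np.float32)
        C = np.vstack(C_rows).astype(np.float32)
    else:
        A = np.zeros((d, 0), dtype=np.float32)
        C = np.zeros((0, T), dtype=np.float32)
    return InitResult(A=A, C_raw=C, seeds=seeds)


def refine_traces_given_background(A, Y, Bf, b0, joint: bool = True):
    """Re-read each trace from the background-subtracted movie.

    Uses the thresholded footprint (pixels >= half its peak) as weights:
    ``c_i = a~' (Y - Bf - b0 1') / (a~' a~)``; the thresholding reduces the
    contribution of smaller neighbouring neurons.  With ``joint=True``
    (default) components whose thresholded footprints overlap are solved as
    one least-squares system, which removes the crosstalk the per-neuron
    ratio cannot (for disjoint footprints the two forms coincide).
    """
    K = A.shape[1]
    T = Y.shape[1]
    C = np.zeros((K, T))
    resid = Y - Bf - b0[:, None]
    At = np.zeros_like(A, dtype=np.float64)
    alive = []
    for i in range(K):
        a = A[:, i]
        if a.max() <= 0:
            continue
        At[:, i] = np.where(a >= a.max() / 2.0, a, 0.0)
        alive.append(i)
    if not alive:
        return C
    if joint:
        G = At[:, alive].T @ At[:, alive]
        G[np.diag_indices_from(G)] *= 1.0 + 1e-9
        rhs = At[:, alive].T @ resid
        try:
            C[alive] = np.linalg.solve(G, rhs)
            return C
        except np.linalg.LinAlgError:
            pass
    for i in alive:
        at = At[:, i]
        C[i] = (at @ resid) / float(at @ at)
    return C


def decorrelate_initial_spikes(S, overlap_pairs, ar_models=None):
    """Resolve simultaneous spikes of spatially overlapping components.

    For every frame in which both members of an overlapping pair have a
    nonzero spike, only the larger one is kept.  When AR models are given,
    traces are re-derived from the thresholded spikes.

    Returns ``(S, C)`` (``C`` is None when no AR models are supplied).
    """
    S = S.copy()
    for i, j in overlap_pairs:
        both = (S[i] > 0) & (S[j] > 0)
        if not both.any():
            continue
        win_i = S[i] >= S[j]
        S[i, both & ~win_i] = 0.0
        S[j, both & win_i] = 0.0
    C = None
    if ar_models is not None:
        from scipy.signal import fftconvolve

        T = S.shape[1]
        C = np.zeros_like(S)
        for k in range(S.shape[0]):
            h = ar_models[k].impulse_response(T)
            C[k] = fftconvolve(S[k], h)[:T]
    return S, C
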