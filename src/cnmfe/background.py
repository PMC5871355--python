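"""Ring-structured background estimation.

The fluctuating background at each pixel is modelled as a linear combination
of the pixels on an annulus of radius ``ln`` around it (chosen larger than a
soma, so the ring shares the spatially coarse background but not the
pixel's own neuron).  Fitting reduces to one small linear regression per
pixel; robustness to unmodelled neural transients comes from clipping
frames that exceed the current background estimate by ``zeta`` noise
standard deviations.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
import scipy.sparse as sp
from scipy import signal
from scipy.linalg import cho_factor, cho_solve

__all__ = [
    "RingIndex",
    "BackgroundModel",
    "build_ring_index",
    "estimate_constant_baseline",
    "clip_outlier_frames",
    "fit_ring_weights",
    "estimate_background",
    "rank_r_nmf_background",
]


@dataclass
class RingIndex:
    """Annulus neighbourhoods: for pixel ``i`` the pixels at Euclidean
    distance in ``[ln, ln + 1)``, clipped to the field of view."""

    fov_shape: tuple
    ln: float
    indptr: np.ndarray   # CSR-style: neighbours of i are indices[indptr[i]:indptr[i+1]]
    indices: np.ndarray
    offsets: np.ndarray  # (m, 2) integer offsets of the full (unclipped) ring

    def neighbors(self, i: int) -> np.ndarray:
        return self.indices[self.indptr[i] : self.indptr[i + 1]]

    @property
    def n_pixels(self) -> int:
        return self.fov_shape[0] * self.fov_shape[1]


def ring_offsets(ln: float) -> np.ndarray:
    """Integer offsets (dy, dx) with ``ln <= sqrt(dy^2+dx^2) < ln + 1``."""
    r = int(np.ceil(ln + 1))
    dy, dx = np.mgrid[-r : r + 1, -r : r + 1]
    dist = np.sqrt(dy**2 + dx**2)
    mask = (dist >= ln) & (dist < ln + 1)
    return np.column_stack([dy[mask], dx[mask]])


def build_ring_index(fov_shape, ln: float) -> RingIndex:
    """Enumerate the ring neighbourhood of every pixel."""
    H, W = fov_shape
    if ln < 1:
        raise ValueError("ring radius must be at least 1 pixel")
    offs = ring_offsets(ln)
    if len(offs) == 0 or ln >= np.hypot(H, W):
        raise ValueError("ring radius too large for this field of view")
    rows = np.arange(H)[:, None] + offs[:, 0][None, :]   # (H, m)
    cols = np.arange(W)[:, None] + offs[:, 1][None, :]   # (W, m)
    rvalid = (rows >= 0) & (rows < H)
    cvalid = (cols >= 0) & (cols < W)

    indptr = np.zeros(H * W + 1, dtype=np.int64)
    chunks = []
    i = 0
    for y in range(H):
        rv = rvalid[y]
        rr = rows[y]
        for x in range(W):
            ok = rv & cvalid[x]
            idx = rr[ok] * W + cols[x, ok]
            chunks.append(idx)
            i += 1
            indptr[i] = indptr[i - 1] + len(idx)
    indices = np.concatenate(chunks)
    if indptr[-1] == 0:
        raise ValueError("ring radius leaves every pixel without neighbours")
    return RingIndex(fov_shape=(H, W), ln=ln, indptr=indptr,
                     indices=indices, offsets=offs)


@dataclass
class BackgroundModel:
    """Fitted ring weights and constant baseline.

    The fluctuating background is reconstructed on demand as
    ``Bf = W (Y - A C - b0 1^T)``; because ``b0`` is the per-pixel temporal
    mean of the neural residual, ``Bf`` has (numerically) zero temporal mean
    at every pixel.
    """

    W: sp.csr_matrix
    b0: np.ndarray
    ring: RingIndex

    def fluctuating(self, Y, A=None, C=None) -> np.ndarray:
        X = Y - self.b0[:, None]
        if A is not None and A.shape[1] > 0:
            X = X - A @ C
        return self.W @ X

    def full(self, Y, A=None, C=None) -> np.ndarray:
        return self.fluctuating(Y, A, C) + self.b0[:, None]


def estimate_constant_baseline(Y, A=None, C=None) -> np.ndarray:
    """Per-pixel temporal mean of the neural residual ``Y - A C``."""
    b0 = Y.mean(axis=1)
    if A is not None and A.shape[1] > 0:
        b0 = b0 - A @ C.mean(axis=1)
    return np.asarray(b0, dtype=np.float32)


def clip_outlier_frames(X, B_prev, sigma, zeta: float = 10.0) -> np.ndarray:
    """Replace entries exceeding the background estimate by ``zeta * sigma``
    with the background estimate (hard robust clipping)."""
    thr = B_prev + zeta * np.asarray(sigma, dtype=np.float32)[:, None]
    return np.where(X >= thr, B_prev, X).astype(np.float32)


def _ring_mean(X, ring: RingIndex) -> np.ndarray:
    """Per-pixel mean of the ring pixels, used as the first background guess."""
    H, W = ring.fov_shape
    T = X.shape[1]
    r = int(np.ceil(ring.ln + 1))
    kern = np.zeros((2 * r + 1, 2 * r + 1), dtype=np.float32)
    kern[ring.offsets[:, 0] + r, ring.offsets[:, 1] + r] = 1.0
    frames = X.T.reshape(T, H, W)
    num = signal.fftconvolve(frames, kern[None, ::-1, ::-1], mode="same", axes=(1, 2))
    den = signal.fftconvolve(np.ones((1, H, W), dtype=np.float32),
                             kern[None, ::-1, ::-1], mode="same", axes=(1, 2))
    den = np.maximum(den, 1e-6)
    out = (num / den).reshape(T, H * W).T
    return out.astype(np.float32)


def fit_ring_weights(X, ring: RingIndex, ridge: float = 10.0,
                     sigma=None) -> sp.csr_matrix:
    """Per-pixel ring-weight regression with noise-calibrated shrinkage.

    For each pixel ``i`` solve
    ``min_w ||X_i - w^T X_{ring(i)}||^2 + lam_i ||w - u||^2`` where ``u``
    is the uniform ring-average weight vector and
    ``lam_i = ridge * T * mean(sigma_ring^2)``.  The shrinkage suppresses
    the noise the unpenalised regression would otherwise absorb (the ring
    has many free weights per pixel relative to the number of frames) and
    vanishes for noiseless data, where the fit reduces to plain least
    squares.  When ``sigma`` is omitted a tiny conditioning ridge (1e-5 of
    the mean trace energy) is used instead.  Weights are unconstrained
    reals; pixels with an empty ring get a zero row.
    """
    X32 = np.ascontiguousarray(X, dtype=np.float32)
    G = X32 @ X32.T                        # Gram of pixel traces (float32)
    d, T = X.shape
    lam_cond = 1e-5 * max(float(np.trace(G)) / max(d, 1), 1e-12)
    if sigma is not None:
        sigma2 = np.asarray(sigma, dtype=np.float64) ** 2
    data = []
    cols = []
    indptr = [0]
    for i in range(d):
        idx = ring.neighbors(i)
        if len(idx) == 0:
            indptr.append(indptr[-1])
            continue
        m = len(idx)
        if sigma is not None:
            lam = max(ridge * T * float(sigma2[idx].mean()), lam_cond)
        else:
            lam = lam_cond
        Gi = G[np.ix_(idx, idx)].astype(np.float64)
        Gi[np.diag_indices_from(Gi)] += lam
        gi = G[idx, i].astype(np.float64) + lam / m   # shrink toward ring mean
        try:
            w = cho_solve(cho_factor(Gi, lower=True), gi)
        except np.linalg.LinAlgError:
            Gi[np.diag_indices_from(Gi)] += 100 * lam_cond
            w = np.linalg.solve(Gi, gi)
        data.append(w)
        cols.append(idx)
        indptr.append(indptr[-1] + len(idx))
    if data:
        data = np.concatenate(data)
        cols = np.concatenate(cols)
    return sp.csr_matrix((data, cols, np.asarray(indptr)), shape=(d, d))


def estimate_background(Y, A, C, ring: RingIndex, sigma, zeta: float = 10.0,
                        n_robust_iters: int = 2, ridge: float = 10.0) -> BackgroundModel:
    """Estimate ``(W, b0)`` by iterating robust clipping and ring regression.

    Parameters
    ----------
    Y : ndarray (d, T)
        Movie.
    A, C : ndarray or None
        Current neural estimates (``A C`` subtracted before fitting).
    sigma : ndarray (d,)
        Per-pixel noise standard deviation of the raw movie.
    zeta : float
        Outlier threshold in noise standard deviations.
    n_robust_iters : int
        Number of clip -> fit sweeps; the first sweep clips against the
        ring-mean of the residual.
    """
    b0 = estimate_constant_baseline(Y, A, C)
    X = Y - b0[:, None]
    if A is not None and A.shape[1] > 0:
        X = X - A @ C
    X = np.ascontiguousarray(X, dtype=np.float32)
    B_prev = _ring_mean(X, ring)
    W = None
    for _ in range(max(1, n_robust_iters)):
        Xc = clip_outlier_frames(X, B_prev, sigma, zeta)
        W = fit_ring_weights(Xc, ring, ridge, sigma=sigma)
        B_prev = (W @ Xc).astype(np.float32)
    return BackgroundModel(W=W, b0=b0, ring=ring)


def rank_r_nmf_background(Y, rank: int = 1, n_iters: int = 200, seed: int = 0,
                          tol: float = 1e-6):
    """Multiplicative-update NMF baseline used only for comparisons.

    Factorises the nonnegative movie into ``rank`` components and returns
    their product as the background estimate.
    """
    if rank < 1:
        raise ValueError("rank must be >= 1")
    rng = np.random.default_rng(seed)
    Y = np.maximum(np.asarray(Y, dtype=np.float64), 0.0)
    d, T = Y.shape
    scale = np.sqrt(Y.mean() / rank) if Y.mean() > 0 else 1.0
    U = scale * rng.random((d, rank)) + 1e-6
    V = scale * rng.random((rank, T)) + 1e-6
    prev = None
    for _ in range(n_iters):
        U *= (Y @ V.T) / np.maximum(U @ (V @ V.T), 1e-12)
        V *= (U.T @ Y) / np.maximum((U.T @ U) @ V, 1e-12)
        err = float(((Y - U @ V) ** 2).sum())
        if prev is not None and abs(prev - err) <= tol * max(prev, 1.0):
            break
        prev = err
    return U @ V
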