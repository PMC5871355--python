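"""Per-pixel noise estimation, band-pass spatial filtering, and the
correlation / peak-to-noise-ratio summary images that drive seeding.

The spatial filter is a mean-centred Gaussian shaped like a cell body of
diameter ``l``; correlating each frame with it suppresses the spatially
coarse background while boosting neuron-sized objects.  Seed pixels are then
ranked by the pixelwise product of the local-correlation image L and the
peak-to-noise-ratio image P, both computed on the filtered movie.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal

__all__ = [
    "FilterKernel",
    "SummaryImages",
    "estimate_noise_sigma",
    "make_filter_kernel",
    "spatial_filter",
    "correlation_image",
    "pnr_image",
    "compute_summary_images",
]


def estimate_noise_sigma(traces: np.ndarray, freq_band: tuple = (0.25, 0.5),
                         nperseg: int = 256) -> np.ndarray:
    """Estimate the noise standard deviation of each trace from the mean
    power spectral density over a high-frequency band.

    Parameters
    ----------
    traces : ndarray, shape (..., T)
        One trace per leading index.  ``T >= 32`` is required.
    freq_band : (low, high)
        Band in cycles/frame over which the Welch PSD is averaged; the
        default upper half of the spectrum excludes slow calcium and
        background dynamics.

    Returns
    -------
    sigma : ndarray, shape traces.shape[:-1]
        ``sqrt(mean PSD / 2)``; for white noise this converges to its
        standard deviation.  Constant traces give 0.
    """
    traces = np.asarray(traces, dtype=np.float32)
    T = traces.shape[-1]
    if T < 32:
        raise ValueError("need at least 32 frames for PSD noise estimation")
    nps = min(nperseg, T)
    if traces.ndim == 2 and traces.shape[0] > 8192:
        out = np.empty(traces.shape[0], dtype=np.float64)
        for s0 in range(0, traces.shape[0], 8192):
            out[s0 : s0 + 8192] = estimate_noise_sigma(
                traces[s0 : s0 + 8192], freq_band, nperseg)
        return out
    freqs, pxx = signal.welch(traces, fs=1.0, nperseg=nps, axis=-1)
    band = (freqs >= freq_band[0]) & (freqs <= freq_band[1])
    # one-sided density: flat at 2*sigma^2 for white noise sampled at fs=1
    return np.sqrt(pxx[..., band].mean(axis=-1) / 2.0)


@dataclass
class FilterKernel:
    """Gaussian cell-body template ``h`` and its mean-centred version ``h~``.

    ``h(x) = exp(-||x||^2 / (2 (l/4)^2))`` on an odd window of width ~``l``;
    the centred kernel ``h - mean(h)`` integrates to zero, so spatially
    constant patches filter to zero.
    """

    raw: np.ndarray
    centered: np.ndarray
    width: int  # neuron diameter l in pixels

    @property
    def radius(self) -> int:
        return self.raw.shape[0] // 2


def make_filter_kernel(l: int) -> FilterKernel:
    """Build the matched filter for neurons of diameter ``l`` pixels.

    The window is the nearest odd size to ``l`` (so an exact centre pixel
    exists); the Gaussian width is ``l/4``.
    """
    if l < 3:
        raise ValueError("neuron diameter must be at least 3 pixels")
    size = l if l % 2 == 1 else l + 1
    r = size // 2
    yy, xx = np.mgrid[-r : r + 1, -r : r + 1]
    h = np.exp(-(xx**2 + yy**2) / (2.0 * (l / 4.0) ** 2))
    return FilterKernel(raw=h, centered=h - h.mean(), width=l)


def spatial_filter(frames: np.ndarray, kernel: FilterKernel,
                   chunk: int = 500) -> np.ndarray:
    """Correlate every frame with the centred kernel (reflect padding).

    Parameters
    ----------
    frames : ndarray, shape (T, H, W)
    kernel : FilterKernel

    Returns
    -------
    ndarray, shape (T, H, W), the filtered movie Z (may be negative).
    """
    k = kernel.centered
    r = kernel.radius
    T, H, W = frames.shape
    if k.shape[0] > H or k.shape[1] > W:
        raise ValueError("kernel window does not fit in the field of view")
    # correlation == convolution for this symmetric kernel
    out = np.empty_like(frames, dtype=np.float32)
    for start in range(0, T, chunk):
        blk = frames[start : start + chunk]
        padded = np.pad(blk, ((0, 0), (r, r), (r, r)), mode="reflect")
        filt = signal.fftconvolve(padded, k[None], mode="same", axes=(1, 2))
        out[start : start + chunk] = filt[:, r : r + H, r : r + W]
    return out


def _clip_below(Z: np.ndarray, sigma: np.ndarray, n_sigma: float = 3.0) -> np.ndarray:
    """Set values below n_sigma * sigma (per pixel) to zero."""
    thr = n_sigma * sigma.reshape(sigma.shape + (1,))
    return np.where(Z >= thr, Z, 0.0).astype(np.float32)


def correlation_image(Z: np.ndarray, sigma: np.ndarray, fov_shape: tuple,
                      n_sigma: float = 3.0) -> np.ndarray:
    """Local correlation image of the filtered movie.

    Each pixel's filtered trace is clipped below ``n_sigma * sigma`` to zero,
    then Pearson-correlated with its 4 nearest neighbours; border pixels use
    the neighbours available.  Pixels whose clipped trace is constant get 0.

    Parameters
    ----------
    Z : ndarray, shape (d, T)
        Filtered movie, pixels by frames.
    sigma : ndarray, shape (d,)
        Noise map of the filtered movie.

    Returns
    -------
    L : ndarray, shape (d,), values in [-1, 1].
    """
    H, W = fov_shape
    Zc = _clip_below(Z, sigma, n_sigma)
    Zc -= Zc.mean(axis=1, keepdims=True)
    norms = np.linalg.norm(Zc, axis=1)
    good = norms > 0
    Zc[~good] = 0.0
    Zc[good] /= norms[good, None]
    cube = Zc.reshape(H, W, -1)
    goodmap = good.reshape(H, W)

    acc = np.zeros((H, W), dtype=np.float64)
    cnt = np.zeros((H, W), dtype=np.float64)
    for dy, dx in ((1, 0), (-1, 0), (0, 1), (0, -1)):
        ys = slice(max(dy, 0), H + min(dy, 0))
        yn = slice(max(-dy, 0), H + min(-dy, 0))
        xs = slice(max(dx, 0), W + min(dx, 0))
        xn = slice(max(-dx, 0), W + min(-dx, 0))
        both = goodmap[ys, xs] & goodmap[yn, xn]
        corr = np.einsum("ijt,ijt->ij", cube[ys, xs], cube[yn, xn])
        acc[ys, xs] += np.where(both, corr, 0.0)
        cnt[ys, xs] += 1  # neighbours exist regardless; zero-trace pairs count as 0
    L = np.zeros(H * W)
    L = (acc / cnt).ravel()
    L[~good] = 0.0
    return np.clip(L, -1.0, 1.0)


def pnr_image(Z: np.ndarray, sigma: np.ndarray) -> np.ndarray:
    """Peak-to-noise ratio per pixel: ``max_t Z / sigma`` (0 where sigma=0)."""
    peak = Z.max(axis=1)
    with np.errstate(divide="ignore", invalid="ignore"):
        P = np.where(sigma > 0, peak / np.where(sigma > 0, sigma, 1.0), 0.0)
    return np.maximum(P, 0.0)


@dataclass
class SummaryImages:
    """Filtered movie and the seed-ranking images computed from it."""

    Z: np.ndarray          # (d, T) filtered movie
    sigma: np.ndarray      # (d,) noise map of Z
    L: np.ndarray          # (d,) local correlation image
    P: np.ndarray          # (d,) peak-to-noise ratio image
    fov_shape: tuple
    kernel: FilterKernel

    @property
    def R(self) -> np.ndarray:
        """Seed-ranking image, the pixelwise product P * L."""
        return self.P * self.L


def compute_summary_images(movie, l: int, freq_band=(0.25, 0.5),
                           sigma=None) -> SummaryImages:
    """Filter the movie and compute the noise map and the L, P images.

    ``sigma`` overrides the per-pixel noise map of the filtered movie; used
    when summarising model residuals, whose own PSD under-estimates the
    noise floor (the background regression absorbs part of it).
    """
    kernel = make_filter_kernel(l)
    H, W = movie.fov_shape
    d, T = movie.data.shape
    r = kernel.radius
    # stream frame chunks straight into the pixels-by-frames output to keep
    # peak memory at ~2 movie copies for large fields of view
    Z = np.empty_like(movie.data)
    chunk = max(1, int(5e7) // max(d, 1))
    for start in range(0, T, chunk):
        end = min(start + chunk, T)
        blk = movie.data[:, start:end].T.reshape(end - start, H, W)
        filt = spatial_filter(blk, kernel)
        Z[:, start:end] = filt.reshape(end - start, d).T
    if sigma is None:
        sigma = estimate_noise_sigma(Z, freq_band)
    L = correlation_image(Z, sigma, movie.fov_shape)
    P = pnr_image(Z, sigma)
    return SummaryImages(Z=Z, sigma=sigma, L=L, P=P,
                         fov_shape=movie.fov_shape, kernel=kernel)
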