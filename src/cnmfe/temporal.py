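"""Trace updates: AR-model fitting and sparse nonnegative deconvolution.

Each neuron's calcium trace is modelled as a stable AR(p) process driven by
a nonnegative, sparse spike signal: ``c_t = sum_j gamma_j c_{t-j} + s_t``,
``s_t >= 0``.  The block-coordinate temporal update projects the movie
residual onto each footprint to get an unconstrained trace estimate, then
denoises it with a constrained deconvolution:

* AR(1): an exact online active-set (OASIS-style pool-adjacent-violators)
  solver for the L1-penalised problem; sparsity alternatively enforced by a
  minimum-spike threshold (greedy pool merging).
* AR(p>=2): projected-gradient (FISTA) on the spike vector with the AR
  impulse-response kernel, followed by thresholding and a nonnegative
  least-squares refit on the detected support.
"""

from __future__ import annotations

from dataclasses import dataclass

import numpy as np
from scipy import signal
from scipy.optimize import nnls

__all__ = [
    "ARModel",
    "fit_ar_coefficients",
    "ar_impulse_response",
    "oasis_ar1",
    "deconvolve_trace",
    "project_residual_trace",
    "update_temporal",
]


@dataclass
class ARModel:
    """AR(p) calcium dynamics: coefficients and derived quantities."""

    coefficients: np.ndarray  # (p,)

    @property
    def order(self) -> int:
        return len(self.coefficients)

    def impulse_response(self, T: int) -> np.ndarray:
        return ar_impulse_response(self.coefficients, T)

    def spikes_from_trace(self, c: np.ndarray) -> np.ndarray:
        """Apply the banded difference operator: s = G c."""
        s = c.copy().astype(np.float64)
        for j, g in enumerate(self.coefficients, start=1):
            s[j:] -= g * c[:-j]
        return s


def ar_impulse_response(coefficients, T: int) -> np.ndarray:
    h = np.zeros(T)
    h[0] = 1.0
    p = len(coefficients)
    for t in range(1, T):
        h[t] = sum(coefficients[j] * h[t - 1 - j] for j in range(min(p, t)))
    return h


def _project_stable(coefficients, max_modulus=0.99):
    poly = np.concatenate([[1.0], -np.asarray(coefficients, dtype=float)])
    roots = np.roots(poly)
    mods = np.abs(roots)
    if np.all(mods <= max_modulus) and np.all(
        (np.abs(roots.imag) > 1e-12) | (roots.real >= 0)
    ):
        return np.asarray(coefficients, dtype=float)
    roots = np.where(mods > max_modulus, roots * (max_modulus / np.maximum(mods, 1e-12)), roots)
    # real roots are kept nonnegative (monotone decay between spikes)
    roots = np.where((np.abs(roots.imag) <= 1e-12) & (roots.real < 0), 0.0, roots)
    new_poly = np.real(np.poly(roots))
    return -new_poly[1:]


def fit_ar_coefficients(y, p: int, sigma: float, max_modulus: float = 0.95,
                        tail_lags: tuple = (3, 8)) -> ARModel:
    """Noise-corrected Yule-Walker estimate of the AR coefficients, with a
    robust fallback.

    The lag-0 autocovariance of the observed trace is reduced by the noise
    variance ``sigma**2`` before solving.  The Yule-Walker fit is kept only
    when its characteristic roots are real, nonnegative and at most
    ``max_modulus`` (a non-oscillating, decaying calcium kernel); otherwise
    — the normal equations are ill-conditioned for traces contaminated by
    slow background residuals — the model falls back to an AR(1) whose
    decay rate is the median of the tail autocovariance ratios
    ``acov(k+1)/acov(k)``, which are insensitive to white noise and far
    more stable than the lag-1 ratio.
    """
    y = np.asarray(y, dtype=np.float64)
    T = len(y)
    if T <= 3 * p:
        raise ValueError("trace too short for AR fitting")
    yc = y - y.mean()
    kmax = max(p + 1, tail_lags[1])
    acov = np.array([yc[: T - k] @ yc[k:] / T for k in range(kmax + 1)])
    acov0 = max(acov[0] - sigma**2, 1e-12)
    # autocorrelated signal must be present (white noise -> no dynamics)
    if acov0 <= 1e-12 or acov[1] <= 0.25 * acov[0]:
        return ARModel(np.zeros(p))
    ac = acov.copy()
    ac[0] = acov0
    # Overdetermined Yule-Walker: the AR recursion must hold for the
    # autocovariance at every positive lag, so regress ac[k+1] on
    # [ac[k], ..., ac[k-p+1]] over k = 1..kmax-1.  Only the first equation
    # touches the noise-corrected lag 0, making the fit robust both to the
    # noise correction and to the near-singular plain p x p system.
    rows = np.array([[ac[k - j] for j in range(p)] for k in range(1, kmax)])
    rhs = np.array([ac[k + 1] for k in range(1, kmax)])
    gammas, *_ = np.linalg.lstsq(rows, rhs, rcond=None)
    poly = np.concatenate([[1.0], -gammas])
    roots = np.roots(poly)
    ok = (np.all(np.abs(roots.imag) < 1e-9)
          and np.all(roots.real >= 0)
          and np.all(roots.real <= max_modulus))
    if ok:
        return ARModel(np.asarray(gammas, dtype=float))
    # robust fallback: exponential-decay AR(1) from tail ratios
    k0, k1 = tail_lags
    k1 = min(k1, kmax)
    ratios = [acov[k + 1] / acov[k] for k in range(k0, k1) if acov[k] > 0]
    r = float(np.clip(np.median(ratios), 0.2, max_modulus)) if ratios else 0.0
    gammas = np.zeros(p)
    gammas[0] = r
    return ARModel(gammas)


def oasis_ar1(y, gamma: float, lam: float = 0.0, s_min: float = 0.0):
    """Exact AR(1) constrained deconvolution by pool adjacent violators.

    Solves ``min_c 0.5 ||y - c||^2 + lam * sum(s)`` subject to
    ``s_t = c_t - gamma c_{t-1} >= 0`` (with ``s_1 = c_1``).  With
    ``s_min > 0`` (and typically ``lam = 0``) pools whose onset jump is
    positive but below ``s_min`` are greedily merged away, the thresholded
    variant used for hard-sparsity deconvolution.

    Returns ``(c, s)``.
    """
    y = np.asarray(y, dtype=np.float64)
    T = len(y)
    # absorb the L1 penalty into the data: sum(s) = sum_t mu_t c_t
    mu = np.full(T, 1.0 - gamma)
    mu[-1] = 1.0
    ytil = y - lam * mu

    # pools: [value, weight, start, length]
    pools: list[list[float]] = []

    def merge(p, q):
        f = gamma ** p[3]
        w = p[1] + f * f * q[1]
        v = (p[1] * p[0] + f * q[1] * q[0]) / w
        return [v, w, p[2], p[3] + q[3]]

    for t in range(T):
        pools.append([ytil[t], 1.0, t, 1])
        while len(pools) > 1:
            p, q = pools[-2], pools[-1]
            if q[0] >= gamma ** p[3] * p[0] - 1e-15:
                break
            pools[-2:] = [merge(p, q)]

    if s_min > 0:
        # greedily remove undersized onsets (smallest first), restoring
        # the violation-free pool structure after each merge
        while len(pools) > 1:
            # onset at pool i start: v_i - gamma * (end value of pool i-1)
            onsets = [
                pools[i][0] - gamma * pools[i - 1][0] * gamma ** (pools[i - 1][3] - 1)
                for i in range(1, len(pools))
            ]
            small = [
                (s, i + 1) for i, s in enumerate(onsets) if 0 < s < s_min
            ]
            if not small:
                break
            _, j = min(small)
            pools[j - 1 : j + 1] = [merge(pools[j - 1], pools[j])]
            # restore violation-free structure around the merge point
            k = j - 1
            while 0 < k < len(pools):
                p, q = pools[k - 1], pools[k]
                if q[0] >= gamma ** p[3] * p[0] - 1e-15:
                    break
                pools[k - 1 : k + 1] = [merge(p, q)]
                k -= 1

    c = np.empty(T)
    for v, w, t0, length in pools:
        v = max(v, 0.0)
        c[int(t0) : int(t0) + int(length)] = v * gamma ** np.arange(int(length))
    s = np.empty(T)
    s[0] = c[0]
    s[1:] = c[1:] - gamma * c[:-1]
    s[np.abs(s) < 1e-12] = 0.0
    return c, s


def _fista_deconvolve(y, h, lam, n_iters=250, tol=1e-9):
    """FISTA for min_s 0.5||conv(h, s) - y||^2 + lam * 1's, s >= 0."""
    T = len(y)
    n = 2 * T
    H = np.fft.rfft(h, n)
    L = float(np.max(np.abs(H) ** 2))
    L = max(L, 1e-12)

    def conv(v, kernel_fft):
        return np.fft.irfft(np.fft.rfft(v, n) * kernel_fft, n)[:T]

    Hrev = np.fft.rfft(h[::-1], n)

    def corr(v):
        # correlation with h == convolution with reversed h, aligned causally
        full = np.fft.irfft(np.fft.rfft(v, n) * Hrev, n)
        return full[T - 1 : 2 * T - 1]

    s = np.zeros(T)
    z = s.copy()
    tk = 1.0
    prev_obj = np.inf
    for _ in range(n_iters):
        r = conv(z, H) - y
        grad = corr(r) + lam
        s_new = np.maximum(z - grad / L, 0.0)
        tk_new = 0.5 * (1 + np.sqrt(1 + 4 * tk**2))
        z = s_new + (tk - 1) / tk_new * (s_new - s)
        s, tk = s_new, tk_new
        obj = 0.5 * float(((conv(s, H) - y) ** 2).sum()) + lam * s.sum()
        if abs(prev_obj - obj) <= tol * max(abs(prev_obj), 1.0):
            break
        prev_obj = obj
    return s


def _refit_on_support(y, h, support):
    """Nonnegative LS refit of spike amplitudes on a fixed support."""
    T = len(y)
    cols = np.zeros((T, len(support)))
    for j, t0 in enumerate(support):
        cols[t0:, j] = h[: T - t0]
    amps, _ = nnls(cols, y)
    s = np.zeros(T)
    s[support] = amps
    return s


def deconvolve_trace(y, ar: ARModel, sigma: float, mode: str = "thresholded",
                     s_min: float | None = None, lam: float | None = None,
                     s_min_factor: float = 3.0, optimize_baseline: bool = True,
                     n_baseline_iters: int = 4):
    """Denoise and deconvolve one trace under the AR constraint.

    Parameters
    ----------
    y : ndarray (T,)
        Unconstrained (noisy) trace estimate.
    ar : ARModel
    sigma : float
        Noise standard deviation of ``y``; calibrates the default sparsity.
    mode : {"thresholded", "l1"}
        Hard minimum-spike threshold (default ``s_min_factor * sigma *
        ||impulse response||``) or an L1 penalty on the spikes.
    optimize_baseline : bool
        Jointly estimate a free scalar baseline by alternation.

    Returns
    -------
    (c, s, baseline)
    """
    y = np.asarray(y, dtype=np.float64)
    T = len(y)
    h = ar.impulse_response(T)
    hnorm = float(np.linalg.norm(h))
    if mode == "thresholded":
        # matched-filter calibration: a spike of amplitude s yields a
        # detection statistic s * ||h|| / sigma, so require it to be
        # at least s_min_factor
        smin = s_min if s_min is not None else s_min_factor * sigma / max(hnorm, 1e-12)
        lam_eff = 0.0
    elif mode == "l1":
        smin = 0.0
        lam_eff = lam if lam is not None else sigma * hnorm
    else:
        raise ValueError(f"unknown sparsity mode {mode!r}")

    if np.allclose(ar.coefficients, 0):
        # degenerate dynamics: spikes are the positive part of the trace
        b = float(np.median(y)) if optimize_baseline else 0.0
        c = np.maximum(y - b, 0.0)
        if smin > 0:
            c[c < smin] = 0.0
        return c, c.copy(), b

    b = float(np.percentile(y, 10)) if optimize_baseline else 0.0
    c = np.zeros(T)
    s = np.zeros(T)
    for _ in range(n_baseline_iters if optimize_baseline else 1):
        yb = y - b
        if ar.order == 1 or not np.any(ar.coefficients[1:]):
            c, s = oasis_ar1(yb, float(ar.coefficients[0]), lam=lam_eff, s_min=smin)
        else:
            s = _fista_deconvolve(yb, h, lam_eff if lam_eff > 0 else 0.5 * sigma)
            # the L1 solution smears each spike over neighbouring bins and
            # shrinks it; gather support generously, let the NNLS refit
            # consolidate the mass, and only then apply the spike threshold
            low = max(0.25 * smin, 1e-8) if smin > 0 else 1e-8
            support = np.flatnonzero(s >= low)
            if len(support) > 400:
                support = support[np.argsort(-s[support])[:400]]
                support.sort()
            if len(support):
                s = _refit_on_support(yb, h, support)
                if smin > 0:
                    support = np.flatnonzero(s >= smin)
                    s = _refit_on_support(yb, h, support) if len(support) else np.zeros(T)
            else:
                s = np.zeros(T)
            c = signal.fftconvolve(s, h)[:T]
            c = np.maximum(c, 0.0)
        if not optimize_baseline:
            break
        b_new = float(np.mean(y - c))
        if abs(b_new - b) < 1e-9 * max(1.0, abs(b)):
            b = b_new
            break
        b = b_new
    return c, s, b


def project_residual_trace(Y_res, a, c_prev, support=None):
    """Unconstrained trace estimate by projecting the residual on a footprint.

    ``y_hat = c_prev + a' Y_res / (a'a)`` where ``Y_res`` excludes this
    neuron's own contribution having been left in the residual.
    """
    nrm = float(a @ a)
    if nrm <= 0:
        raise ValueError("zero footprint; delete the component first")
    if support is not None:
        return c_prev + (a[support] @ Y_res[support]) / nrm
    return c_prev + (a @ Y_res) / nrm


def update_temporal(Y, A, C, S, b0, Bf, ar_models, sigma_traces=None,
                    order=None, **deconv_kwargs):
    """One block-coordinate pass over all traces, then refresh ``b0``.

    Neurons are visited in the given order (default: descending trace
    energy).  Returns ``(C, S, C_raw, b0, ar_models, kept)`` where ``kept``
    flags components whose trace did not collapse to zero.
    """
    K, T = C.shape
    C = C.astype(np.float64).copy()
    S = S.astype(np.float64).copy()
    C_raw = np.zeros_like(C)
    R = Y - b0[:, None] - Bf
    if K:
        R = R - A @ C
    if order is None:
        order = np.argsort(-np.einsum("kt,kt->k", C, C))
    kept = np.ones(K, dtype=bool)
    supports = [np.flatnonzero(A[:, i] > 0) for i in range(K)]
    for i in order:
        a = A[:, i]
        idx = supports[i]
        if len(idx) == 0:
            kept[i] = False
            continue
        y_hat = project_residual_trace(R, a, C[i], support=idx)
        C_raw[i] = y_hat
        sig = (
            float(sigma_traces[i]) if sigma_traces is not None
            else _trace_noise(y_hat)
        )
        c_new, s_new, _ = deconvolve_trace(y_hat, ar_models[i], sig, **deconv_kwargs)
        # monotone guard: the thresholded deconvolution is not an exact
        # projection, so keep the previous trace if the new one would
        # increase this neuron's (mean-adjusted) residual
        prev_err = _mean_adjusted_sq(y_hat - C[i])
        new_err = _mean_adjusted_sq(y_hat - c_new)
        if new_err > prev_err and np.any(C[i] > 0):
            continue
        if not np.any(c_new > 0):
            kept[i] = False
        R[idx] += np.outer(a[idx], C[i] - c_new)
        C[i] = c_new
        S[i] = s_new
    b0_new = estimate_b0_given_background(Y, A, C, Bf)
    return C, S, C_raw, b0_new, ar_models, kept


def _mean_adjusted_sq(r):
    r = r - r.mean()
    return float(r @ r)


def estimate_b0_given_background(Y, A, C, Bf):
    """Closed-form baseline refresh: per-pixel mean of ``Y - A C - Bf``."""
    b0 = Y.mean(axis=1) - Bf.mean(axis=1)
    if A is not None and A.shape[1] > 0:
        b0 = b0 - A @ C.mean(axis=1)
    return np.asarray(b0, dtype=np.float32)


def _trace_noise(y):
    from .summary import estimate_noise_sigma

    if len(y) >= 32:
        return float(estimate_noise_sigma(y[None])[0])
    return float(np.std(np.diff(y)) / np.sqrt(2)) if len(y) > 1 else 0.0
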