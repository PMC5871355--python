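"""Synthetic one-photon microendoscopic movies with ground truth.

The generator emulates the standard benchmark conditions for this recording
modality: spherical 2-D Gaussian somata, Bernoulli spike trains convolved
with a double-exponential calcium kernel, a handful of spatially wide
background sources with random-walk temporal dynamics (out-of-focus
fluorescence), an optional blood-vessel artifact, and white Gaussian noise
whose standard deviation can be inflated by an SNR-reduction factor.

Presets
-------
``background``   many background sources, used to benchmark background
                 recovery (base geometry 256 x 256 x 1000, 50 neurons,
                 23 sources, vessel on).
``population``   dense population for initialization / full-pipeline
                 benchmarks (base geometry 253 x 316 x 2000, 200 neurons).
``pair``         two overlapping neurons whose traces share a common
                 component tuned to a requested correlation level.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
from scipy.ndimage import gaussian_filter
from scipy.optimize import brentq

from .movie import Movie

__all__ = [
    "SimConfig",
    "SimulationTruth",
    "simulate_footprints",
    "simulate_traces",
    "calcium_kernel",
    "simulate_background",
    "make_correlated_pair",
    "assemble_movie",
    "simulate_movie",
    "preset_config",
]

# Homogeneous noise floor: a unit-peak footprint times a single-spike
# transient (peak ~0.578 for tau_d=6, tau_r=1) reaches ~10 sigma at
# SNR-reduction factor 1.
DEFAULT_SIGMA = 0.0578


@dataclass
class SimConfig:
    """Study conditions for one synthetic movie."""

    fov_shape: tuple = (128, 128)
    n_frames: int = 1000
    n_neurons: int = 50
    neuron_diameter: int = 12        # l, pixels
    spike_prob: float = 0.01         # Bernoulli rate per timebin
    tau_d: float = 6.0               # decay time constant, timebins
    tau_r: float = 1.0               # rise time constant, timebins
    n_bg_sources: int = 10
    vessel: bool = False
    bg_var_ratio: float = 10.0       # background variance / neural variance
    # Density (neurons per pixel) used as the reference for the background
    # amplitude instead of the actual neuron count; lets sparse scenes (the
    # two-neuron preset) carry the same background level as a dense
    # population in the same field of view.
    bg_ref_density: float | None = None
    baseline: float = 2.0            # constant per-pixel offset
    sigma: float = DEFAULT_SIGMA     # noise std at SNR factor 1
    snr_factor: float = 1.0          # multiplies sigma
    trace_correlation: float | None = None  # pair mode target correlation
    # Skip retaining the dense background and noise arrays in the truth
    # object (the exact decomposition is then not re-checkable, but large
    # benchmark scenes only need A/C/S and the centres).
    light_truth: bool = False
    seed: int = 0

    def __post_init__(self):
        if self.tau_d <= self.tau_r:
            raise ValueError("decay time constant must exceed rise time constant")


@dataclass
class SimulationTruth:
    """Exact ground-truth decomposition Y = A C + B + E."""

    A: np.ndarray          # (d, K) footprints
    C: np.ndarray          # (K, T) calcium traces
    S: np.ndarray          # (K, T) spikes
    B: np.ndarray          # (d, T) background incl. constant baseline
    sigma: np.ndarray      # (d,) noise std actually used
    E: np.ndarray          # (d, T) realized noise
    centers: np.ndarray    # (K, 2) neuron centres (row, col)


def _gaussian_footprint(fov_shape, center, widths, trunc=1e-3):
    H, W = fov_shape
    yy, xx = np.mgrid[0:H, 0:W]
    g = np.exp(
        -((yy - center[0]) ** 2) / (2 * widths[0] ** 2)
        - ((xx - center[1]) ** 2) / (2 * widths[1] ** 2)
    )
    g[g < trunc] = 0.0
    return g.ravel()


def simulate_footprints(n_neurons, fov_shape, l, rng, centers=None):
    """Spherical 2-D Gaussian footprints, unit peak.

    Per-axis Gaussian widths are drawn from N(l/4, (l/40)^2); footprints are
    truncated at 1e-3 of the peak.  Returns ``(A, centers)``.
    """
    H, W = fov_shape
    if centers is None:
        centers = np.column_stack([rng.uniform(0, H, n_neurons),
                                   rng.uniform(0, W, n_neurons)])
    centers = np.asarray(centers, dtype=float)
    A = np.zeros((H * W, len(centers)), dtype=np.float32)
    for k, c in enumerate(centers):
        widths = rng.normal(l / 4.0, l / 40.0, size=2)
        widths = np.clip(widths, l / 8.0, None)  # guard degenerate draws
        a = _gaussian_footprint(fov_shape, c, widths)
        peak = a.max()
        A[:, k] = a / peak if peak > 0 else a  # exact unit peak on the grid
    return A, centers


def calcium_kernel(tau_d, tau_r, T):
    """Causal double-exponential response g(t) = exp(-t/tau_d) - exp(-t/tau_r)."""
    t = np.arange(T)
    return np.exp(-t / tau_d) - np.exp(-t / tau_r)


def simulate_traces(n_neurons, T, spike_prob, tau_d, tau_r, rng):
    """Bernoulli spike trains convolved with the calcium kernel."""
    S = (rng.random((n_neurons, T)) < spike_prob).astype(np.float32)
    g = calcium_kernel(tau_d, tau_r, T)
    C = np.empty_like(S)
    for k in range(n_neurons):
        C[k] = np.convolve(S[k], g)[:T]
    return C, S


def _random_walk(T, rng):
    w = np.cumsum(rng.standard_normal(T))
    w -= w.mean()
    sd = w.std()
    return w / sd if sd > 0 else w


def simulate_background(fov_shape, n_sources, l, T, rng, vessel=False,
                        extra_profiles=None):
    """Fluctuating background: wide Gaussian sources with random-walk traces.

    Source widths follow the neuron width law scaled by 5; the optional
    vessel footprint is a cubic curve across the FOV rasterised and blurred
    with a width-3 Gaussian.  Temporal traces are variance-normalised random
    walks (amplitude scaling happens at assembly time).  ``extra_profiles``
    adds sources with caller-supplied temporal traces (used by the pair
    preset to share a trace with the background).

    Returns ``(A_bg, C_bg)`` with ``B_fluct = A_bg @ C_bg``.
    """
    H, W = fov_shape
    profiles = []
    traces = []
    for _ in range(n_sources):
        c = (rng.uniform(0, H), rng.uniform(0, W))
        widths = 5.0 * np.clip(rng.normal(l / 4.0, l / 40.0, size=2), l / 8.0, None)
        profiles.append(_gaussian_footprint(fov_shape, c, widths, trunc=1e-3))
        traces.append(_random_walk(T, rng))
    if vessel:
        x = np.arange(W)
        a3 = rng.uniform(-2.0, 2.0) / max(W, 1) ** 2
        a1 = rng.uniform(-0.5, 0.5)
        c0 = rng.uniform(0.3 * H, 0.7 * H)
        yc = a3 * (x - W / 2) ** 3 + a1 * (x - W / 2) + c0
        img = np.zeros((H, W))
        rows = np.clip(np.round(yc).astype(int), 0, H - 1)
        img[rows, x] = 1.0
        img = gaussian_filter(img, 3.0)
        img /= img.max() if img.max() > 0 else 1.0
        profiles.append(img.ravel())
        traces.append(_random_walk(T, rng))
    if extra_profiles:
        for prof, tr in extra_profiles:
            profiles.append(prof)
            traces.append(tr)
    if not profiles:
        return (np.zeros((H * W, 0), dtype=np.float32),
                np.zeros((0, T), dtype=np.float32))
    return (np.array(profiles, dtype=np.float32).T,
            np.array(traces, dtype=np.float32))


def make_correlated_pair(c1, c2, gamma_level, rng_or_c3, T=None, spike_prob=0.01,
                         tau_d=6.0, tau_r=1.0):
    """Mix two traces with a shared component to a target correlation.

    ``c' = (1 - rho) c + rho c3`` with ``c3`` simulated like ``c1``/``c2``
    and ``rho`` solved numerically so that ``corr(c1', c2')`` hits
    ``gamma_level``.  Returns ``(c1', c2', c3, rho)``; the shared trace is
    also meant to be added to the background to mimic neuron-background
    correlation.
    """
    if not 0 <= gamma_level < 1:
        raise ValueError("correlation level must be in [0, 1)")
    if isinstance(rng_or_c3, np.random.Generator):
        if T is None:
            T = len(c1)
        c3 = simulate_traces(1, T, spike_prob, tau_d, tau_r, rng_or_c3)[0][0]
    else:
        c3 = np.asarray(rng_or_c3)

    def realized(rho):
        u = (1 - rho) * c1 + rho * c3
        v = (1 - rho) * c2 + rho * c3
        return np.corrcoef(u, v)[0, 1]

    if gamma_level <= realized(0.0):
        rho = 0.0
    else:
        try:
            rho = brentq(lambda r: realized(r) - gamma_level, 0.0, 1.0 - 1e-9)
        except ValueError as err:
            raise ValueError(f"correlation level {gamma_level} infeasible") from err
    return (1 - rho) * c1 + rho * c3, (1 - rho) * c2 + rho * c3, c3, rho


def assemble_movie(A, C, B, sigma, snr_factor, rng, fov_shape, S=None,
                   centers=None, light=False):
    """Add white Gaussian noise and build the Movie plus its exact truth.

    With ``light=True`` the noise is generated chunk-wise in place and the
    truth object retains neither the background nor the noise array
    (halves the peak memory of large scenes).
    """
    d, T = B.shape
    sigma = np.broadcast_to(np.asarray(sigma, dtype=np.float32), (d,)).copy()
    if light:
        Y = (A @ C).astype(np.float32)
        Y += B
        chunk = max(1, int(2e7) // max(T, 1))
        for start in range(0, d, chunk):
            end = min(start + chunk, d)
            Y[start:end] += (snr_factor * sigma[start:end, None]) * \
                rng.standard_normal((end - start, T)).astype(np.float32)
        B_store = None
        E = None
    else:
        E = (snr_factor * sigma)[:, None] * rng.standard_normal((d, T)).astype(np.float32)
        Y = A @ C + B + E
        B_store = B
    truth = SimulationTruth(
        A=A, C=C, S=S if S is not None else np.zeros_like(C), B=B_store,
        sigma=snr_factor * sigma, E=E,
        centers=centers if centers is not None else np.zeros((A.shape[1], 2)),
    )
    return Movie(Y, fov_shape), truth


def simulate_movie(config: SimConfig):
    """Generate one movie under the given study conditions.

    Returns ``(Movie, SimulationTruth)``.  The fluctuating background is
    scaled so its total variance is ``bg_var_ratio`` times the total neural
    variance (background dominates, as in real one-photon recordings).
    """
    rng = np.random.default_rng(config.seed)
    fov, T = config.fov_shape, config.n_frames
    d = fov[0] * fov[1]
    l = config.neuron_diameter

    if config.trace_correlation is not None:
        # two overlapping neurons at fixed spacing near the FOV centre
        cy, cx = fov[0] / 2.0, fov[1] / 2.0
        off = l / 2.0
        centers = np.array([[cy, cx - off / 2], [cy, cx + off / 2]])
        A, centers = simulate_footprints(2, fov, l, rng, centers=centers)
        C, S = simulate_traces(2, T, config.spike_prob, config.tau_d,
                               config.tau_r, rng)
        c1p, c2p, c3, _ = make_correlated_pair(
            C[0], C[1], config.trace_correlation, rng, T,
            config.spike_prob, config.tau_d, config.tau_r)
        C = np.vstack([c1p, c2p]).astype(np.float32)
        shared_profile = _gaussian_footprint(
            fov, (cy, cx), (5 * l / 4.0, 5 * l / 4.0))
        c3n = (c3 - c3.mean())
        c3n /= c3n.std() if c3n.std() > 0 else 1.0
        extra = [(shared_profile.astype(np.float32), c3n.astype(np.float32))]
    else:
        A, centers = simulate_footprints(config.n_neurons, fov, l, rng)
        C, S = simulate_traces(config.n_neurons, T, config.spike_prob,
                               config.tau_d, config.tau_r, rng)
        extra = None

    A_bg, C_bg = simulate_background(fov, config.n_bg_sources, l, T, rng,
                                     vessel=config.vessel,
                                     extra_profiles=extra)
    neural_var = float((A.astype(np.float64) ** 2).sum(0)
                       @ C.astype(np.float64).var(1)) if A.shape[1] else 0.0
    if config.bg_ref_density is not None and A.shape[1]:
        per_neuron = neural_var / A.shape[1]
        neural_var = per_neuron * config.bg_ref_density * d
    if A_bg.shape[1] > 0:
        Bf = A_bg @ C_bg
        Bf -= Bf.mean(axis=1, keepdims=True)
        bg_var = float((Bf.astype(np.float64) ** 2).sum() / T)
        if bg_var > 0 and neural_var > 0:
            Bf *= np.sqrt(config.bg_var_ratio * neural_var / bg_var)
        B = Bf + config.baseline
    else:
        B = np.full((d, T), config.baseline, dtype=np.float32)
    return assemble_movie(A, C, B.astype(np.float32), config.sigma,
                          config.snr_factor, rng, fov, S=S, centers=centers,
                          light=config.light_truth)


def preset_config(name: str, scale: float = 1.0, seed: int = 0,
                  **overrides) -> SimConfig:
    """Named study conditions, optionally shrunk by ``scale``.

    ``scale`` multiplies the FOV side lengths and the frame count, and
    scales the neuron / background-source counts with the FOV area.
    """
    base = {
        "background": dict(fov_shape=(256, 256), n_frames=1000, n_neurons=50,
                           n_bg_sources=23, vessel=True),
        "population": dict(fov_shape=(253, 316), n_frames=2000, n_neurons=200,
                           n_bg_sources=15, vessel=True),
        "pair": dict(fov_shape=(64, 64), n_frames=2000, n_neurons=2,
                     n_bg_sources=3, vessel=False, trace_correlation=0.9,
                     bg_ref_density=200.0 / (253 * 316)),
    }
    if name not in base:
        raise ValueError(f"unknown preset {name!r}")
    cfg = dict(base[name])
    if scale != 1.0:
        H, W = cfg["fov_shape"]
        cfg["fov_shape"] = (max(16, int(round(H * scale))),
                            max(16, int(round(W * scale))))
        cfg["n_frames"] = max(64, int(round(cfg["n_frames"] * scale)))
        area = scale ** 2
        if name != "pair":
            cfg["n_neurons"] = max(1, int(round(cfg["n_neurons"] * area)))
            cfg["n_bg_sources"] = max(1, int(round(cfg["n_bg_sources"] * area)))
    cfg.update(overrides)
    return SimConfig(seed=seed, **cfg)
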