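"""The CNMF-E model object and its fitted results.

The movie is modelled as ``Y = A C + b0 1' + Bf + E``: nonnegative, local
footprints ``A``; nonnegative AR-constrained calcium traces ``C`` (with
deconvolved activity ``S``); a constant per-pixel baseline ``b0``; and a
fluctuating background ``Bf`` expressed through ring weights,
``Bf = W (Y - A C - b0 1')``.  Fitting alternates greedy initialization,
ring-background regression, support-constrained HALS footprint updates and
per-neuron constrained deconvolution, with automated interventions (merge,
SNR filter, residual pickup, footprint cleanup) between rounds.

Typical use::

    model = CNMFE(movie, neuron_diameter=12, min_corr=0.8, min_pnr=10)
    res = model.fit()
    print(res.summary())
"""

from __future__ import annotations

from dataclasses import dataclass, field, asdict

import numpy as np

from . import background as bg_mod
from . import initialization as init_mod
from . import spatial as spatial_mod
from . import temporal as temporal_mod
from .evaluation import compute_snr, pairwise_correlations
from .movie import Movie, save_results
from .summary import compute_summary_images, estimate_noise_sigma

__all__ = ["FitConfig", "CNMFE", "CNMFEResults", "compute_rss",
           "merge_components", "filter_components_by_snr", "detect_from_residual"]


@dataclass
class FitConfig:
    """All tunable parameters of the fit.

    The five key parameters (neuron diameter ``l``, ring radius ``ln``,
    seeding thresholds ``min_corr``/``min_pnr``, outlier factor ``zeta``)
    follow the standard defaults for this method; everything else is an
    implementation knob with a documented default.
    """

    neuron_diameter: int = 12          # l, pixels
    ring_radius: float | None = None   # ln, pixels; default 2 * l
    min_corr: float = 0.8              # Lmin
    min_pnr: float = 10.0              # Pmin
    zeta: float = 10.0                 # outlier threshold / noise ratio
    max_neurons: int | None = None
    # initialization details
    bg_corr_cut: float = 0.3
    neuron_corr_cut: float = 0.7
    min_pixels: int = 5
    bg_stat: str = "median"
    # background
    # Ring-regression shrinkage: inside the pipeline the neural signal is
    # subtracted before the fit, so a nearly unpenalised regression that
    # absorbs all smooth structure gives the cleanest neural residual; the
    # standalone background-recovery default (background.estimate_background)
    # is stronger because there the background estimate itself is the target.
    n_robust_iters: int = 2
    ridge: float = 0.3
    # spatial
    hals_sweeps: int = 5
    support_dilation: int = 2
    opening_radius: int = 1
    # temporal
    ar_order: int | None = None        # default: 2 at >=10 Hz (or unknown), else 1
    sparsity_mode: str = "thresholded"
    s_min_factor: float = 3.0
    # interventions
    merge_spatial: float = 0.65
    merge_temporal: float = 0.5
    # Drop components whose denoised trace carries essentially no signal
    # relative to their residual; kept permissive so weak real neurons in
    # low-SNR recordings survive (the filter targets empty components, not
    # marginal ones).
    snr_cutoff: float = 0.2
    # The residual pass uses lower thresholds than the raw-movie pass: once
    # the background is subtracted, genuinely missed neurons (e.g. the
    # weaker member of a highly correlated pair) only retain a fraction of
    # their peak-to-noise ratio in the residual.
    pickup_residual: bool = True
    pickup_min_corr: float | None = None  # default: 0.75 * min_corr
    pickup_min_pnr: float | None = None   # default: 0.4 * min_pnr
    decorrelate_overlap: float = 0.65
    # outer loop
    max_outer_iters: int = 5
    min_outer_iters: int = 2
    seed: int = 0

    def resolved_ring_radius(self) -> float:
        return self.ring_radius if self.ring_radius is not None else 2.0 * self.neuron_diameter

    def resolved_ar_order(self, frame_rate) -> int:
        if self.ar_order is not None:
            return self.ar_order
        return 1 if (frame_rate is not None and frame_rate < 10) else 2


def compute_rss(Y, A, C, b0, Bf) -> float:
    """Residual sum of squares ``||Y - A C - b0 1' - Bf||_F^2``."""
    R = Y.astype(np.float64) - b0.astype(np.float64)[:, None] - Bf
    if A is not None and A.shape[1] > 0:
        R -= A.astype(np.float64) @ C
    return float((R**2).sum())


def _rank1_nonneg(M, n_iters=60):
    """Leading nonnegative rank-1 factors of a nonnegative matrix
    (deterministic power iteration)."""
    v = M.sum(axis=0).astype(np.float64)
    nv = np.linalg.norm(v)
    v = v / nv if nv > 0 else np.ones(M.shape[1]) / np.sqrt(M.shape[1])
    for _ in range(n_iters):
        u = M @ v
        nu = np.linalg.norm(u)
        if nu == 0:
            break
        u /= nu
        v = M.T @ u
        nv = np.linalg.norm(v)
        if nv == 0:
            break
        v /= nv
    u = np.maximum(M @ v, 0.0)
    scale = np.linalg.norm(u)
    if scale > 0:
        u /= scale
    c = np.maximum(M.T @ u, 0.0)
    return u, c


def merge_components(A, C, S, C_raw, ar_models, spatial_thr=0.65,
                     temporal_thr=0.5, fov_shape=None, ar_order=2, log=None):
    """Merge groups of components that overlap spatially and are temporally
    correlated above both thresholds.

    Each connected group is replaced by the rank-1 factorisation of the sum
    of its members' spatiotemporal activity, restricted to the union
    support; the AR model is refit on the merged trace.
    """
    K = A.shape[1]
    if K < 2:
        return A, C, S, C_raw, ar_models
    norms = np.linalg.norm(A, axis=0)
    norms[norms == 0] = 1.0
    spat = (A / norms).T @ (A / norms)
    temp = pairwise_correlations(C)
    adj = (spat > spatial_thr) & (temp > temporal_thr)
    np.fill_diagonal(adj, False)

    parent = list(range(K))

    def find(x):
        while parent[x] != x:
            parent[x] = parent[parent[x]]
            x = parent[x]
        return x

    for i in range(K):
        for j in range(i + 1, K):
            if adj[i, j]:
                pi, pj = find(i), find(j)
                if pi != pj:
                    parent[pj] = pi
    groups: dict[int, list[int]] = {}
    for i in range(K):
        groups.setdefault(find(i), []).append(i)

    new_A, new_C, new_S, new_Craw, new_ar = [], [], [], [], []
    for members in groups.values():
        if len(members) == 1:
            k = members[0]
            new_A.append(A[:, k])
            new_C.append(C[k])
            new_S.append(S[k])
            new_Craw.append(C_raw[k])
            new_ar.append(ar_models[k])
            continue
        if log is not None:
            log.append({"intervention": "merge", "members": list(map(int, members))})
        support = np.flatnonzero((A[:, members] > 0).any(axis=1))
        M = A[np.ix_(support, members)].astype(np.float64) @ C[members]
        u, c_new = _rank1_nonneg(M)
        a_new = np.zeros(A.shape[0])
        a_new[support] = u
        sigma = temporal_mod._trace_noise(c_new)
        ar = temporal_mod.fit_ar_coefficients(c_new, ar_order, sigma)
        c_den, s_new, _ = temporal_mod.deconvolve_trace(c_new, ar, sigma)
        new_A.append(a_new)
        new_C.append(c_den if np.any(c_den > 0) else c_new)
        new_S.append(s_new)
        new_Craw.append(C_raw[members].sum(axis=0))
        new_ar.append(ar)
    A2 = np.column_stack(new_A) if new_A else np.zeros((A.shape[0], 0))
    return (A2, np.array(new_C), np.array(new_S), np.array(new_Craw), new_ar)


def filter_components_by_snr(A, C, S, C_raw, ar_models, cutoff, log=None):
    """Drop components with trace SNR below the cutoff; sort by SNR desc."""
    K = A.shape[1]
    snrs = np.array([compute_snr(C_raw[k], C[k]) if np.any(C[k] != 0) else 0.0
                     for k in range(K)])
    keep = np.flatnonzero(snrs >= cutoff)
    if log is not None and len(keep) < K:
        dropped = sorted(set(range(K)) - set(keep.tolist()))
        log.append({"intervention": "snr_filter", "removed": list(map(int, dropped))})
    order = keep[np.argsort(-snrs[keep], kind="stable")]
    return (A[:, order], C[order], S[order], C_raw[order],
            [ar_models[k] for k in order], snrs[order])


def detect_from_residual(Y, fov_shape, A, C, b0, Bf, config: FitConfig, log=None,
                         sigma_filtered=None):
    """Run the greedy initializer on the model residual and return any new
    components (the same algorithm as the raw initialization, but with the
    background already removed).  ``sigma_filtered`` carries the noise map
    of the filtered raw movie so residual peak-to-noise ratios are judged
    against the true noise floor."""
    resid = Y - b0[:, None] - Bf
    if A is not None and A.shape[1] > 0:
        resid = resid - (A @ C).astype(np.float32)
    resid = np.maximum(resid, 0.0).astype(np.float32)
    res_movie = Movie(resid, fov_shape)
    summaries = compute_summary_images(res_movie, config.neuron_diameter,
                                       sigma=sigma_filtered)
    new = init_mod.greedy_initialize(
        res_movie, summaries,
        min_corr=(config.pickup_min_corr if config.pickup_min_corr is not None
                  else 0.75 * config.min_corr),
        min_pnr=(config.pickup_min_pnr if config.pickup_min_pnr is not None
                 else 0.4 * config.min_pnr),
        max_neurons=None, bg_corr_cut=config.bg_corr_cut,
        neuron_corr_cut=config.neuron_corr_cut,
        min_pixels=config.min_pixels, bg_stat=config.bg_stat,
    )
    if log is not None and new.n_components:
        log.append({"intervention": "residual_pickup",
                    "added": int(new.n_components)})
    return new


class CNMFE:
    """Source-extraction model for a one-photon calcium imaging movie.

    Parameters
    ----------
    movie : Movie
        Motion-corrected input movie.
    config : FitConfig, optional
        Full parameter set; keyword overrides are applied on top.
    """

    def __init__(self, movie: Movie, config: FitConfig | None = None, **overrides):
        self.movie = movie
        cfg = config if config is not None else FitConfig()
        if overrides:
            cfg = FitConfig(**{**asdict(cfg), **overrides})
        self.config = cfg

    @classmethod
    def from_file(cls, path, config: FitConfig | None = None, **overrides):
        from .movie import load_movie

        return cls(load_movie(path), config=config, **overrides)

    # -- fitting ---------------------------------------------------------

    def fit(self, verbose: bool = False) -> "CNMFEResults":
        cfg = self.config
        movie = self.movie
        Y = movie.data
        fov = movie.fov_shape
        d, T = Y.shape
        p = cfg.resolved_ar_order(movie.frame_rate)
        log: list = []
        rss_log: list = []

        def record(stage, A, C, b0, Bf):
            rss_log.append({"stage": stage, "rss": compute_rss(Y, A, C, b0, Bf),
                            "K": 0 if A is None else A.shape[1]})
            if verbose:
                print(f"[{stage}] K={rss_log[-1]['K']} rss={rss_log[-1]['rss']:.4g}")

        # 1. summary images and greedy initialization
        summaries = compute_summary_images(movie, cfg.neuron_diameter)
        sigma_raw = estimate_noise_sigma(Y)
        init = init_mod.greedy_initialize(
            movie, summaries, min_corr=cfg.min_corr, min_pnr=cfg.min_pnr,
            max_neurons=cfg.max_neurons, bg_corr_cut=cfg.bg_corr_cut,
            neuron_corr_cut=cfg.neuron_corr_cut, min_pixels=cfg.min_pixels,
            bg_stat=cfg.bg_stat)
        A = init.A.astype(np.float32)
        C_raw = init.C_raw.astype(np.float64)
        ar_models, C, S = self._deconvolve_all(C_raw, p, cfg)
        A, C, S, C_raw, ar_models = self._decorrelate(A, C, S, C_raw, ar_models, cfg, log)

        # 2. background from the neural residual
        ring = bg_mod.build_ring_index(fov, cfg.resolved_ring_radius())
        bg = bg_mod.estimate_background(Y, A, C, ring, sigma_raw, cfg.zeta,
                                        cfg.n_robust_iters, cfg.ridge)
        Bf = bg.fluctuating(Y, A, C).astype(np.float32)
        b0 = bg.b0
        record("background", A, C, b0, Bf)

        # 3. trace refinement against the background-subtracted movie
        if A.shape[1] > 0:
            C_raw = init_mod.refine_traces_given_background(A, Y, Bf, b0)
            ar_models, C, S = self._deconvolve_all(C_raw, p, cfg, ar_models)
            record("refine", A, C, b0, Bf)

        # 4. outer loop: spatial -> temporal -> interventions -> background
        for it in range(cfg.max_outer_iters):
            K_before = A.shape[1]
            if K_before > 0:
                # (P-S): support-constrained HALS with the background fixed
                supports = spatial_mod.determine_supports(A, fov, cfg.support_dilation)
                Y_tilde = (Y - Bf - Y.mean(axis=1, keepdims=True)).astype(np.float64)
                C_tilde = C - C.mean(axis=1, keepdims=True)
                A = spatial_mod.update_spatial(Y_tilde, C_tilde, A, supports,
                                               cfg.hals_sweeps)
                alive = np.linalg.norm(A, axis=0) > 0
                A, C, S, C_raw = A[:, alive], C[alive], S[alive], C_raw[alive]
                ar_models = [m for m, k in zip(ar_models, alive) if k]
                A = A.astype(np.float32)
                # b0 is part of (P-S) and has a closed-form update
                b0 = temporal_mod.estimate_b0_given_background(Y, A, C, Bf)
                record("spatial", A, C, b0, Bf)

                # (P-T): block-coordinate trace updates + b0 refresh
                C, S, C_raw, b0, ar_models, kept = temporal_mod.update_temporal(
                    Y, A, C, S, b0, Bf, ar_models,
                    mode=cfg.sparsity_mode, s_min_factor=cfg.s_min_factor)
                A, C, S, C_raw = A[:, kept], C[kept], S[kept], C_raw[kept]
                ar_models = [m for m, k in zip(ar_models, kept) if k]
                record("temporal", A, C, b0, Bf)

                # interventions: footprint cleanup first
                A, pp_kept = spatial_mod.postprocess_footprints(A, fov, cfg.opening_radius)
                if not pp_kept.all():
                    log.append({"intervention": "postprocess_drop",
                                "removed": int((~pp_kept).sum())})
                A, C, S, C_raw = A[:, pp_kept], C[pp_kept], S[pp_kept], C_raw[pp_kept]
                ar_models = [m for m, k in zip(ar_models, pp_kept) if k]
            if cfg.pickup_residual and it == 0:
                new = detect_from_residual(Y, fov, A, C, b0, Bf, self.config, log,
                                           sigma_filtered=summaries.sigma)
                if new.n_components:
                    A = np.column_stack([A, new.A]).astype(np.float32)
                    # restart all traces from the background-subtracted movie
                    # so appended components are demixed consistently
                    C_raw = init_mod.refine_traces_given_background(A, Y, Bf, b0)
                    ar_models, C, S = self._deconvolve_all(C_raw, p, cfg)
            if A.shape[1] > 1:
                A, C, S, C_raw, ar_models = merge_components(
                    A, C, S, C_raw, ar_models, cfg.merge_spatial,
                    cfg.merge_temporal, fov, p, log)
                A = A.astype(np.float32)
            if A.shape[1] > 0:
                A, C, S, C_raw, ar_models, snrs = filter_components_by_snr(
                    A, C, S, C_raw, ar_models, cfg.snr_cutoff, log)
            record("interventions", A, C, b0, Bf)

            # (P-B): background refresh
            bg = bg_mod.estimate_background(Y, A, C, ring, sigma_raw, cfg.zeta,
                                            cfg.n_robust_iters, cfg.ridge)
            Bf = bg.fluctuating(Y, A, C).astype(np.float32)
            b0 = bg.b0
            record("background", A, C, b0, Bf)

            if A.shape[1] == K_before and it + 1 >= cfg.min_outer_iters:
                break

        snrs = np.array([compute_snr(C_raw[k], C[k]) if np.any(C[k] != 0) else 0.0
                         for k in range(A.shape[1])])
        return CNMFEResults(
            model=self, A=A, C=C, S=S, C_raw=C_raw, background=bg, Bf=Bf,
            ar_models=ar_models, snr=snrs, rss_log=rss_log, log=log,
            fov_shape=fov, config=cfg, init_seeds=init.seeds)

    # -- helpers ---------------------------------------------------------

    @staticmethod
    def _deconvolve_all(C_raw, p, cfg: FitConfig, ar_models=None):
        K, T = C_raw.shape
        out_ar, C, S = [], np.zeros((K, T)), np.zeros((K, T))
        for k in range(K):
            sigma = temporal_mod._trace_noise(C_raw[k])
            ar = (ar_models[k] if ar_models is not None
                  else temporal_mod.fit_ar_coefficients(C_raw[k], p, sigma))
            c, s, _ = temporal_mod.deconvolve_trace(
                C_raw[k], ar, sigma, mode=cfg.sparsity_mode,
                s_min_factor=cfg.s_min_factor)
            out_ar.append(ar)
            C[k], S[k] = c, s
        return out_ar, C, S

    @staticmethod
    def _decorrelate(A, C, S, C_raw, ar_models, cfg: FitConfig, log):
        K = A.shape[1]
        if K < 2:
            return A, C, S, C_raw, ar_models
        norms = np.linalg.norm(A, axis=0)
        norms[norms == 0] = 1.0
        spat = (A / norms).T @ (A / norms)
        temp = pairwise_correlations(C)
        pairs = [(i, j) for i in range(K) for j in range(i + 1, K)
                 if spat[i, j] > cfg.decorrelate_overlap
                 and temp[i, j] < cfg.merge_temporal]
        if not pairs:
            return A, C, S, C_raw, ar_models
        S2, C2 = init_mod.decorrelate_initial_spikes(S, pairs, ar_models)
        log.append({"intervention": "spike_decorrelation", "pairs": len(pairs)})
        return A, C2 if C2 is not None else C, S2, C_raw, ar_models


@dataclass
class CNMFEResults:
    """Fitted footprints, traces and background, with diagnostics.

    Attributes mirror the model decomposition: ``A`` (d x K), ``C``/``S``/
    ``C_raw`` (K x T), the ring ``background`` model (W, b0) and the frozen
    fluctuating background ``Bf`` from the last background solve.
    """

    model: CNMFE
    A: np.ndarray
    C: np.ndarray
    S: np.ndarray
    C_raw: np.ndarray
    background: bg_mod.BackgroundModel
    Bf: np.ndarray
    ar_models: list
    snr: np.ndarray
    rss_log: list
    log: list
    fov_shape: tuple
    config: FitConfig
    init_seeds: list = field(default_factory=list)

    @property
    def n_components(self) -> int:
        return self.A.shape[1]

    @property
    def b0(self) -> np.ndarray:
        return self.background.b0

    @property
    def rss(self) -> float:
        return self.rss_log[-1]["rss"] if self.rss_log else np.nan

    def reconstruct(self) -> np.ndarray:
        """Denoised movie ``A C + b0 1' + Bf``."""
        out = self.Bf + self.b0[:, None]
        if self.n_components:
            out = out + self.A @ self.C
        return out

    def residual(self) -> np.ndarray:
        return self.model.movie.data - self.reconstruct()

    def summary(self):
        """Per-component summary table (pandas DataFrame)."""
        import pandas as pd

        rows = []
        for k in range(self.n_components):
            rows.append({
                "component": k,
                "snr": self.snr[k],
                "n_pixels": int((self.A[:, k] > 0).sum()),
                "n_events": int((self.S[k] > 0).sum()),
                "peak_dff": float(self.C[k].max()),
                "ar_coefficients": np.round(self.ar_models[k].coefficients, 4).tolist(),
            })
        df = pd.DataFrame(rows)
        df.attrs["rss"] = self.rss
        return df

    def plot_contours(self, ax=None, image=None, **kwargs):
        """Footprint contours over a summary image."""
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        H, W = self.fov_shape
        if image is None:
            image = self.A.sum(axis=1).reshape(H, W) if self.n_components \
                else np.zeros((H, W))
        ax.imshow(np.asarray(image).reshape(H, W), cmap="gray")
        for k in range(self.n_components):
            img = self.A[:, k].reshape(H, W)
            if img.max() > 0:
                ax.contour(img, levels=[img.max() / 2], **kwargs)
        return ax

    def plot_traces(self, ax=None, offset=None, max_components=20):
        import matplotlib.pyplot as plt

        if ax is None:
            _, ax = plt.subplots()
        n = min(self.n_components, max_components)
        if offset is None:
            offset = 1.2 * (self.C[:n].max() if n else 1.0)
        for k in range(n):
            ax.plot(self.C_raw[k] + k * offset, color="0.7", lw=0.5)
            ax.plot(self.C[k] + k * offset, lw=1.0)
        ax.set_xlabel("frame")
        return ax

    def save(self, path: str) -> None:
        save_results(self, self.background, path, config=asdict(self.config),
                     log=self.log)
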