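import numpy as np
import pytest

from cnmfe.evaluation import match_components
from cnmfe.model import (
    CNMFE,
    FitConfig,
    compute_rss,
    detect_from_residual,
    filter_components_by_snr,
    merge_components,
)
from cnmfe.movie import Movie
from cnmfe.simulate import SimConfig, simulate_movie
from cnmfe.temporal import ARModel


class TestComputeRss:
    def test_exact_model_gives_zero(self, rng):
        d, K, T = 30, 2, 40
        A = rng.random((d, K))
        C = rng.random((K, T))
        b0 = rng.random(d).astype(np.float32)
        Bf = rng.standard_normal((d, T))
        Y = A @ C + b0[:, None] + Bf
        assert compute_rss(Y, A, C, b0, Bf) == pytest.approx(0.0, abs=1e-8)

    def test_empty_model_counts_entries(self):
        Y = np.ones((10, 7))
        rss = compute_rss(Y, None, None, np.zeros(10, dtype=np.float32),
                          np.zeros((10, 7)))
        assert rss == pytest.approx(70.0)

    def test_matches_elementwise_sum(self, rng):
        d, K, T = 25, 3, 30
        Y = rng.random((d, T))
        A = rng.random((d, K))
        C = rng.random((K, T))
        b0 = rng.random(d).astype(np.float32)
        Bf = rng.standard_normal((d, T))
        brute = sum(
            (Y[i, t] - A[i] @ C[:, t] - b0[i] - Bf[i, t]) ** 2
            for i in range(d) for t in range(T)
        )
        assert compute_rss(Y, A, C, b0, Bf) == pytest.approx(brute, rel=1e-6)


def _toy_components(rng, fov=(12, 12), T=200):
    d = fov[0] * fov[1]
    yy, xx = np.mgrid[0 : fov[0], 0 : fov[1]]
    a1 = np.exp(-((yy - 4.0) ** 2 + (xx - 4.0) ** 2) / 4.0).ravel()
    a2 = np.exp(-((yy - 8.0) ** 2 + (xx - 8.0) ** 2) / 4.0).ravel()
    c1 = np.abs(rng.random(T))
    c2 = np.abs(rng.random(T))
    return a1, a2, c1, c2


class TestMerge:
    def test_exact_duplicates_merged(self, rng):
        a1, _, c1, _ = _toy_components(rng)
        A = np.column_stack([a1, a1])
        C = np.vstack([c1, c1])
        S = np.zeros_like(C)
        ars = [ARModel(np.array([0.8]))] * 2
        A2, C2, S2, Craw2, ars2 = merge_components(A, C, S, C.copy(), ars,
                                                   0.65, 0.5)
        assert A2.shape[1] == 1
        merged = np.outer(A2[:, 0], C2[0])
        target = np.outer(a1, c1) * 2
        assert np.linalg.norm(merged - target) < 1e-6 * np.linalg.norm(target)

    def test_distant_uncorrelated_components_unchanged(self, rng):
        a1, a2, c1, c2 = _toy_components(rng)
        A = np.column_stack([a1, a2])
        C = np.vstack([c1, c2])
        ars = [ARModel(np.array([0.8]))] * 2
        A2, C2, *_ = merge_components(A, C, np.zeros_like(C), C.copy(), ars,
                                      0.65, 0.5)
        assert A2.shape[1] == 2

    def test_split_footprint_recovered_by_merge(self, rng):
        # one neuron split into two overlapping half-footprints sharing its
        # trace (real splits overlap along the dividing band)
        a1, _, c1, _ = _toy_components(rng)
        img = a1.reshape(12, 12)
        left = img.copy()
        left[:, 6:] = 0
        right = img.copy()
        right[:, :4] = 0  # columns 4-5 shared by both halves
        A = np.column_stack([left.ravel(), right.ravel()])
        C = np.vstack([c1, c1 * 1.01])
        ars = [ARModel(np.array([0.8]))] * 2
        A2, C2, *_ = merge_components(A, C, np.zeros_like(C), C.copy(), ars,
                                      0.1, 0.5)
        assert A2.shape[1] == 1
        cos = A2[:, 0] @ a1 / (np.linalg.norm(A2[:, 0]) * np.linalg.norm(a1))
        assert cos >= 0.95


class TestSnrFilter:
    def _pack(self, C, C_raw):
        K = C.shape[0]
        A = np.abs(np.random.default_rng(0).random((10, K))) + 0.1
        S = np.zeros_like(C)
        ars = [ARModel(np.array([0.8]))] * K
        return A, C, S, C_raw, ars

    def test_cutoff_thresholds_snr(self):
        c = np.array([2.0, 0.0, 0.0, 0.0])
        y = np.array([2.0, 1.0, 0.0, 0.0])
        # snr = 4 / 1 = 4
        A, C, S, Craw, ars = self._pack(c[None], y[None])
        kept3 = filter_components_by_snr(A, C, S, Craw, ars, cutoff=3.0)
        kept5 = filter_components_by_snr(A, C, S, Craw, ars, cutoff=5.0)
        assert kept3[0].shape[1] == 1
        assert kept5[0].shape[1] == 0

    def test_zero_trace_always_removed(self):
        C = np.zeros((1, 4))
        y = np.ones((1, 4))
        A, C, S, Craw, ars = self._pack(C, y)
        out = filter_components_by_snr(A, C, S, Craw, ars, cutoff=0.1)
        assert out[0].shape[1] == 0

    def test_perfect_fit_always_kept(self):
        c = np.array([[1.0, 2.0, 1.0]])
        A, C, S, Craw, ars = self._pack(c, c.copy())
        out = filter_components_by_snr(A, C, S, Craw, ars, cutoff=1e9)
        assert out[0].shape[1] == 1
        assert np.isinf(out[5][0])


class TestResidualPickup:
    def test_planted_neuron_recovered_from_residual(self):
        cfg = SimConfig(fov_shape=(48, 48), n_frames=600, n_neurons=1,
                        n_bg_sources=0, vessel=False, seed=13)
        movie, truth = simulate_movie(cfg)
        d, T = movie.data.shape
        fc = FitConfig(neuron_diameter=12, min_corr=0.8, min_pnr=10)
        new = detect_from_residual(
            movie.data, movie.fov_shape, np.zeros((d, 0)), np.zeros((0, T)),
            np.zeros(d, dtype=np.float32), np.zeros((d, T), dtype=np.float32), fc)
        rep = match_components(new.A, new.C_raw, truth.A, truth.C, min_sim=0.5)
        assert rep.n_matched == 1
        assert rep.spatial_cosine[0] >= 0.9

    def test_clean_residual_yields_nothing(self, rng):
        d, T = 48 * 48, 400
        noise = (0.05 * rng.standard_normal((d, T))).astype(np.float32)
        fc = FitConfig(neuron_diameter=12, min_corr=0.8, min_pnr=10)
        new = detect_from_residual(
            noise - noise.min(), (48, 48), np.zeros((d, 0)), np.zeros((0, T)),
            np.zeros(d, dtype=np.float32), np.zeros((d, T), dtype=np.float32), fc)
        assert new.n_components == 0


@pytest.fixture(scope="module")
def fitted(small_scene):
    movie, truth = small_scene
    res = CNMFE(movie, neuron_diameter=12, min_corr=0.9, min_pnr=15).fit()
    return res, truth


class TestFit:
    def test_all_neurons_recovered(self, fitted):
        res, truth = fitted
        rep = match_components(res.A, res.C, truth.A, truth.C, min_sim=0.5)
        assert rep.n_matched == truth.A.shape[1]
        assert np.median(rep.spatial_cosine) >= 0.9
        assert np.median(rep.temporal_cosine) >= 0.9

    def test_rss_monotone_across_matrix_stages(self, fitted):
        res, _ = fitted
        log = res.rss_log
        for prev, cur in zip(log, log[1:]):
            if prev["K"] != cur["K"]:
                continue
            if (prev["stage"], cur["stage"]) in (
                ("background", "spatial"), ("spatial", "temporal")):
                assert cur["rss"] <= prev["rss"] * (1 + 1e-6)

    def test_summary_table_well_formed(self, fitted):
        res, _ = fitted
        df = res.summary()
        assert len(df) == res.n_components
        assert {"component", "snr", "n_pixels", "n_events"} <= set(df.columns)

    def test_background_dominates_variance(self, fitted):
        # hallmark of the recording modality: most variance is background
        res, _ = fitted
        movie = res.model.movie
        raw_var = movie.data.var(axis=1).sum()
        neural = (res.A @ res.C).astype(np.float32)
        resid_var = (movie.data - res.Bf - res.b0[:, None] - neural).var(axis=1).sum()
        bg_var = (res.Bf + res.b0[:, None]).var(axis=1).sum()
        assert bg_var > 0.5 * raw_var
        assert resid_var < 0.3 * raw_var

    def test_no_all_zero_components(self, fitted):
        res, _ = fitted
        assert np.all(np.linalg.norm(res.A, axis=0) > 0)
        assert np.all([np.any(res.C[k] > 0) for k in range(res.n_components)])

    def test_correlation_structure_recovered(self, fitted):
        # estimated trace correlations closer to truth than raw pixel ROIs
        from cnmfe.evaluation import pairwise_correlations

        res, truth = fitted
        rep = match_components(res.A, res.C, truth.A, truth.C, min_sim=0.5)
        est_idx = [i for i, _ in rep.pairs]
        tru_idx = [j for _, j in rep.pairs]
        M_true = pairwise_correlations(truth.C[tru_idx])
        M_est = pairwise_correlations(res.C[est_idx])
        movie = res.model.movie
        H, W = res.fov_shape
        roi = []
        for j in tru_idx:
            cy, cx = np.clip(np.round(truth.centers[j]).astype(int), 0, [H-1, W-1])
            roi.append(movie.data[cy * W + cx])
        M_roi = pairwise_correlations(np.array(roi))
        assert np.linalg.norm(M_est - M_true) < np.linalg.norm(M_roi - M_true)
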