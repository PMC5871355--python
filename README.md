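# cnmfe

Constrained nonnegative matrix factorization with a ring-structured
background model (CNMF-E) for extracting single-neuron calcium signals
from one-photon microendoscopic movies.

## The problem

Miniature microscopes with implanted GRIN lenses record calcium activity
deep in the brain of freely moving animals. The price is a huge, blurry,
fast-fluctuating background from out-of-focus fluorescence, neuropil and
vessels: it typically carries ~90% of the signal variance and fluctuates
on the same timescales as the neurons. ROI averaging and PCA/ICA leave
that background inside the extracted traces; low-rank background models
under-fit it. This package is for experimentalists and analysts who need
demixed, denoised, deconvolved single-neuron signals from such recordings.

## The model

A movie `Y ∈ R₊^{d×T}` (d pixels, T frames) is decomposed as

    Y = A C + b0·1ᵀ + Bf + E

with nonnegative, spatially localized footprints `A ∈ R₊^{d×K}`,
nonnegative calcium traces `C ∈ R₊^{K×T}` constrained by a stable AR(p)
model `s_i = G⁽ⁱ⁾ c_i ≥ 0` (sparse spikes `s_i`), a constant per-pixel
baseline `b0`, white noise `E`, and a fluctuating background constrained
by the ring model

    Bf = W (Y − A C − b0·1ᵀ),   W_ij = 0 unless dist(x_i, x_j) ∈ [ln, ln+1).

Each pixel's background is predicted from an annulus wider than a soma:
spatially coarse structure is captured with one small regression per
pixel, and a neuron can never be absorbed because its own soma is outside
its ring. Fitting minimizes `‖Y − AC − b0·1ᵀ − Bf‖²_F` by alternating
footprint updates (support-constrained HALS), trace updates (per-neuron
projection + OASIS-style constrained deconvolution), and background
regression with robust clipping, after a greedy seed-pixel initialization
driven by the correlation × peak-to-noise-ratio image of the spatially
filtered movie. See `docs/methods.md` for the full account.

## Worked example

```python
import numpy as np
from cnmfe import CNMFE, match_components
from cnmfe.simulate import SimConfig, simulate_movie

cfg = SimConfig(fov_shape=(64, 64), n_frames=1000, n_neurons=10,
                n_bg_sources=5, vessel=True, seed=3)
movie, truth = simulate_movie(cfg)

model = CNMFE(movie, neuron_diameter=12, min_corr=0.9, min_pnr=15)
res = model.fit()
print(f"components found: {res.n_components}")
print(res.summary().to_string(index=False))

report = match_components(res.A, res.C, truth.A, truth.C, min_sim=0.5)
print(f"matched to ground truth: {report.n_matched}/{truth.A.shape[1]}")
print("median spatial cosine: %.3f" % np.median(report.spatial_cosine))
print("median temporal cosine: %.3f" % np.median(report.temporal_cosine))
```

prints

```
components found: 15
 component       snr  n_pixels  n_events  peak_dff   ar_coefficients
         0 80.191796       309        34  4.950918 [1.0451, -0.1677]
         1 61.350657       254        18  5.652104 [1.2001, -0.3179]
         2 56.903113       255        24  4.532178  [1.0263, -0.156]
         3 51.757768       205        15  3.914996 [1.1827, -0.3089]
         4 50.670596       256        23  4.664125  [1.261, -0.3748]
         5 40.868635       511       222  2.261516       [0.95, 0.0]
         6 38.442682       635        22  4.895712 [0.9415, -0.0617]
         7 36.300705       565        23  4.960594 [1.1844, -0.2967]
         8 31.154859       718       209  2.133746       [0.95, 0.0]
         9 26.721825       402       153  2.438401       [0.95, 0.0]
        10 25.630749       545        20  5.177245 [1.1987, -0.3049]
        11 19.957863       647        61  4.178959  [0.9652, -0.048]
        12 14.641256       375       130  2.207180       [0.95, 0.0]
        13 13.809066       359        11  4.458655 [1.0886, -0.2183]
        14 12.328876       232       109  1.988158       [0.95, 0.0]
matched to ground truth: 10/10
median spatial cosine: 0.996
median temporal cosine: 0.995
```

All ten planted neurons are recovered essentially exactly (cosine
similarity ≈ 1 in space and time). The per-component table reads as
follows: `snr` is `‖c‖²/‖ŷ−c‖²` of the denoised trace against the raw
projected trace; `n_events` counts deconvolved spikes; `ar_coefficients`
are the fitted calcium dynamics — the 10 real neurons show the
double-exponential AR(2) signature (γ ≈ [1.2, −0.3]), while the five
extra components (a typical by-product of automated-only operation) track
residual background: hundreds of "events", low peak amplitude, and a
decay-only kernel clipped at the stability bound. They can be pruned by a
stricter `snr_cutoff` or by inspection of exactly these columns.

`res` also exposes `plot_contours()`, `plot_traces()`, `reconstruct()`,
`residual()` and `save(path)` (HDF5). The same pipeline is scriptable
from the shell:

```bash
cnmfe simulate --preset population --scale 0.25 --seed 1 --output movie.h5
cnmfe fit --input movie.h5 --output fit.h5 --neuron-diameter 12 \
          --min-corr 0.9 --min-pnr 15
cnmfe evaluate --truth movie_truth.h5 --fit fit.h5
```

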