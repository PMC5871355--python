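# Methods

## Model

A motion-corrected one-photon (microendoscopic) movie is stored as a
nonnegative pixels-by-frames matrix `Y ∈ R_+^{d×T}` (frames flattened
row-major). The generative model is

    Y = A C + b0 · 1ᵀ + Bf + E

* `A ∈ R_+^{d×K}` — spatial footprints, one nonnegative, spatially
  localized column per neuron;
* `C ∈ R_+^{K×T}` — calcium traces, each an AR(p) process driven by a
  nonnegative, sparse spike signal `s = G c` (G the banded difference
  operator built from the AR coefficients γ₁…γ_p);
* `b0 ∈ R_+^d` — per-pixel constant baseline;
* `Bf` — fluctuating background, constrained by the *ring model*: each
  pixel's background is a linear combination of the pixels on an annulus
  at distance `[ln, ln+1)` around it, `Bf = W (Y − A C − b0·1ᵀ)` with
  `W_ij = 0` off the annulus. The ring radius `ln` is larger than a soma
  (default `2l`), so the ring shares the spatially coarse background but
  never the pixel's own neuron;
* `E` — white Gaussian noise with per-pixel standard deviation σ_i.

The fit minimises the residual sum of squares
`‖Y − A C − b0·1ᵀ − Bf‖_F²` under these constraints, split into the
classic three subproblems (footprints, traces, background) that are
solved in alternation.

Why a ring model: in this recording modality the background (out-of-focus
fluorescence, neuropil, vessels, slow global drifts) carries most of the
variance and is spatially much coarser than a soma. A low-rank model
under-fits it badly; predicting each pixel from its annulus exploits the
coarseness directly, costs one small regression per pixel, and cannot
absorb a soma because the annulus excludes it by construction.

## Summary images and initialization

Noise is estimated per pixel from the mean Welch power spectral density
over `[0.25, 0.5]` cycles/frame (slow calcium and background dynamics are
excluded from the band); `σ = sqrt(mean PSD / 2)` equals the noise standard
deviation for white noise. The movie is correlated frame-by-frame (reflect
padding) with a mean-centred Gaussian of width `l/4` on an odd window of
about `l` pixels — a cell-body template whose zero sum suppresses the
coarse background. On the filtered movie `Z` two images are computed:

* `L(x)` — mean Pearson correlation of the pixel's filtered trace
  (clipped below `3σ(x)` to zero) with its 4 nearest neighbours, border
  pixels averaging the neighbours that exist;
* `P(x) = max_t Z(x,t) / σ(x)` — peak-to-noise ratio.

σ here is estimated on the filtered movie: both images compare filtered
signal against filtered noise. A second noise map on the raw movie feeds
the background module's outlier clipping.

Seed pixels are local maxima of `R = P·L` within an `(l/4)²` window that
pass both thresholds (`Lmin`, `Pmin`), processed in descending `R` with
row-major tie-breaking. Each seed initializes one neuron from a
`(2l+1)²` box: pixels whose filtered traces correlate with the seed above
0.7 provide the trace (their mean filtered trace), pixels below 0.3
provide a local background trace (median of their raw traces — the median
is robust to stray neurons in the annulus of the box), and the footprint
is the nonnegative part of the per-pixel regression of the raw box onto
`[trace, local background, constant]`. Seeds whose footprint has fewer
than 5 pixels above half its peak are rejected. The accepted neuron's
rank-1 activity is peeled from the working movie and from its filtered
version (the same linear operator is applied to the footprint), and `L`,
`P` are recomputed inside the affected window only.

After the first background estimate every trace is re-read from the
background-subtracted movie through its thresholded footprint (pixels at
least half the peak). Components whose thresholded footprints overlap are
solved as one least-squares system; for disjoint footprints this reduces
to the per-neuron weighted average, and for overlapping ones it removes
crosstalk that the per-neuron form amplifies downstream (footprint
updates magnify correlated trace errors by `1/(1−ρ²)` at trace
correlation ρ).

## Background estimation

Given current `A, C`: `b0` is the per-pixel temporal mean of `Y − A C`;
`X = Y − A C − b0·1ᵀ` is clipped at `B⁻ + ζ σ` (entries exceeding the
current background estimate by ζ noise standard deviations are replaced
by the estimate — this deletes unmodelled calcium transients), the ring
weights are refit on the clipped data, and the clip/fit cycle runs
`n_robust_iters = 2` times. The first cycle clips against the plain ring
average.

The per-pixel regression is a ridge shrinkage toward the uniform
ring-average weights: `min_w ‖X_i − wᵀX_ring‖² + λ_i ‖w − u‖²` with
`λ_i = ridge · T · mean(σ_ring²)`. The annulus has ~100 free weights per
pixel against a few hundred frames, so unpenalised least squares absorbs
observation noise; shrinking toward the ring average (itself an excellent
predictor of a spatially coarse field) suppresses exactly that. The
penalty vanishes for noiseless data, where the fit reduces to least
squares. Two defaults are exposed deliberately: `ridge = 10` when the
background estimate itself is the target (standalone use, neural signal
left in the data), and `ridge = 0.3` inside the pipeline, where `A C` has
been subtracted and the cleanest possible *neural residual* matters more
than parsimony of the background weights.

## Trace updates and deconvolution

Traces are updated by block coordinate descent: for each neuron the
current residual is projected onto its footprint,
`ŷ = c_prev + aᵀ Y_res / (aᵀa)`, and the unconstrained estimate is
denoised by constrained deconvolution. `b0` is refreshed in closed form
after every spatial and temporal pass (it is the unconstrained minimiser).

AR coefficients are estimated per neuron by an overdetermined Yule-Walker
regression: the AR recursion must hold for the autocovariance at every
positive lag, so `acov(k+1)` is regressed on `[acov(k), …, acov(k−p+1)]`
for `k = 1…7`, with the lag-0 term noise-corrected (`acov(0) − σ²`). Only
one equation touches lag 0, which makes the fit robust both to the noise
correction and to the near-singular plain p×p system. A fit is accepted
only if its characteristic roots are real, nonnegative and at most 0.95
(a decaying, non-oscillating calcium kernel); otherwise the model falls
back to an AR(1) whose decay rate is the median tail autocovariance ratio
— insensitive to white noise and stable under slow contamination. Traces
indistinguishable from white noise (lag-1 autocorrelation below 0.25) get
zero dynamics.

Deconvolution solves `min ‖ŷ − c − b‖²` s.t. `s = G c ≥ 0` plus sparsity:

* **AR(1)** — an exact online active-set (pool-adjacent-violators)
  solver. The L1 penalty is absorbed into the data
  (`Σs = Σ μ_t c_t`, so `ỹ = y − λμ`), pools are merged while the decay
  constraint is violated, and pool values are clamped at zero. The
  minimum-spike variant (`s_min`) greedily merges pools whose onset jump
  is positive but undersized, smallest first, re-establishing the
  violation-free structure after each merge. On random small instances
  the solver matches a brute-force QP oracle (an exact NNLS reduction) to
  10⁻⁶ in objective.
* **AR(p ≥ 2)** — projected gradient (FISTA) on the spike vector with the
  AR impulse-response kernel, followed by support consolidation: the L1
  solution smears each spike over neighbouring bins, so support is
  gathered at `0.25·s_min`, amplitudes are refit by nonnegative least
  squares on that support, and the spike threshold is applied to the
  *refit* amplitudes.

The block-coordinate update carries a monotone guard: the thresholded
deconvolution is not an exact projection, so a neuron's new trace is
accepted only if it does not increase that neuron's mean-adjusted
residual — this makes the recorded objective non-increasing through the
temporal stage by construction.

The default sparsity mode is the hard minimum-spike threshold with the
matched-filter calibration `s_min = 3 σ / ‖h‖₂` (a spike of amplitude `s`
yields detection statistic `s‖h‖/σ`, so this keeps every spike detectable
at 3σ); an L1 mode with `λ = σ‖h‖` is available. A free scalar baseline
is estimated by alternation (deconvolve, then `b ← mean(y − c)`), started
from the 10th percentile of the trace.

## Footprint updates

Support-constrained HALS: each footprint may only occupy a disk-dilated
version (radius 2) of its previous support; sweeps update components in
descending trace energy with the closed-form nonnegative coordinate
update, leaving the objective non-increasing. Sparsity of `A` is realized
structurally (supports + nonnegativity + morphological cleanup) rather
than through a penalty weight. Cleanup binarises each footprint,
applies a morphological opening (disk radius 1, edge-padded so border
neurons survive), and keeps only the largest 8-connected component.

## Interventions and the outer loop

Per outer iteration: spatial update, temporal update, then interventions
— footprint cleanup, residual pickup (first iteration only), automated
merging (groups exceeding *both* a footprint cosine of 0.65 and a trace
correlation of 0.5 are replaced by the rank-1 factorisation of their
summed activity, AR refit on the merged trace), an SNR filter
(`‖c‖²/‖ŷ−c‖² ≥ 0.2`; the cutoff is permissive on purpose — it removes
components with essentially no denoisable signal while letting weak real
neurons in low-SNR data survive) — and finally a background refresh. The
loop stops when the component count is stable (at least 2, at most 5
iterations).

Residual pickup reruns the greedy initializer on
`Y − A C − b0·1ᵀ − Bf` with thresholds at `0.75·Lmin` and `0.4·Pmin`:
once the background is gone, a genuinely missed neuron (e.g. the weaker
member of a highly correlated pair) retains only a fraction of its
original peak-to-noise ratio. The residual's own PSD under-estimates the
noise floor (the ring regression absorbs part of the noise), so residual
peak-to-noise ratios are computed against the noise map of the filtered
*raw* movie.

The RSS is recorded after every stage with `b0` at its closed-form
optimum and `Bf` frozen from the most recent background solve; across
any background → spatial → temporal stage sequence at fixed K the
recorded RSS is non-increasing. Footprint cleanup runs in the
interventions block (once per iteration) so the monotonicity statement
refers to pure matrix-update stages.

## Synthetic data

The generator emulates the standard benchmark conditions for this
modality: spherical 2-D Gaussian somata (per-axis widths drawn from
`N(l/4, (l/40)²)`, unit peak, truncated at 10⁻³), Bernoulli(0.01) spike
trains convolved with `g(t) = exp(−t/τ_d) − exp(−t/τ_r)` (τ_d = 6,
τ_r = 1 timebins), background sources that are 5× wider Gaussians with
variance-normalised random-walk time courses, an optional blood-vessel
artifact (a cubic curve rasterised and blurred with a width-3 Gaussian),
a constant baseline, and white Gaussian noise whose standard deviation is
multiplied by an SNR-reduction factor.

Amplitude conventions (all tunable): the homogeneous noise floor is set
so a single-spike transient at a footprint peak is ≈ 10σ at factor 1;
the fluctuating background is scaled so its total variance is 10× the
total neural variance (background dominates, as in real recordings). The
two-neuron preset places the pair at centre distance `l/2` (half-max
contours just overlapping), mixes their traces with a shared component
tuned numerically to the requested correlation, adds that shared trace to
the background as well, and scales the background against a *reference
neural density* (the dense population's) rather than the 2-neuron scene.

What the generator does **not** capture: background extracted from real
recordings (spatially structured beyond sums of Gaussians), inhomogeneous
noise maps, motion residuals, photobleaching trends, and non-Gaussian
noise. Tests passing on these simulations therefore validate the
estimator's mechanics — background separation, seeding, demixing,
deconvolution — under known ground truth, not its end-to-end behaviour on
arbitrary real data.

## Numerical choices

* Filter window: nearest odd size to `l`, so an exact centre pixel exists
  and `h(centre) = 1`.
* Boundary rules: reflect padding for filtering; ring annuli and supports
  clipped at the field of view; decimation averages trailing partial
  blocks over their actual extent.
* Ties: seed candidates with equal ranking break row-major; HALS sweeps
  order by descending trace energy, index-stable.
* Degenerate inputs: all-constant traces give σ = 0 and zero PNR; zero
  footprints/traces flag the component for deletion; empty rings give
  zero background rows; K = 0 models are valid everywhere.
* Determinism: a fixed configuration and seed reproduce the fit exactly;
  the only randomised routine (the rank-1 NMF comparison baseline) is
  seeded.

## Problem sizes in the test suite

The validation suite regenerates the benchmark regimes at sizes chosen
for a single-CPU laptop-class budget: background recovery at 128×128×500
(plus a 48×48×400 sweep over source counts against the rank-1 NMF
baseline), initialization at 128×128×1000 with 50 neurons, the noise
sweep at 64×64×1000 with 12 neurons, the correlated-pair sweep at
64×64×1000, and stage-monotonicity checks on a 0.2-scaled population
scene. The full-scale 253×316×2000 / 200-neuron initialization benchmark
runs in the reproduction script (`scripts/acceptance.py`), at about
3.3 GB peak memory.

## Known limitations

* **Highly correlated overlapping pairs.** Footprint estimation error
  amplifies trace impurity by `1/(1−ρ²)`. At trace correlation 0.95 a
  footprint cosine of 0.9 demands trace purity beyond what this noise
  level supports (the irreducible error is crosstalk in genuinely shared
  spike amplitudes), so the weaker member's footprint saturates around
  0.75–0.85 while both traces stay above 0.95. With exact traces the
  footprints reach 0.98, and with exact footprints the traces reach
  0.99 — the joint problem, not either half, is the bottleneck.
* Single-block processing only: no patch tiling, no multi-session mode,
  no parallelism; memory is ~5 movie-sized arrays at peak.
* Automated interventions only; no manual merge/split GUI. Splitting
  mistakenly fused components is not automated.
* The AR model assumes a global, stationary kernel per neuron; adaptive
  or non-AR response kernels are out of scope.
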