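# Methods

## Problem and model

Given a noisy grayscale image `y` and a clean reference `r` (both real-valued
on [0, 255]), the package searches for the parameter vector `x` of a fixed
five-stage filter chain `D_x` that minimizes

    f(x) = lambda * (1 - SSIM(r, D_x(y))) + (1 - lambda) * MSE(r, D_x(y)) / 255^2

with `lambda = 0.5` by default. Both terms are dimensionless and bounded on
ordinary inputs, which keeps the scalarization balanced; MSE/255^2 is used as
the fidelity term rather than PSNR because PSNR's dB scale is unbounded as
MSE approaches 0. `f` is zero only for a perfect reconstruction. Tuning
requires the clean reference; blind denoising is out of scope.

### Search space (8 dimensions, fixed order)

| dim | parameter          | bounds    | decoding                      |
|-----|--------------------|-----------|-------------------------------|
| 0   | gaussian_sigma     | [0.3, 3]  | pass-through (pixels)         |
| 1   | gaussian_ksize     | [0, 1]    | 3 equal bins -> {3, 5, 7}     |
| 2   | median_ksize       | [0, 1]    | 3 equal bins -> {3, 5, 7}     |
| 3   | mean_ksize         | [0, 1]    | 3 equal bins -> {3, 5, 7}     |
| 4   | bilateral_sigma_r  | [5, 75]   | pass-through (intensity)      |
| 5   | bilateral_sigma_d  | [0.5, 5]  | pass-through (pixels)         |
| 6   | bilateral_ksize    | [0, 1]    | 3 equal bins -> {3, 5, 7}     |
| 7   | sharpen_amount     | [0, 2]    | pass-through (blend weight)   |

Window sizes are restricted to odd edges {3, 5, 7}: odd windows are required
by the median/mean definitions and this range keeps the search box compact
while covering the useful smoothing scales at 128-256 px image sizes.

## Filter chain

The order Gaussian -> median -> mean -> bilateral -> sharpening is fixed and
not searched. Implementation notes:

- The Gaussian kernel is the standard normalized discrete form
  `w(x, y) ∝ exp(-(x² + y²)/(2σ²))`, renormalized over the window so constant
  images are exact fixed points.
- The bilateral weight is the product of a spatial Gaussian (sigma_d, pixel
  offsets) and a range Gaussian (sigma_r, intensity differences); the center
  weight is exactly 1, so the normalizing denominator never vanishes.
- Sharpening convolves with the classic kernel [[0,-1,0],[-1,5,-1],[0,-1,0]]
  (sums to 1) and blends: `out = (1-a)·img + a·(img ⊛ K)`, `a ∈ [0, 2]`;
  `a = 0` is the identity, `a = 1` plain convolution. Exposing a blend weight
  gives the optimizer a continuous handle on sharpening strength.
- Border handling is reflective everywhere (scipy `mode='reflect'`, edge
  pixel repeated). This avoids border darkening that would corrupt the
  boundary-ROI EPI. One consequence: on a linear ramp the outermost row and
  column keep a small median bias (the reflected window duplicates the edge
  value), so "near identity" statements hold on the interior.
- Every stage clips to [0, 255] on exit. Metrics are always computed on the
  pre-quantization real-valued image; quantization (round half away from
  zero to uint8) happens only when writing PNG/TIFF, and the run manifest
  records this.

## Tent chaos

At `mu = 2` the tent map is the dyadic bit-shift map: in binary floating
point every orbit reaches 0 within about 53 steps, and 0, 1/2, 1 are
absorbing. To keep the published `mu = 2` while producing non-degenerate
sequences, any iterate within `collapse_epsilon = 1e-12` of {0, 1/2, 1} is
nudged toward the interior by `collapse_epsilon * (1 + u)`, `u` a fresh
uniform draw from the run RNG. Nudge events are countable by callers
(`tent_sequence(..., with_events=True)`), and float iterates are bit-exact
against rational arithmetic up to the first event (doubling and the
reflection `2(1-x)` are both exact float operations). The tent seed `x0` is
drawn once per run from the seeded RNG unless supplied, and recorded in the
run manifest. One global sequence is consumed row-major across
(individual, dimension); per-dimension sequences would work as well, but a
single stream makes the affine-recovery invariant trivial to verify.

## Optimizer

Published constants: population N = 20, iterations T = 50, movement draws
m ~ U[0.4, 0.9] and beta ~ U[-1, 1] (fresh per individual per iteration),
pheromone threshold 0.3. Pheromones start at 1, are incremented (decremented)
by `f_old_i / sum_j f_old_j` on improvement (worsening), clipped to [0, 1],
and reset to 1 on replacement. Replacement uses three distinct random peers
`x_r1 + sigma (x_r2 - x_r3)` with `sigma ~ Bernoulli(1/2)`. Ties for the best
individual break toward the lowest index. All positions are clipped to the
box after every update, and the best-so-far record is kept outside the
population, which makes the reported history non-increasing by construction.
A non-finite fitness aborts the run with a diagnostic.

Two deliberately exposed interpretation knobs:

- `movement_sign`: `as_printed` (default) keeps the published leading minus
  in the movement update, which is repulsive from the best position for
  m > 0; `attractive` flips it into the conventional attraction step. Both
  modes pass the package's recovery benchmarks; the manifest records the
  mode used.
- The Gaussian + tent perturbation of the best position treats the tent map
  as the *range guard* of the step: the jittered coordinate is normalized to
  `u = (y - lo)/(hi - lo)` and folded into [0, 1] by the tent reflection
  (identity on [0, 1], `2 - u` on (1, 2], periodic beyond). In-range jitter
  therefore stays local to the best position — which is what makes late-stage
  refinement possible — while out-of-range jitter re-enters the box by
  reflection instead of saturating at a face. The fold is exactly the
  full-height tent map applied on the doubled domain. An unconditional tent
  remap of in-range coordinates was evaluated and rejected: it destroys the
  locality of the perturbation, and the optimizer then fails to beat an
  equal-budget random search on the 2-D quadratic benchmark.

The perturbation candidate supplements (not replaces) the movement step each
iteration and is accepted per individual only on improvement. Its scale is
0.1 of the per-dimension span by default — large enough to escape shallow
basins early, small enough to refine once the normalized best is interior.

Evaluation budget: N initial + 2N per iteration (move + perturbation) plus
one per replacement; about 2,020 evaluations at N = 20, T = 50 in d = 2.
The benchmarks compare against uniform random search at exactly the realized
budget.

## Metrics

- MSE, PSNR: standard; PSNR uses n = 8 bits, returns +inf (or a configured
  cap) at MSE = 0, and is strictly decreasing in MSE.
- SSIM is computed from *global* image statistics (means, variances,
  covariance of the whole image) — the single-window form of the index, not
  the sliding-window variant common in libraries. The two differ on real
  images; comparisons across packages must use the same form.
- ENL: mean over ROIs of `mu² / (sigma² + 1e-12)` with population variance.
  The epsilon lets constant ROIs (legitimate for synthetic phantoms) return
  a large finite "saturated" value instead of failing. ENL is invariant to
  intensity scaling. Default ROIs: three 32x32 squares at relative positions
  (1/4, 1/4), (1/4, 3/4), (3/4, 1/2), clamped into the image.
- EPI: sum of |I(x+1, y) - I(x-1, y)| (horizontal central difference, x the
  column index) over boundary ROIs, noisy over denoised. The orientation is
  kept as defined even though it means stronger smoothing yields values
  above 1; no inversion is applied, and the direction is documented wherever
  the value is reported. Only the horizontal difference enters. Default
  ROIs: four 16-pixel frames along the borders, inset by 1 px so the central
  difference is defined; a zero denominator raises a degenerate-input error.

## Synthetic data

Phantoms (`make_phantom`) are 8-bit-range, deterministic under seed, and all
contain at least one large homogeneous region and one strong step edge:

- `piecewise_constant`: flat background (60) with two flat rectangles
  (180, 120) — the main end-to-end benchmark image;
- `gradient`: rows strictly increasing (40 to 200 across the width) with an
  additive +50 step at 3/4 width;
- `edges`: concentric flat frames (tones 50/200/90/160);
- `blobs`: smooth random Gaussian blobs on a flat background whose top-left
  third is kept blob-free (a perfectly constant patch that saturates ENL),
  plus one hard step edge.

Noise models: additive Gaussian (sigma 25 by default, the benchmark
condition), salt-and-pepper (total density 0.05, symmetric 50/50 salt and
pepper — the split is a package choice), Poisson modeled on the intensity
scale with a photons-per-intensity-unit parameter (default 1.0), and speckle
as multiplicative Gaussian `img * (1 + N(0, var))` with var = 0.04 (the
standard multiplicative model for bright/dark speckle). All noise is clipped
to [0, 255], which slightly reduces the effective sigma of Gaussian noise
near the range ends.

What the phantoms do not emulate: anatomical texture, partial-volume
effects, scanner-specific noise correlation, or the intensity statistics of
real lung CT. Passing benchmarks on phantoms therefore demonstrates the
machinery (optimizer convergence, chain behavior per noise type, metric
correctness), not clinical performance; absolute metric values on real CT
data would differ.

## Ablation

Variants follow the published three-arm design, with the flag reading
adopted here: BWOA = tent initialization + sharpening; BWOA1.0 = neither;
BWOA2.0 = tent without sharpening. The two flags are independent in
`BWOAConfig`, so other readings are configurable. Within a seed all variants
consume a byte-identical noisy image (verified by a SHA-256 fingerprint in
each ablation row), making the design paired; the CSV reports
MSE/PSNR/SSIM/ENL/EPI per variant per seed. No ordering among variants is
asserted by the test suite — on synthetic phantoms the directional effects
are dataset-dependent.

## Problem sizes and numerical choices

End-to-end benchmark runs use 128 x 128 phantoms with N = 20 and a shortened
schedule of T = 8 iterations: the 8-D chain box is small enough that the
optimizer's gains plateau well before T = 50 (the default config retains the
published T = 50). The quadratic-recovery study uses the full N = 20,
T = 50 setting. Tolerances: filter implementations match brute-force oracles
to 1e-9 (median exactly); metric implementations match moment/summation
oracles to 1e-12 relative; tent sequences are compared to rational
arithmetic at 1e-9. Degenerate inputs are first-class: constant images are
fixed points of every stage, constant ROIs saturate ENL, a zero EPI
denominator raises, degenerate bounds and even window sizes are rejected at
construction.

## Known limitations

- Requires a clean reference; no blind or no-reference mode.
- Global-statistics SSIM can be insensitive to localized structural damage.
- The EPI orientation (noisy/denoised) rewards gradient retention only by
  proximity to 1; consumers comparing to conventions that invert the ratio
  must flip it.
- Grayscale 2-D only; no DICOM/NIfTI readers; no GPU or FFT acceleration.
- The optimizer is heuristic: no convergence guarantees are claimed beyond
  the benchmarked behavior.
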