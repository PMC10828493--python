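# chaoswidow

Tent-chaos-enhanced Black Widow optimization of a five-stage filter chain
for denoising 8-bit grayscale medical-style images.

Medical images (CT, ultrasound, PET) are corrupted by characteristic noise —
additive Gaussian, salt-and-pepper impulses, Poisson photon noise,
multiplicative speckle — and classical filters each handle only some of it.
This package tunes a fixed chain of five classical filters

    Gaussian -> median -> mean -> bilateral -> sharpening

so that the chain as a whole adapts to whatever noise is present. The tuner
is the Black Widow Optimization Algorithm (BWOA), a population metaheuristic,
improved with a tent chaotic map: initial positions come from the tent map

    x_{k+1} = mu x_k            (x_k <= 1/2)
    x_{k+1} = mu (1 - x_k)      (x_k >  1/2),     mu = 2,

mapped affinely into the search box. Each of the N = 20 widows encodes one
8-dimensional chain parameter vector (sigmas, window sizes in {3,5,7},
sharpening amount); per iteration, individuals move relative to the current
best position with random coefficients m in [0.4, 0.9] and beta in [-1, 1],
a Gaussian + tent-map perturbation of the best is accepted on improvement,
a per-individual pheromone in [0, 1] tracks relative quality, and widows
whose pheromone drops to <= 0.3 are replaced by a random recombination of
three peers. The fitness minimized for a noisy image y against a clean
reference r is

    f(x) = lambda (1 - SSIM(r, D_x(y))) + (1 - lambda) MSE(r, D_x(y)) / 255^2

where D_x is the chain decoded from position x and lambda = 0.5.

Results are scored with five standard metrics: MSE, PSNR (n = 8 bits), the
global-statistics SSIM (k1 = 0.01, k2 = 0.03, L = 255), ENL
(mean over three ROIs of mu^2/sigma^2, smoothness of homogeneous regions)
and EPI (ratio of absolute horizontal gradient sums, noisy over denoised,
on boundary ROIs). Synthetic phantoms plus seeded noise generators make
every experiment self-contained and reproducible.

## Worked example

```python
from chaoswidow import (BWOAConfig, FitnessSpec, NoiseSpec, PhantomSpec,
                        add_noise, apply_chain, make_phantom,
                        optimize_denoise, psnr, ssim)

ref = make_phantom(PhantomSpec(kind="piecewise_constant", size=128))
noisy = add_noise(ref, NoiseSpec(kind="gaussian", gaussian_sigma=25.0, seed=7))

cfg = BWOAConfig(population_size=20, max_iterations=8, rng_seed=7)
result, params = optimize_denoise(FitnessSpec(reference=ref, noisy=noisy), cfg)
denoised = apply_chain(noisy, params, use_sharpen=cfg.use_sharpen)

print(f"{psnr(ref, noisy):.2f} -> {psnr(ref, denoised):.2f} dB,",
      f"SSIM {ssim(ref, denoised):.4f}")
```

prints

```
20.26 -> 32.54 dB, SSIM 0.9902
```

i.e. the optimized chain removed roughly 94% of the noise energy
(a 12.3 dB PSNR gain) while keeping the phantom's structure (SSIM near 1).
The scripts in `examples/` walk through each capability: chaotic
initialization, the filter chain, the metrics, quadratic parameter
recovery, end-to-end denoising, and the BWOA / BWOA1.0 / BWOA2.0 ablation.

## Command line

```sh
chaoswidow phantom --kind piecewise_constant --size 128 --seed 1 -o ref.png
chaoswidow add-noise ref.png --kind gaussian --sigma 25 --seed 3 -o noisy.png
chaoswidow denoise noisy.png --ref ref.png --seed 7 -o out.png \
    --report report.json --history history.csv --manifest manifest.json
chaoswidow evaluate --ref ref.png --noisy noisy.png --denoised out.png
chaoswidow ablate --ref ref.png --kind salt_pepper --seeds 3 -o ablation.csv
```

All randomness flows from `--seed`; repeating an invocation reproduces its
outputs byte for byte.

## Layout

- `src/chaoswidow/chaos.py` — tent map, chaotic sequences, initialization
- `src/chaoswidow/filterbank.py` — the five filters and the fixed chain
- `src/chaoswidow/quality.py` — MSE/PSNR/SSIM/ENL/EPI with ROI support
- `src/chaoswidow/bwoa.py` — the optimizer and the denoising fitness
- `src/chaoswidow/harness.py` — phantoms, noise, I/O, end-to-end and ablation runs
- `src/chaoswidow/cli.py` — the `chaoswidow` command
- `docs/methods.md` — model details, defaults, numerical choices, limitations
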