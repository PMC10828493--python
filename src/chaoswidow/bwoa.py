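"""Tent-chaos-enhanced Black Widow Optimization (BWOA).

A population of N "black widows" searches a box-bounded continuous space for
the parameter vector minimizing a fitness function.  Each iteration applies:

1.  Movement toward/away from the current best position,
        x_i(t+1) = x_i(t) -/+ m (x*(t) - x_i(t))            beta >= 0
        x_i(t+1) = x_i(t) -/+ m (x*(t) - x_i(t))
                   + beta (x*(t) - x_i(t))                  beta <  0
    with m ~ U[0.4, 0.9] and beta ~ U[-1, 1] drawn fresh per individual per
    iteration.  The sign of the m-term is configurable: ``as_printed``
    (the default, for fidelity to the published update) keeps the leading
    minus, while ``attractive`` flips it into the conventional attraction
    step; both are exposed and the run manifest records which one produced
    a result.
2.  A Gaussian + tent-map perturbation of the best position, accepted for
    individual i only when it improves on i's moved position.  The tent map
    acts here as the range guard: perturbed coordinates that leave the box
    are folded back into it by the tent's reflection (in normalized
    coordinates, u -> u for u in [0, 1], u -> 2 - u for u in (1, 2],
    periodically extended), so in-range perturbations keep their locality
    and out-of-range ones re-enter the box instead of piling up on a face.
3.  A pheromone update: individuals whose fitness improved gain
    f_old_i / sum_j f_old_j, worsened individuals lose the same amount;
    pheromone is clipped to [0, 1].
4.  Replacement: any individual whose pheromone falls to <= phi_th (0.3) is
    replaced by x_r1 + sigma (x_r2 - x_r3) with three distinct random peers
    and sigma ~ Bernoulli(1/2), and its pheromone resets to 1.

The initial population comes from the tent chaotic map (``use_tent=True``)
or plain uniform draws (the BWOA1.0 ablation).  The best-so-far position is
tracked separately from the population, so the reported fitness history is
non-increasing by construction.
"""

from __future__ import annotations

from dataclasses import dataclass, field, replace
from typing import Callable, List, Optional, Tuple

import numpy as np

from . import filterbank, quality
from .chaos import ChaosConfig, init_positions, tent_step
from .errors import (
    ConfigurationError,
    ContractViolationError,
    DegenerateInputError,
)
from .filterbank import FilterChainParams, apply_chain
from .space import Bounds

__all__ = [
    "Bounds",
    "BWOAConfig",
    "FitnessSpec",
    "OptimizeResult",
    "PARAM_ORDER",
    "default_bounds",
    "decode_params",
    "fitness",
    "make_objective",
    "move",
    "gaussian_tent_perturb",
    "update_pheromone",
    "replace_if_weak",
    "optimize",
    "optimize_denoise",
]

# fixed order of the 8 search dimensions
PARAM_ORDER = (
    "gaussian_sigma",
    "gaussian_ksize",
    "median_ksize",
    "mean_ksize",
    "bilateral_sigma_r",
    "bilateral_sigma_d",
    "bilateral_ksize",
    "sharpen_amount",
)


def default_bounds() -> Bounds:
    """Default 8-D search box: sigmas on their natural scales, window sizes
    as [0, 1] bin coordinates decoded to {3, 5, 7}."""
    lower = [0.3, 0.0, 0.0, 0.0, 5.0, 0.5, 0.0, 0.0]
    upper = [3.0, 1.0, 1.0, 1.0, 75.0, 5.0, 1.0, 2.0]
    return Bounds(np.array(lower), np.array(upper))


@dataclass
class BWOAConfig:
    """Algorithm constants plus the design knobs.

    Defaults follow the published settings: N = 20 widows, T = 50
    iterations, m in [0.4, 0.9], beta in [-1, 1], pheromone threshold 0.3.
    """

    population_size: int = 20
    max_iterations: int = 50
    m_range: Tuple[float, float] = (0.4, 0.9)
    beta_range: Tuple[float, float] = (-1.0, 1.0)
    pheromone_threshold: float = 0.3
    fitness_weight: float = 0.5
    perturbation_scale: float = 0.1
    use_tent: bool = True
    use_sharpen: bool = True
    movement_sign: str = "as_printed"
    rng_seed: int = 0
    chaos: ChaosConfig = field(default_factory=ChaosConfig)

    def __post_init__(self) -> None:
        if self.population_size < 4:
            raise ConfigurationError("population_size must be >= 4 (replacement needs 3 peers)")
        if self.max_iterations < 1:
            raise ConfigurationError("max_iterations must be >= 1")
        if not (0.0 < self.pheromone_threshold < 1.0):
            raise ConfigurationError("pheromone_threshold must lie in (0, 1)")
        if not (0.0 <= self.fitness_weight <= 1.0):
            raise ConfigurationError("fitness_weight must lie in [0, 1]")
        if self.perturbation_scale <= 0.0:
            raise ConfigurationError("perturbation_scale must be positive")
        if self.movement_sign not in ("as_printed", "attractive"):
            raise ConfigurationError("movement_sign must be 'as_printed' or 'attractive'")


@dataclass
class FitnessSpec:
    """Inputs of the denoising fitness: a clean reference and a noisy image."""

    reference: np.ndarray
    noisy: np.ndarray
    lambda_weight: float = 0.5
    use_sharpen: bool = True

    def __post_init__(self) -> None:
        self.reference = np.asarray(self.reference, dtype=float)
        self.noisy = np.asarray(self.noisy, dtype=float)
        if self.reference.shape != self.noisy.shape:
            raise ConfigurationError("reference and noisy images must share dimensions")
        if not (0.0 <= self.lambda_weight <= 1.0):
            raise ConfigurationError("lambda_weight must lie in [0, 1]")


@dataclass
class OptimizeResult:
    """Outcome of one optimizer run."""

    best_position: np.ndarray
    best_fitness: float
    history: List[dict]          # per-iteration {"iteration", "best_fitness", "mean_pheromone"}
    n_evaluations: int
    chaos_x0: Optional[float]    # tent seed actually used (None for uniform init)


# --------------------------------------------------------------------------
# parameter decoding and fitness

_KSIZE_DIMS = {1, 2, 3, 6}


def _decode_ksize(value: float, lo: float, hi: float) -> int:
    u = (value - lo) / (hi - lo)
    idx = min(int(u * 3.0), 2)
    return filterbank.ALLOWED_KSIZES[idx]


def decode_params(x: np.ndarray, bounds: Bounds) -> FilterChainParams:
    """Decode a continuous 8-D position into filter-chain settings.

    Sigma and amount dimensions pass through unchanged; window-size
    dimensions are split into three equal bins mapped to 3, 5, 7.  Decoding
    is idempotent by construction (pure function of the position).
    """
    x = np.asarray(x, dtype=float).ravel()
    if x.size != len(PARAM_ORDER) or bounds.ndim != len(PARAM_ORDER):
        raise ContractViolationError(
            f"expected a {len(PARAM_ORDER)}-D position/bounds, got {x.size}/{bounds.ndim}"
        )
    if not bounds.contains(x):
        raise ContractViolationError("position lies outside the search bounds")
    vals = {}
    for d, name in enumerate(PARAM_ORDER):
        if d in _KSIZE_DIMS:
            vals[name] = _decode_ksize(x[d], bounds.lower[d], bounds.upper[d])
        else:
            vals[name] = float(x[d])
    return FilterChainParams(**vals)


def fitness(x: np.ndarray, spec: FitnessSpec, bounds: Bounds | None = None) -> float:
    """Scalarized denoising objective (minimized).

    lambda * (1 - SSIM(ref, denoised)) + (1 - lambda) * MSE(ref, denoised)/L^2,
    with L = 255.  Zero only for a perfect reconstruction.
    """
    if bounds is None:
        bounds = default_bounds()
    p = decode_params(x, bounds)
    denoised = apply_chain(spec.noisy, p, use_sharpen=spec.use_sharpen)
    lam = spec.lambda_weight
    s = quality.ssim(spec.reference, denoised)
    m = quality.mse(spec.reference, denoised)
    return lam * (1.0 - s) + (1.0 - lam) * m / (255.0**2)


def make_objective(spec: FitnessSpec, bounds: Bounds) -> Callable[[np.ndarray], float]:
    """Bind a FitnessSpec into a plain ``objective(x) -> float`` callable."""

    def objective(x: np.ndarray) -> float:
        return fitness(x, spec, bounds)

    return objective


# --------------------------------------------------------------------------
# update operators

def move(
    x_i: np.ndarray,
    x_best: np.ndarray,
    m: float,
    beta: float,
    sign_mode: str = "attractive",
    m_range: Tuple[float, float] = (0.4, 0.9),
    beta_range: Tuple[float, float] = (-1.0, 1.0),
) -> np.ndarray:
    """One movement step; the caller clips the result to bounds."""
    if not (m_range[0] <= m <= m_range[1]):
        raise ContractViolationError(f"m={m} outside {m_range}")
    if not (beta_range[0] <= beta <= beta_range[1]):
        raise ContractViolationError(f"beta={beta} outside {beta_range}")
    x_i = np.asarray(x_i, dtype=float)
    diff = np.asarray(x_best, dtype=float) - x_i
    if sign_mode == "as_printed":
        out = x_i - m * diff
    elif sign_mode == "attractive":
        out = x_i + m * diff
    else:
        raise ConfigurationError(f"unknown sign_mode {sign_mode!r}")
    if beta < 0.0:
        out = out + beta * diff
    return out


def gaussian_tent_perturb(
    x_best: np.ndarray,
    bounds: Bounds,
    scale: float,
    rng: np.random.Generator,
) -> np.ndarray:
    """Gaussian jitter of the best position with tent-map range folding.

    y = x_best + eps with eps ~ N(0, (scale * span)^2) per dimension; each
    coordinate is normalized to u = (y - x_min) / (x_max - x_min) and folded
    back into [0, 1] by the tent reflection (u unchanged inside [0, 1],
    u -> 2 - u on (1, 2], extended periodically), then rescaled into the
    box.  The fold is exactly the full-height tent map applied on the
    doubled domain, serving as the range guarantee of the perturbation:
    in-range jitter stays local to the best position, out-of-range jitter
    reflects off the box faces.  Always lands inside the bounds.
    """
    if scale <= 0.0:
        raise ConfigurationError("perturbation scale must be positive")
    x_best = np.asarray(x_best, dtype=float)
    y = x_best + rng.normal(0.0, scale * bounds.span)
    u = (y - bounds.lower) / bounds.span
    u = np.mod(u, 2.0)
    u = np.where(u <= 1.0, u, 2.0 - u)
    return bounds.lower + bounds.span * u


def update_pheromone(phi_i: float, f_old: float, f_new: float, f_sum: float) -> float:
    """Pheromone bookkeeping: reward improvement, punish worsening."""
    if f_sum <= 0.0:
        raise DegenerateInputError("population fitness sum must be positive")
    delta = f_old / f_sum
    phi = phi_i + delta if f_old >= f_new else phi_i - delta
    return float(np.clip(phi, 0.0, 1.0))


def replace_if_weak(
    i: int,
    positions: np.ndarray,
    pheromone: np.ndarray,
    phi_th: float,
    bounds: Bounds,
    rng: np.random.Generator,
) -> Tuple[np.ndarray, bool]:
    """Replace individual i when its pheromone has dropped to <= phi_th.

    New position: x_r1 + sigma (x_r2 - x_r3) with r1, r2, r3 distinct
    indices != i and sigma in {0, 1} equiprobable; clipped to bounds.
    Returns (position, replaced_flag); the caller resets pheromone on
    replacement.
    """
    n = positions.shape[0]
    if n < 4:
        raise ConfigurationError("replacement needs a population of at least 4")
    if pheromone[i] > phi_th:
        return positions[i].copy(), False
    others = [j for j in range(n) if j != i]
    r1, r2, r3 = rng.choice(others, size=3, replace=False)
    sigma = float(rng.integers(0, 2))
    new = positions[r1] + sigma * (positions[r2] - positions[r3])
    return bounds.clip(new), True


# --------------------------------------------------------------------------
# main loop

def optimize(
    objective: Callable[[np.ndarray], float],
    bounds: Bounds,
    cfg: BWOAConfig,
) -> OptimizeResult:
    """Run the improved black-widow search on an arbitrary objective.

    Deterministic under ``cfg.rng_seed``: one ``numpy`` Generator drives the
    tent seed, the movement draws, the perturbations and the replacements.
    """
    rng = np.random.default_rng(cfg.rng_seed)
    n, d = cfg.population_size, bounds.ndim
    n_evals = 0

    def evaluate(x: np.ndarray) -> float:
        nonlocal n_evals
        f = float(objective(x))
        if not np.isfinite(f):
            raise DegenerateInputError(f"non-finite fitness {f} at position {x}")
        n_evals += 1
        return f

    chaos_x0: Optional[float] = None
    if cfg.use_tent:
        ccfg = cfg.chaos
        if ccfg.x0 is None:
            ccfg = replace(ccfg, x0=float(rng.uniform(1e-6, 1.0 - 1e-6)))
        chaos_x0 = ccfg.x0
        positions = init_positions(bounds, n, d, ccfg, rng)
    else:
        positions = bounds.lower + bounds.span * rng.random((n, d))

    fit = np.array([evaluate(x) for x in positions])
    pheromone = np.ones(n)
    best_idx = int(np.argmin(fit))  # argmin breaks ties by lowest index
    best_x = positions[best_idx].copy()
    best_f = float(fit[best_idx])

    history: List[dict] = []
    for t in range(cfg.max_iterations):
        f_old = fit.copy()
        f_sum = float(f_old.sum())
        for i in range(n):
            m = float(rng.uniform(*cfg.m_range))
            beta = float(rng.uniform(*cfg.beta_range))
            cand = move(positions[i], best_x, m, beta, cfg.movement_sign,
                        cfg.m_range, cfg.beta_range)
            cand = bounds.clip(cand)
            positions[i] = cand
            fit[i] = evaluate(cand)

            pert = gaussian_tent_perturb(best_x, bounds, cfg.perturbation_scale, rng)
            f_pert = evaluate(pert)
            if f_pert < fit[i]:
                positions[i] = pert
                fit[i] = f_pert

            if f_sum > 0.0:
                pheromone[i] = update_pheromone(pheromone[i], f_old[i], fit[i], f_sum)

        for i in range(n):
            new_pos, replaced = replace_if_weak(
                i, positions, pheromone, cfg.pheromone_threshold, bounds, rng
            )
            if replaced:
                positions[i] = new_pos
                fit[i] = evaluate(new_pos)
                pheromone[i] = 1.0

        cur = int(np.argmin(fit))
        if fit[cur] < best_f:
            best_f = float(fit[cur])
            best_x = positions[cur].copy()
        history.append(
            {
                "iteration": t,
                "best_fitness": best_f,
                "mean_pheromone": float(pheromone.mean()),
            }
        )

    return OptimizeResult(
        best_position=best_x,
        best_fitness=best_f,
        history=history,
        n_evaluations=n_evals,
        chaos_x0=chaos_x0,
    )


def optimize_denoise(
    spec: FitnessSpec,
    cfg: BWOAConfig,
    bounds: Bounds | None = None,
) -> Tuple[OptimizeResult, FilterChainParams]:
    """Optimize the filter chain for one (reference, noisy) pair.

    ``spec.use_sharpen`` and ``spec.lambda_weight`` are synchronized with the
    config so ablation variants need only flip config flags.
    """
    if bounds is None:
        bounds = default_bounds()
    spec = FitnessSpec(
        reference=spec.reference,
        noisy=spec.noisy,
        lambda_weight=cfg.fitness_weight,
        use_sharpen=cfg.use_sharpen,
    )
    result = optimize(make_objective(spec, bounds), bounds, cfg)
    return result, decode_params(result.best_position, bounds)
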