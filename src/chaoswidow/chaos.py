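"""Tent chaotic map and chaos-based population initialization.

The tent map

    x_{k+1} = mu * x_k         if x_k <= 1/2
    x_{k+1} = mu * (1 - x_k)   if x_k >  1/2

with control parameter ``mu = 2`` produces well-spread, low-discrepancy
sequences on [0, 1] that are used to seed the initial positions of the
black-widow population: position (i, d) is the affine image of one element of
a single global tent sequence consumed in row-major order,

    x[i, d] = x_min[d] + (x_max[d] - x_min[d]) * c .

Numerical caveat: at mu = 2 the map is exactly the bit-shift map, so in binary
floating point every orbit collapses to 0 within ~53 steps, and the points
0, 1/2 and 1 are absorbing.  We therefore nudge any iterate that lands within
``collapse_epsilon`` of one of those values toward the interior by
``collapse_epsilon * (1 + u)`` with u a fresh uniform draw from the run RNG.
The nudge keeps mu = 2 while guaranteeing non-degenerate sequences; nudge
events are reported so tests can compare against exact rational arithmetic up
to the first event.
"""

from __future__ import annotations

from dataclasses import dataclass
from typing import Optional

import numpy as np

from .errors import ConfigurationError, DomainError
from .space import Bounds

__all__ = ["ChaosConfig", "tent_step", "tent_sequence", "init_positions"]


@dataclass
class ChaosConfig:
    """Parameters of the tent-map sequence generator.

    Attributes
    ----------
    mu
        Control parameter, 0 < mu <= 2.  mu = 2 gives full-height chaos.
    x0
        Seed in the open interval (0, 1).  ``None`` means "draw once from the
        run RNG"; the drawn value is recorded in run manifests.
    collapse_epsilon
        Radius of the absorbing-value guard described in the module docstring.
    """

    mu: float = 2.0
    x0: Optional[float] = None
    collapse_epsilon: float = 1e-12

    def __post_init__(self) -> None:
        if not (0.0 < self.mu <= 2.0):
            raise ConfigurationError(f"mu must lie in (0, 2], got {self.mu}")
        if self.x0 is not None and not (0.0 < self.x0 < 1.0):
            raise ConfigurationError(f"x0 must lie in (0, 1), got {self.x0}")
        if not (0.0 < self.collapse_epsilon < 1e-3):
            raise ConfigurationError("collapse_epsilon must be a small positive number")


def tent_step(x: float, mu: float = 2.0) -> float:
    """One application of the tent map.

    Both printed branch conditions are closed at 1/2 (the branches agree
    there); we take the lower branch for x <= 1/2.
    """
    if not (0.0 <= x <= 1.0):
        raise DomainError(f"tent map iterate must lie in [0, 1], got {x}")
    if not (0.0 < mu <= 2.0):
        raise DomainError(f"mu must lie in (0, 2], got {mu}")
    return mu * x if x <= 0.5 else mu * (1.0 - x)


def tent_sequence(
    cfg: ChaosConfig,
    n: int,
    rng: Optional[np.random.Generator] = None,
    *,
    with_events: bool = False,
):
    """Generate ``n`` tent-map iterates starting at the seed itself.

    Returns the sequence as a float array; with ``with_events=True`` also
    returns the list of indices at which the absorbing-value nudge fired.
    """
    if n < 1:
        raise ConfigurationError("sequence length must be >= 1")
    if rng is None:
        rng = np.random.default_rng(0)
    eps = cfg.collapse_epsilon
    x = cfg.x0 if cfg.x0 is not None else float(rng.uniform(eps, 1.0 - eps))

    seq = np.empty(n, dtype=float)
    events: list[int] = []
    for k in range(n):
        seq[k] = x
        # guard the absorbing values before stepping
        nudged = x
        if abs(nudged) <= eps:
            nudged = eps * (1.0 + rng.random())
        elif abs(nudged - 0.5) <= eps:
            nudged = 0.5 + eps * (1.0 + rng.random())
        elif abs(nudged - 1.0) <= eps:
            nudged = 1.0 - eps * (1.0 + rng.random())
        if nudged != x:
            events.append(k)
        x = tent_step(nudged, cfg.mu)
    if with_events:
        return seq, events
    return seq


def init_positions(
    bounds: Bounds,
    n_individuals: int,
    n_dims: int,
    cfg: ChaosConfig,
    rng: Optional[np.random.Generator] = None,
) -> np.ndarray:
    """Chaotic initialization of the population position matrix.

    One global tent sequence of length ``n_individuals * n_dims`` is consumed
    in row-major (individual, dimension) order and mapped affinely into the
    box, so recovering ``(x - x_min) / (x_max - x_min)`` reproduces the
    sequence exactly.
    """
    if n_individuals < 1 or n_dims < 1:
        raise ConfigurationError("population and dimension counts must be >= 1")
    if bounds.ndim != n_dims:
        raise ConfigurationError(
            f"bounds have {bounds.ndim} dimensions, expected {n_dims}"
        )
    c = tent_sequence(cfg, n_individuals * n_dims, rng).reshape(n_individuals, n_dims)
    return bounds.lower + bounds.span * c
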