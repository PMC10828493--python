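"""Box-constrained search spaces.

The optimizer works on a d-dimensional axis-aligned box; every position it
ever produces is clipped back into the box.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np

from .errors import ConfigurationError

__all__ = ["Bounds"]


@dataclass(frozen=True)
class Bounds:
    """Per-dimension lower/upper bounds of the search space.

    Parameters
    ----------
    lower, upper
        1-D arrays of equal length with ``lower[d] < upper[d]`` for every d.
    """

    lower: np.ndarray
    upper: np.ndarray

    def __post_init__(self) -> None:
        lo = np.asarray(self.lower, dtype=float).ravel()
        hi = np.asarray(self.upper, dtype=float).ravel()
        object.__setattr__(self, "lower", lo)
        object.__setattr__(self, "upper", hi)
        if lo.shape != hi.shape or lo.size == 0:
            raise ConfigurationError("bounds vectors must be non-empty and equally long")
        if not np.all(lo < hi):
            raise ConfigurationError("every lower bound must be strictly below its upper bound")

    @property
    def ndim(self) -> int:
        return self.lower.size

    @property
    def span(self) -> np.ndarray:
        return self.upper - self.lower

    def clip(self, x: np.ndarray) -> np.ndarray:
        """Project a position (or stack of positions) onto the box."""
        return np.clip(x, self.lower, self.upper)

    def contains(self, x: np.ndarray, atol: float = 1e-9) -> bool:
        x = np.asarray(x, dtype=float)
        return bool(np.all(x >= self.lower - atol) and np.all(x <= self.upper + atol))

    def to_lists(self) -> dict:
        return {"lower": self.lower.tolist(), "upper": self.upper.tolist()}
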