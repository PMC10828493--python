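"""The black-widow optimizer on a known 2-D objective.

Minimizing ||x - theta||^2 with theta = (1.3, -2.1) shows the optimizer
recovering a known parameter vector; the printed history is the
non-increasing best-so-far fitness.
"""

import numpy as np

from chaoswidow import Bounds, BWOAConfig, optimize

theta = np.array([1.3, -2.1])
bounds = Bounds(np.array([-5.0, -5.0]), np.array([5.0, 5.0]))
cfg = BWOAConfig(rng_seed=1)  # N = 20, T = 50 defaults

result = optimize(lambda x: float(np.sum((x - theta) ** 2)), bounds, cfg)

print(f"target    : {theta}")
print(f"recovered : {np.round(result.best_position, 4)}")
print(f"fitness   : {result.best_fitness:.3g} after {result.n_evaluations} evaluations")
print("\nbest-so-far fitness every 10 iterations:")
for h in result.history[::10]:
    print(f"  iter {h['iteration']:3d}: {h['best_fitness']:.4g}")
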