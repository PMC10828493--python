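"""Tent chaotic sequences and population initialization.

The tent map at mu = 2 spreads points evenly over [0, 1]; mapping one long
sequence affinely into the search box seeds the black-widow population with
well-scattered starting positions.
"""

import numpy as np

from chaoswidow import Bounds, ChaosConfig, init_positions, tent_sequence

cfg = ChaosConfig(mu=2.0, x0=0.137)
seq = tent_sequence(cfg, 10)
print("first 10 tent iterates from x0=0.137:")
print(np.round(seq, 6))

bounds = Bounds(np.array([0.3, 5.0]), np.array([3.0, 75.0]))
pos = init_positions(bounds, n_individuals=5, n_dims=2, cfg=cfg)
print("\n5 initial positions in the box [0.3,3] x [5,75]:")
print(np.round(pos, 3))
print("\nEach row is one widow; chaotic spacing avoids the clustering that "
      "plain uniform draws can produce in small populations.")
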