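"""Detect spatial modules with the two-level map equation.

Builds a weighted directed network with two planted communities (dense
within, one weak bridge) and recovers them by minimising the map-equation
description length. The codelength of the best partition is compared against
the trivial one-module partition: fewer bits means the module structure
genuinely compresses a random walk's itinerary.
"""

import numpy as np

from storknet import mapeq

w = np.zeros((8, 8))
for grp in (range(4), range(4, 8)):
    for i in grp:
        for j in grp:
            if i != j:
                w[i, j] = 10.0
w[3, 4] = w[4, 3] = 1.0  # weak bridge

flow = mapeq.stationary_flow(w, tau=0.15)
one_module = mapeq.codelength(np.zeros(8, dtype=int), flow, w)
part = mapeq.detect_modules(w, seed=0)

print(f"one-module codelength: {one_module:.4f} bits (= entropy of visit rates)")
print(f"optimal partition:     {part.codelength_bits:.4f} bits")
print(f"modules found: {part.modules.tolist()}  (nodes 0-3 vs 4-7)")
print("the planted two-clique structure saves "
      f"{one_module - part.codelength_bits:.3f} bits per walk step")
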