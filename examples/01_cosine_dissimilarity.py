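"""Cosine-distance dissimilarity between functional-connectivity patterns.

Builds two small FC edge vectors and prints their dissimilarity in the
three regimes that anchor interpretation: proportional patterns (distance
0: same connectivity profile up to overall strength), orthogonal patterns
(distance 1: unrelated profiles), and antipodal patterns (distance 2).
"""

import numpy as np

from fcx.network_stats import cosine_distance

rng = np.random.default_rng(0)
a = rng.standard_normal(45)  # edge vector of a 10-region FC matrix

print(f"proportional (b = 2a):   d = {cosine_distance(a, 2 * a):.6f}")
b = np.concatenate([np.zeros(22), rng.standard_normal(23)])
a_disjoint = np.concatenate([a[:22], np.zeros(23)])
print(f"orthogonal (disjoint):   d = {cosine_distance(a_disjoint, b):.6f}")
print(f"antipodal (b = -a):      d = {cosine_distance(a, -a):.6f}")
print()
print("A distance near 0 means two task conditions engage the same")
print("connectivity pattern (differing at most in overall strength); near 1")
print("means the patterns are unrelated.")
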