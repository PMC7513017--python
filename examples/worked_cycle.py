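"""Worked example: all measures on the 4-node unit-weight cycle.

Every node of the cycle has two unit edges, so the stationary random walk
is uniform and every quantity has a closed form: H = log2 4 = 2 bits, the
walker always faces a binary choice so H(Xt+1|Xt) = 1 bit and MI = 1 bit,
and knowing the future on top of the past removes no uncertainty, so the
erasure mutual information is also 1 bit.
"""

import numpy as np

from connwalk import ConnectivityMatrix, build_model, compute_global, compute_local

C = np.zeros((4, 4))
for a, b in [(0, 1), (1, 2), (2, 3), (3, 0)]:
    C[a, b] = C[b, a] = 1.0

model = build_model(ConnectivityMatrix(C))

print("Global measures (bits):")
for name, value in compute_global(model).as_dict().items():
    print(f"  {name:15s} {value:.4f}")

print("\nPer-node measures (bits):")
print(compute_local(model).round(4))

print(
    "\nEvery node is interchangeable, so the per-node decompositions are "
    "flat: surprise E = 2 bits (mu_i = 1/4 each) and each of I1, I2, I1e "
    "contributes exactly its global counterpart (1 bit)."
)
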