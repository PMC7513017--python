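"""How the global measures respond to edge density.

Sweeps the edge count of 128-node random networks and prints the
replicate-averaged measures.  Entropy saturates toward log2(128) = 7 bits
as the graph densifies, while mutual information first rises (very sparse
graphs leave nodes disconnected) and then decays: the more connections a
node has, the less its identity tells you about the next step.
"""

from connwalk import edge_sweep

table = edge_sweep(
    "random",
    n=128,
    m_values=[16, 64, 128, 512, 1024, 2048, 4096, 8128],
    replicates=5,
    seed=7,
)
mean = table.groupby("m")[["H", "MI", "EMI"]].mean()
print("Random family, n = 128, 5 replicates per edge count (values in bits):\n")
print(mean.round(4))
print(
    "\nH climbs toward 7 bits with density; MI and EMI peak at low edge "
    "counts and then fall as extra edges make the walk harder to predict."
)
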