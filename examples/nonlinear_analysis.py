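"""Chaos-theoretic analysis of simulated interspike-interval series.

Runs healthy and pathology simulations, then characterizes a CA3
pyramidal cell's ISI sequence: embedding delay (autocorrelation), minimal
embedding dimension (false nearest neighbors), correlation dimension
(Grassberger-Procaccia) and Shannon entropy, plus the recurrence-plot
distance matrix.
"""

import numpy as np

import hipposim as h
from hipposim.nonlinear import nla_summary, recurrence_matrix, shannon_entropy

net = h.build_default_network(seed=2)
control = h.run(net, 10000.0, seed=2)
pathology = h.run(net, 10000.0, seed=2, lesion_schedule=h.build_lesion_schedule(net))

isi = np.diff(control.spike_trains["P5"])
res = nla_summary(isi)
print(f"P5 (healthy): {isi.size} ISIs")
print(f"  embedding delay tau        : {res.delay} samples")
print(f"  FNN embedding dimension    : {res.embedding_dimension}")
print(f"  correlation dimension D2   : {res.correlation_dimension:.2f}")
print(f"  Shannon entropy            : {res.entropy_bits:.2f} bits (16-bin ISI histogram)")

mat = recurrence_matrix(isi, res.delay, m=3)
print(f"  recurrence matrix          : {mat.shape[0]}x{mat.shape[1]} Euclidean distances")

h_ctrl = np.mean([shannon_entropy(np.diff(control.spike_trains[c]))
                  for c in ("P5", "P6", "P7", "P8") if control.spike_count(c) > 2])
h_path = np.mean([shannon_entropy(np.diff(pathology.spike_trains[c]))
                  for c in ("P5", "P6", "P7", "P8") if pathology.spike_count(c) > 2])
print(f"\nCA3 PC ISI entropy: healthy {h_ctrl:.2f} vs pathology {h_path:.2f} bits")
print("Synaptic deletion impoverishes the firing repertoire, lowering ISI entropy.")
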