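"""The 42-element feature vector of one rhythm-filtered channel.

A 2-level Daubechies-4 wavelet packet transform yields six coefficient
nodes; each node contributes five entropies (Shannon, log-energy, norm,
threshold, SURE) and two fractal dimensions (Higuchi, Katz).
"""

import numpy as np

import eegvote as ev
from eegvote.features import feature_labels

rng = np.random.default_rng(0)
t = np.arange(8064) / 128.0
# a 10 Hz oscillation buried in noise, as a stand-in for an alpha waveform
signal = 5.0 * np.sin(2 * np.pi * 10.0 * t) + rng.standard_normal(8064)

nodes = ev.wpt_decompose(signal)
print(f"wavelet-packet nodes: {[(n.level, n.node_index) for n in nodes]}")

vector = ev.channel_features(signal)
print(f"feature vector length: {len(vector)}\n")
print("first node (level 1, approximation) features:")
for label, value in zip(feature_labels()[:7], vector[:7]):
    print(f"  {label:10s} {value:14.4f}")
print("\nEntropies summarize the energy structure of the node's")
print("coefficients; the fractal dimensions (typically between 1 and 2)")
print("measure how rough the coefficient sequence is.")
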