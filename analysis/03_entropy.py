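#!/usr/bin/env python
"""Entropy diagnostics: which hemilineages look multimodal, and why.

Computes neuron-level entropy H(N_h) and mean synapse-level entropy H(S_h)
for every hemilineage, then labels each by the quartile quadrants: high
H(N_h) with low H(S_h) indicates genuine neuron-level transmitter
segregation, high H(S_h) indicates within-neuron prediction mixing.
"""

import argparse
from pathlib import Path

import pandas as pd

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

ent = pd.read_csv(args.results / "entropy.csv")
print(ent.to_string(index=False, float_format=lambda v: f"{v:.3f}"))

truth = pd.read_csv(args.results / "study" / "truth_hemilineages.csv")
merged = ent.merge(truth, on="hemilineage")
multi = merged[merged["m_true"] > 1]
single = merged[merged["m_true"] == 1]
print(
    f"\nmean H(N_h): single-transmitter {single['H_neuron'].mean():.3f}, "
    f"multi-transmitter {multi['H_neuron'].mean():.3f}"
    if len(multi)
    else "\nno multi-transmitter hemilineages in this study"
)
if "quadrant" in merged.columns and len(multi):
    seg = multi[multi["quadrant"] == "neuron_segregated"]
    print(f"multi-transmitter hemilineages labeled neuron_segregated: {len(seg)}/{len(multi)}")
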