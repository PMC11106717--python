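#!/usr/bin/env python
"""Cross-hemisphere consistency of neuron-level calls.

Compares each neuron's call with its mirrored homolog: agreement matrix,
match:mismatch ratio, confidence by group (mismatched pairs should be less
confident), and KL similarity of synapse-level distributions.
"""

import argparse
from pathlib import Path

import pandas as pd

from ntcalls import pair_agreement_matrix

parser = argparse.ArgumentParser()
parser.add_argument("--results", type=Path, default=Path("results"))
args = parser.parse_args()

pairs = pd.read_csv(args.results / "pairs.csv")
mismatch = pd.read_csv(args.results / "mismatch.csv")

calls = pd.read_csv(args.results / "neuron_calls.csv").rename(columns={"conf_nt": "winner"})
M, norm = pair_agreement_matrix(pairs[["neuron_a", "neuron_b"]], calls)
print("agreement matrix (rows = right hemisphere, cols = left):")
print(M.to_string())
print("\nmatch/mismatch summary:")
print(mismatch.to_string(index=False))
scored = pairs.dropna(subset=["kl_sym"])
print(f"\nmean symmetrized KL over {len(scored)} pairs: {scored['kl_sym'].mean():.4f} nats")
by_match = scored.dropna(subset=["match"]).groupby("match")["kl_sym"].mean()
print("mean KL by agreement:", {bool(k): round(v, 4) for k, v in by_match.items()})
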