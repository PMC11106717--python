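#!/usr/bin/env python
"""Filter presynapses and produce neuron- and cell-type-level calls.

Applies the standard retention rules (cleft score > 50, axon/dendrite only,
>= 15 um from the soma, >= 0.1 um from the primary dendrite), votes, and
scores confidence against a diagonal-0.9 synapse confusion matrix. Reports
how many calls the full filter changed relative to the threshold-only vote
(the `top_nt` vs `conf_nt` columns).
"""

import argparse
from pathlib import Path

import pandas as pd

from ntcalls import RunConfig, diagonal_confusion, run_pipeline

parser = argparse.ArgumentParser()
parser.add_argument("--seed", type=int, default=1)
parser.add_argument("--study", type=Path, default=Path("results/study"))
parser.add_argument("--out", type=Path, default=Path("results"))
parser.add_argument("--min-presynapses", type=int, default=30)
args = parser.parse_args()

synapses = pd.read_csv(args.study / "synapses.csv")
neurons = pd.read_csv(args.study / "neurons.csv")
C = diagonal_confusion(0.9, level="synapse")

rc = RunConfig(seed=args.seed, out_dir=str(args.out), min_presynapses=args.min_presynapses)
res = run_pipeline(rc, synapses=synapses, neurons=neurons, C=C)

calls = res["calls"]
rep = res["filter_report"]["full"]
print(f"filter ledger: {rep}")
changed = (calls["top_nt"] != calls["conf_nt"]).mean()
uncertain = (calls["conf_nt"] == "uncertain").mean()
print(f"full filtering changed {changed:.1%} of neuron-level calls")
print(f"uncertain calls: {uncertain:.1%} of {len(calls)} neurons")

truth = pd.read_csv(args.study / "truth_neurons.csv")
merged = calls.merge(truth, on="neuron_id")
certain = merged[merged["conf_nt"] != "uncertain"]
acc = (certain["conf_nt"] == certain["true_transmitter"]).mean()
print(f"accuracy of non-uncertain calls vs ground truth: {acc:.1%}")
print(res["celltypes"]["conflicted"].value_counts().rename("cell types").to_string())
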