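"""Parameter-recovery experiments for the hemilineage Bayes analysis.

Simulates hemilineages with a known number of true transmitters under the
i.i.d. confusion-row sampling assumption, runs the full vote -> Bayes
pipeline, and scores how often the one-vs-rest Bayes factor identifies the
true transmitter count. This is the package's main self-validation: with a
diagonal-0.9 confusion matrix, 30 neurons of 200 synapses each, and the
default prior (lambda = 16, eps = 1e-3), recovery should be nearly perfect
for single-transmitter hemilineages and high for balanced two-transmitter
ones.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .aggregation import FilterPolicy, neuron_call
from .bayes import analyze_hemilineage
from .confusion import ConfusionMatrix, SmoothingPrior, diagonal_confusion, expected_confusion
from .labels import N_TRANSMITTERS, TRANSMITTERS, UNCERTAIN

__all__ = ["recovery_study"]


def recovery_study(
    m_true: int,
    n_hemilineages: int = 100,
    n_neurons: int = 30,
    n_synapses: int = 200,
    C_syn: ConfusionMatrix | None = None,
    C_neuron: ConfusionMatrix | None = None,
    prior: SmoothingPrior | None = None,
    split: tuple[float, ...] | None = None,
    min_presynapses: int = 30,
    seed: int = 0,
) -> pd.DataFrame:
    """Simulate ``n_hemilineages`` with ``m_true`` transmitters; score recovery.

    Each hemilineage draws ``m_true`` distinct transmitters, assigns neurons
    by ``split`` (default balanced), samples each neuron's per-synapse labels
    from the synapse confusion row of its true transmitter, votes, and runs
    the Bayes analysis on the non-uncertain winners with the neuron confusion
    matrix. Returns one row per hemilineage with ``best_m``, the top
    one-vs-rest Bayes factor, and a ``correct`` flag.
    """
    if C_syn is None:
        C_syn = diagonal_confusion(0.9, level="synapse")
    if C_neuron is None:
        C_neuron = diagonal_confusion(0.9, level="neuron")
    if prior is None:
        prior = SmoothingPrior(16.0, 1e-3)
    if split is None:
        split = tuple([1.0 / m_true] * m_true)
    if len(split) != m_true or not np.isclose(sum(split), 1.0):
        raise ValueError(f"split must be {m_true} shares summing to 1, got {split}")

    rng = np.random.default_rng(seed)
    C_eff = expected_confusion(C_neuron, prior)
    policy = FilterPolicy(min_presynapses=min_presynapses)

    # largest-remainder allocation of neurons to the hemilineage's transmitters
    raw = np.asarray(split) * n_neurons
    alloc = np.floor(raw).astype(int)
    for i in np.argsort(-(raw - alloc))[: n_neurons - alloc.sum()]:
        alloc[i] += 1

    rows = []
    for h in range(n_hemilineages):
        transmitters = rng.choice(N_TRANSMITTERS, size=m_true, replace=False)
        winners = []
        for t_idx, k in zip(transmitters, alloc):
            row_p = C_syn.C[t_idx]
            for _ in range(int(k)):
                labels_idx = rng.choice(N_TRANSMITTERS, size=n_synapses, p=row_p)
                labels = [TRANSMITTERS[i] for i in labels_idx]
                winners.append(neuron_call(labels, policy=policy).winner)
        usable = [w for w in winners if w != UNCERTAIN]
        res = analyze_hemilineage(
            usable, C_neuron, prior, hemilineage_id=h, C_eff=C_eff
        )
        rows.append(
            {
                "hemilineage": h,
                "m_true": m_true,
                "best_m": res.best_m,
                "K_best": float(res.one_vs_rest_K[res.best_m - 1]),
                "evidence": res.best_evidence,
                "n_usable": len(usable),
                "correct": res.best_m == m_true,
            }
        )
    return pd.DataFrame(rows)
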