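"""Base-6 Shannon entropy diagnostics of transmitter-prediction multimodality.

Two complementary entropies characterize a hemilineage h:

* neuron-level entropy H(N_h): entropy of the distribution of neuron-level
  winning transmitters over the member neurons — high when different neurons
  of the hemilineage are called differently;
* mean synapse-level entropy H(S_h): the per-neuron entropy H(S_n) of
  synapse-label frequencies, averaged over members — high when individual
  neurons carry mixed per-synapse predictions.

Both use the base-6 logarithm so values live in [0, 1] over the six-class
label space: 0 = unanimous, 1 = all six classes equally common. Jointly they
separate genuine neuron-level transmitter segregation within a hemilineage
(high H(N_h), low H(S_h)) from mere per-synapse prediction noise (high
H(S_h)).
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import LABEL_INDEX, N_TRANSMITTERS, UNCERTAIN

__all__ = [
    "base6_entropy",
    "neuron_level_entropy",
    "neuron_synapse_entropy",
    "hemilineage_synapse_entropy",
    "entropy_quadrants",
    "hemilineage_entropies",
    "ELIGIBLE_MIN_NEURONS",
    "ELIGIBLE_MIN_SYNAPSES",
]

#: Eligibility for the hemilineage entropy scatter: strictly more than 10
#: neurons, each with strictly more than 30 presynapses.
ELIGIBLE_MIN_NEURONS = 10
ELIGIBLE_MIN_SYNAPSES = 30


def base6_entropy(p: np.ndarray) -> float:
    """Shannon entropy of a 6-class distribution in base-6, with 0 log 0 := 0."""
    p = np.asarray(p, dtype=float)
    if p.ndim != 1 or p.size != N_TRANSMITTERS:
        raise ValueError(f"expected a {N_TRANSMITTERS}-vector, got shape {p.shape}")
    if np.any(p < -1e-12) or not np.isclose(p.sum(), 1.0, atol=1e-9):
        raise ValueError("entropy argument must be a probability vector")
    nz = p[p > 0]
    return float(-(nz * (np.log(nz) / np.log(N_TRANSMITTERS))).sum()) + 0.0


def _label_distribution(labels, what: str) -> np.ndarray:
    counts = np.zeros(N_TRANSMITTERS)
    n = 0
    for lab in labels:
        if lab == UNCERTAIN:
            continue
        counts[LABEL_INDEX[lab]] += 1
        n += 1
    if n == 0:
        raise ValueError(f"entropy undefined: no usable {what}")
    return counts / n


def neuron_level_entropy(winners) -> float:
    """H(N_h): base-6 entropy of neuron-level winners within a hemilineage.

    "uncertain" calls are excluded (they are not elements of the label
    space); at least one non-uncertain call is required.
    """
    return base6_entropy(_label_distribution(winners, "neuron calls"))


def neuron_synapse_entropy(labels) -> float:
    """H(S_n): base-6 entropy of one neuron's per-synapse label frequencies."""
    return base6_entropy(_label_distribution(labels, "synapse labels"))


def hemilineage_synapse_entropy(per_neuron_labels) -> float:
    """H(S_h): unweighted mean of H(S_n) over a hemilineage's member neurons."""
    entropies = [neuron_synapse_entropy(labels) for labels in per_neuron_labels]
    if not entropies:
        raise ValueError("entropy undefined: hemilineage has no member neurons")
    return float(np.mean(entropies))


def hemilineage_entropies(
    synapses: pd.DataFrame,
    calls: pd.DataFrame,
    neurons: pd.DataFrame,
) -> pd.DataFrame:
    """Per-hemilineage entropy table with eligibility flags.

    A hemilineage is eligible for the quadrant scatter when it has more than
    ``ELIGIBLE_MIN_NEURONS`` member neurons, each with more than
    ``ELIGIBLE_MIN_SYNAPSES`` presynapses; ineligible hemilineages still get
    entropies when computable (``eligible`` = False).
    """
    merged = calls.merge(
        neurons[["neuron_id", "hemilineage"]], on="neuron_id", how="left"
    )
    syn = synapses.merge(
        neurons[["neuron_id", "hemilineage"]], on="neuron_id", how="left"
    )
    rows = []
    for h, group in merged.dropna(subset=["hemilineage"]).groupby("hemilineage", sort=True):
        syn_h = syn[syn["hemilineage"] == h]
        syn_counts = syn_h.groupby("neuron_id").size()
        counted = syn_counts[syn_counts > ELIGIBLE_MIN_SYNAPSES]
        eligible = len(group) > ELIGIBLE_MIN_NEURONS and len(counted) == len(
            syn_counts
        ) and len(syn_counts) > 0
        n_uncertain = int((group["winner"] == UNCERTAIN).sum())
        usable = group.loc[group["winner"] != UNCERTAIN, "winner"]
        h_neuron = neuron_level_entropy(usable) if len(usable) else np.nan
        per_neuron = [
            g["pred_label"].tolist() for _, g in syn_h.groupby("neuron_id", sort=True)
        ]
        h_syn = hemilineage_synapse_entropy(per_neuron) if per_neuron else np.nan
        rows.append(
            {
                "hemilineage": h,
                "n_neurons": len(group),
                "n_uncertain": n_uncertain,
                "H_neuron": h_neuron,
                "H_synapse_mean": h_syn,
                "eligible": eligible,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "hemilineage",
            "n_neurons",
            "n_uncertain",
            "H_neuron",
            "H_synapse_mean",
            "eligible",
        ],
    )


def entropy_quadrants(
    entropies: pd.DataFrame,
) -> tuple[pd.DataFrame, dict[str, float]]:
    """Label hemilineages by quartile bands of H(N_h) and H(S_h).

    Quartiles (25th/75th, linear interpolation between order statistics) are
    computed over the supplied hemilineages. Labels, in precedence order:

    * ``synapse_multimodal``: H(S_h) >= q75(H(S_h)) — per-neuron prediction
      mixing dominates;
    * ``neuron_segregated``: H(N_h) >= q75(H(N_h)) and H(S_h) <= q25(H(S_h))
      — clean within-neuron predictions but split transmitters across neurons;
    * ``homogeneous``: both entropies <= their q25;
    * ``intermediate`` otherwise.

    Returns the annotated copy and the quartile dict.
    """
    df = entropies.dropna(subset=["H_neuron", "H_synapse_mean"])
    if len(df) < 4:
        raise ValueError(
            f"need at least 4 hemilineages for quartile bands, got {len(df)}"
        )
    q = {
        "q25_neuron": float(np.percentile(df["H_neuron"], 25)),
        "q75_neuron": float(np.percentile(df["H_neuron"], 75)),
        "q25_synapse": float(np.percentile(df["H_synapse_mean"], 25)),
        "q75_synapse": float(np.percentile(df["H_synapse_mean"], 75)),
    }

    def label(row) -> str:
        hn, hs = row["H_neuron"], row["H_synapse_mean"]
        # "high"/"low" require clearing both quartiles, so a degenerate
        # spread (q25 == q75) places everything in the middle band
        hs_high = hs >= q["q75_synapse"] and hs > q["q25_synapse"]
        hs_low = hs <= q["q25_synapse"] and hs < q["q75_synapse"]
        hn_high = hn >= q["q75_neuron"] and hn > q["q25_neuron"]
        hn_low = hn <= q["q25_neuron"] and hn < q["q75_neuron"]
        if hs_high:
            return "synapse_multimodal"
        if hn_high and hs_low:
            return "neuron_segregated"
        if hn_low and hs_low:
            return "homogeneous"
        return "intermediate"

    out = df.copy()
    out["quadrant"] = out.apply(label, axis=1)
    return out, q
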