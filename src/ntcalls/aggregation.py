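"""Presynapse filtering and neuron- / cell-type-level transmitter calls.

A neuron's transmitter is called by majority vote over its per-synapse
predictions, after removing presynapses that are likely detection errors:
low detection score, non-axonic/non-dendritic compartments, or locations too
close to the soma or primary dendrite. A call is "uncertain" when the vote is
close (top minus second fraction below 10 percentage points) or the neuron
has too few surviving presynapses.

The confidence of a non-uncertain call is the mean confusion-matrix entry,
in the winning transmitter's row, over the neuron's per-synapse predictions:
a synapse predicted as the winner contributes the winner's recall, a synapse
predicted as some other class contributes the (small) probability of that
misprediction under the winner's true identity.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd

from .confusion import ConfusionMatrix
from .labels import (
    LABEL_INDEX,
    N_TRANSMITTERS,
    TRANSMITTERS,
    UNCERTAIN,
)

__all__ = [
    "FilterPolicy",
    "FilterReport",
    "NeuronCall",
    "filter_synapses",
    "vote_fractions",
    "neuron_call",
    "neuron_confidence",
    "call_neurons",
    "celltype_call",
    "call_celltypes",
]

#: Margin below which a majority vote is declared uncertain (vote-fraction
#: difference between the top two transmitters; "<10%").
UNCERTAIN_MARGIN = 0.10


@dataclass(frozen=True)
class FilterPolicy:
    """Presynapse retention rules.

    Defaults follow the FAFB cleft-score dialect: detection score strictly
    above 50, axonic or dendritic compartment, at least 15 um from the soma
    and 0.1 um from the primary dendrite, and at least 100 surviving
    presynapses for a neuron to be called. ``min_presynapses=30`` is the
    test-set-style setting. ``strict`` rejects rows missing the optional
    compartment/distance columns instead of letting them pass those checks.
    """

    detection_threshold: float = 50.0
    allowed_compartments: frozenset[str] = frozenset({"axon", "dendrite"})
    min_dist_soma_um: float = 15.0
    min_dist_primary_dendrite_um: float = 0.1
    min_presynapses: int = 100
    strict: bool = False

    @classmethod
    def hemibrain(cls, **kw) -> "FilterPolicy":
        """HemiBrain dialect: detection confidence above 0.5."""
        kw.setdefault("detection_threshold", 0.5)
        return cls(**kw)


@dataclass
class FilterReport:
    """Per-rule removed-row ledger from one :func:`filter_synapses` run."""

    n_input: int = 0
    n_retained: int = 0
    removed: dict[str, int] = field(default_factory=dict)

    def __str__(self) -> str:
        parts = ", ".join(f"{rule}: {n}" for rule, n in self.removed.items())
        return f"{self.n_input} in, {self.n_retained} retained ({parts})"


@dataclass(frozen=True)
class NeuronCall:
    """A neuron's winning transmitter with vote fractions and confidence.

    ``winner`` is "uncertain" when the vote margin is below 10 percentage
    points, the top vote is tied, or fewer than ``min_presynapses`` synapses
    survive filtering; ``confidence`` is None in that case.
    """

    neuron_id: object
    fractions: np.ndarray
    winner: str
    margin: float
    n_synapses_used: int
    confidence: float | None = None

    @property
    def is_uncertain(self) -> bool:
        return self.winner == UNCERTAIN


def filter_synapses(
    synapses: pd.DataFrame, policy: FilterPolicy = FilterPolicy()
) -> tuple[pd.DataFrame, FilterReport]:
    """Apply the retention rules; report removals per rule.

    Rules are evaluated on the full table independently (a row violating two
    rules counts in both ledger entries); the retained set satisfies all.
    Rows lacking an optional column pass that column's check unless
    ``policy.strict``.
    """
    report = FilterReport(n_input=len(synapses))
    keep = np.ones(len(synapses), dtype=bool)

    def apply(rule: str, violates: np.ndarray) -> None:
        nonlocal keep
        report.removed[rule] = int(violates.sum())
        keep &= ~violates

    score = synapses["detection_score"].to_numpy(dtype=float)
    apply("detection_score", ~(score > policy.detection_threshold))

    if "compartment" in synapses.columns:
        comp = synapses["compartment"]
        bad = ~comp.isin(policy.allowed_compartments).to_numpy()
        missing = comp.isna().to_numpy()
        bad = np.where(missing, policy.strict, bad).astype(bool)
        apply("compartment", bad)
    elif policy.strict:
        apply("compartment", np.ones(len(synapses), dtype=bool))
    else:
        report.removed["compartment"] = 0

    for rule, col, lo in (
        ("dist_soma", "dist_soma_um", policy.min_dist_soma_um),
        (
            "dist_primary_dendrite",
            "dist_primary_dendrite_um",
            policy.min_dist_primary_dendrite_um,
        ),
    ):
        if col in synapses.columns:
            vals = synapses[col].to_numpy(dtype=float)
            bad = vals < lo  # inclusive retention: "no less than" -> >=
            missing = np.isnan(vals)
            bad = np.where(missing, policy.strict, bad)
            apply(rule, bad.astype(bool))
        elif policy.strict:
            apply(rule, np.ones(len(synapses), dtype=bool))
        else:
            report.removed[rule] = 0

    out = synapses.loc[keep].copy()
    report.n_retained = len(out)
    return out, report


def vote_fractions(labels) -> np.ndarray:
    """Empirical per-synapse label frequencies as a 6-vector on the simplex."""
    labels = list(labels)
    if len(labels) == 0:
        raise ValueError("cannot compute vote fractions with zero synapses")
    counts = np.zeros(N_TRANSMITTERS)
    for lab in labels:
        counts[LABEL_INDEX[lab]] += 1
    return counts / counts.sum()


def _winner_from_fractions(
    fractions: np.ndarray, n_used: int, min_presynapses: int
) -> tuple[str, float]:
    order = np.argsort(fractions)[::-1]
    top, second = fractions[order[0]], fractions[order[1]]
    margin = float(top - second)
    if n_used < min_presynapses or margin < UNCERTAIN_MARGIN:
        return UNCERTAIN, margin
    return TRANSMITTERS[order[0]], margin


def neuron_call(
    labels, neuron_id=None, policy: FilterPolicy = FilterPolicy()
) -> NeuronCall:
    """Majority-vote call for one neuron's (already filtered) synapse labels.

    Exact ties in the top vote give a zero margin and hence "uncertain".
    """
    fractions = vote_fractions(labels)
    n_used = len(list(labels))
    winner, margin = _winner_from_fractions(fractions, n_used, policy.min_presynapses)
    return NeuronCall(
        neuron_id=neuron_id,
        fractions=fractions,
        winner=winner,
        margin=margin,
        n_synapses_used=n_used,
    )


def neuron_confidence(call: NeuronCall, labels, C: ConfusionMatrix) -> float:
    """Mean confusion-matrix entry in the winner's row over per-synapse labels.

    Equivalently the dot product of the winner's row of C with the neuron's
    vote fractions.
    """
    if call.is_uncertain:
        raise ValueError("no confidence is defined for an uncertain call")
    row = C.C[LABEL_INDEX[call.winner]]
    idx = [LABEL_INDEX[lab] for lab in labels]
    if len(idx) == 0:
        raise ValueError("cannot compute confidence with zero synapses")
    return float(np.mean(row[idx]))


def call_neurons(
    synapses: pd.DataFrame,
    C: ConfusionMatrix | None = None,
    policy: FilterPolicy = FilterPolicy(),
) -> pd.DataFrame:
    """Call every neuron in a filtered synapse table.

    Returns one row per neuron: winner (``conf_nt`` column naming is applied
    by the I/O layer), vote fractions, margin, confidence (NaN if uncertain
    or no confusion matrix given) and ``n_synapses_used``.
    """
    rows = []
    for nid, group in synapses.groupby("neuron_id", sort=True):
        labels = group["pred_label"].tolist()
        call = neuron_call(labels, neuron_id=nid, policy=policy)
        conf = np.nan
        if C is not None and not call.is_uncertain:
            conf = neuron_confidence(call, labels, C)
        rec = {
            "neuron_id": nid,
            "winner": call.winner,
            "margin": call.margin,
            "confidence": conf,
            "n_synapses_used": call.n_synapses_used,
        }
        for t, frac in zip(TRANSMITTERS, call.fractions):
            rec[f"frac_{t}"] = frac
        rows.append(rec)
    columns = (
        ["neuron_id", "winner", "margin", "confidence", "n_synapses_used"]
        + [f"frac_{t}" for t in TRANSMITTERS]
    )
    return pd.DataFrame(rows, columns=columns)


def celltype_call(winners) -> tuple[str, bool, int]:
    """Modal transmitter over a cell type's member-neuron calls.

    Returns ``(winner, conflicted, n_used)``. "uncertain" members are
    excluded from the mode; the type is conflicted when two or more distinct
    non-uncertain calls occur; a modal tie yields "uncertain".
    """
    usable = [w for w in winners if w != UNCERTAIN]
    if not usable:
        return UNCERTAIN, False, 0
    counts: dict[str, int] = {}
    for w in usable:
        counts[w] = counts.get(w, 0) + 1
    best = max(counts.values())
    modal = [t for t in TRANSMITTERS if counts.get(t, 0) == best]
    winner = modal[0] if len(modal) == 1 else UNCERTAIN
    return winner, len(counts) > 1, len(usable)


def call_celltypes(calls: pd.DataFrame, neurons: pd.DataFrame) -> pd.DataFrame:
    """Aggregate neuron calls to cell types (modal call + conflict flag)."""
    merged = calls.merge(
        neurons[["neuron_id", "cell_type"]], on="neuron_id", how="left"
    )
    rows = []
    for ct, group in merged.dropna(subset=["cell_type"]).groupby("cell_type", sort=True):
        winner, conflicted, n_used = celltype_call(group["winner"])
        conf = group.loc[group["winner"] != UNCERTAIN, "confidence"]
        rows.append(
            {
                "cell_type": ct,
                "winner": winner,
                "conflicted": conflicted,
                "n_neurons": len(group),
                "n_used": n_used,
                "mean_confidence": float(conf.mean()) if len(conf) else np.nan,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["cell_type", "winner", "conflicted", "n_neurons", "n_used", "mean_confidence"],
    )
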