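"""Cross-hemisphere / cross-dataset consistency of neuron-level calls.

Isomorphic cell types with a single neuron per hemisphere ("singletons") can
be matched unambiguously to their homolog on the other hemisphere or in a
second animal's connectome. Agreement between the two members of each
matched pair measures prediction consistency without any ground truth:

* an agreement (confusion-style) matrix of call_a vs call_b counts, plus a
  row-normalized view;
* Kullback-Leibler divergence between the two members' 6-class synapse-level
  distributions (mean score vectors when scores exist, else label
  frequencies with a pseudo-count of 1), natural log; a symmetrized variant
  is the default in reports since the pair order is a convention;
* a match/mismatch summary with confidence statistics per group — mismatched
  pairs are expected to carry systematically lower confidence.
"""

from __future__ import annotations

import numpy as np
import pandas as pd

from .labels import (
    LABEL_INDEX,
    N_TRANSMITTERS,
    SCORE_COLUMNS,
    TRANSMITTERS,
    UNCERTAIN,
)

__all__ = [
    "pair_agreement_matrix",
    "kl_divergence",
    "kl_similarity",
    "synapse_distribution",
    "pair_report",
    "mismatch_summary",
]

_LABELS_PLUS = tuple(TRANSMITTERS) + (UNCERTAIN,)


class MissingCallError(KeyError):
    """A homolog pair references a neuron without a call."""


def pair_agreement_matrix(
    pairs: pd.DataFrame, calls: pd.DataFrame
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Counts of (call_a, call_b) over homolog pairs, plus a row-normalized view.

    Rows index the first member's call, columns the second's; an extra
    "uncertain" row/column holds pairs with an uncertain member. Rows with no
    observations are left as zero (NaN in the normalized view).
    """
    call_of = calls.set_index("neuron_id")["winner"]
    missing = [
        nid
        for nid in pd.concat([pairs["neuron_a"], pairs["neuron_b"]])
        if nid not in call_of.index
    ]
    if missing:
        raise MissingCallError(f"no call for neuron id(s): {sorted(set(missing))}")
    M = pd.DataFrame(
        np.zeros((len(_LABELS_PLUS), len(_LABELS_PLUS)), dtype=int),
        index=list(_LABELS_PLUS),
        columns=list(_LABELS_PLUS),
    )
    for a, b in zip(pairs["neuron_a"], pairs["neuron_b"]):
        M.loc[call_of[a], call_of[b]] += 1
    totals = M.sum(axis=1)
    with np.errstate(invalid="ignore", divide="ignore"):
        norm = M.div(totals.replace(0, np.nan), axis=0)
    return M, norm


def synapse_distribution(synapses: pd.DataFrame) -> np.ndarray:
    """One neuron's 6-class synapse-level distribution.

    The mean per-synapse score vector when score columns are present;
    otherwise label frequencies with a pseudo-count of 1 per class (so the
    result has full support and KL is always finite).
    """
    if len(synapses) == 0:
        raise ValueError("need at least one synapse")
    if all(c in synapses.columns for c in SCORE_COLUMNS):
        scores = synapses[list(SCORE_COLUMNS)].to_numpy(dtype=float)
        p = scores.mean(axis=0)
        return p / p.sum()
    counts = np.ones(N_TRANSMITTERS)  # pseudo-count
    for lab in synapses["pred_label"]:
        counts[LABEL_INDEX[lab]] += 1
    return counts / counts.sum()


def kl_divergence(p: np.ndarray, q: np.ndarray, smooth: float = 1e-9) -> float:
    """KL(p || q) in nats between two 6-class distributions.

    Zero-support target classes would make the divergence infinite; a tiny
    uniform smoothing is applied to ``q`` (and ``p`` for symmetry of
    treatment) only when needed, keeping exact inputs exact.
    """
    p = np.asarray(p, dtype=float)
    q = np.asarray(q, dtype=float)
    if np.any((q == 0) & (p > 0)):
        p = (p + smooth) / (1 + N_TRANSMITTERS * smooth)
        q = (q + smooth) / (1 + N_TRANSMITTERS * smooth)
    mask = p > 0
    return float(np.sum(p[mask] * np.log(p[mask] / q[mask])))


def kl_similarity(p: np.ndarray, q: np.ndarray, symmetrized: bool = True) -> float:
    """Similarity score between two synapse-level distributions.

    Default is the symmetrized divergence (KL(p||q) + KL(q||p)) / 2; pass
    ``symmetrized=False`` for the directed KL(p || q).
    """
    if symmetrized:
        return 0.5 * (kl_divergence(p, q) + kl_divergence(q, p))
    return kl_divergence(p, q)


def pair_report(
    pairs: pd.DataFrame,
    calls: pd.DataFrame,
    synapses: pd.DataFrame | None = None,
) -> pd.DataFrame:
    """Per-pair table: calls, match flag, confidences, KL similarity.

    ``match`` is NaN when either member is uncertain. KL columns are NaN
    when no synapse table is given or a member has no synapses.
    """
    call_df = calls.set_index("neuron_id")
    rows = []
    syn_groups = (
        dict(tuple(synapses.groupby("neuron_id"))) if synapses is not None else {}
    )
    for _, pr in pairs.iterrows():
        a, b = pr["neuron_a"], pr["neuron_b"]
        if a not in call_df.index or b not in call_df.index:
            raise MissingCallError(f"no call for pair ({a!r}, {b!r})")
        ca, cb = call_df.loc[a, "winner"], call_df.loc[b, "winner"]
        match = np.nan
        if ca != UNCERTAIN and cb != UNCERTAIN:
            match = bool(ca == cb)
        kl = kl_sym = np.nan
        if a in syn_groups and b in syn_groups:
            pa = synapse_distribution(syn_groups[a])
            pb = synapse_distribution(syn_groups[b])
            kl = kl_similarity(pa, pb, symmetrized=False)
            kl_sym = kl_similarity(pa, pb, symmetrized=True)
        rows.append(
            {
                "neuron_a": a,
                "neuron_b": b,
                "relation": pr.get("relation", "left_right"),
                "call_a": ca,
                "call_b": cb,
                "match": match,
                "confidence_a": call_df.loc[a, "confidence"],
                "confidence_b": call_df.loc[b, "confidence"],
                "kl": kl,
                "kl_sym": kl_sym,
            }
        )
    return pd.DataFrame(
        rows,
        columns=[
            "neuron_a",
            "neuron_b",
            "relation",
            "call_a",
            "call_b",
            "match",
            "confidence_a",
            "confidence_b",
            "kl",
            "kl_sym",
        ],
    )


def mismatch_summary(report: pd.DataFrame) -> pd.DataFrame:
    """Match/mismatch counts and confidence statistics per relation.

    Confidence statistics pool both members of each pair; the "n_match :
    n_mismatch" column follows the conventional compact format.
    """
    rows = []
    for rel, group in report.groupby("relation", sort=True):
        scored = group.dropna(subset=["match"])
        for flag, name in ((True, "match"), (False, "mismatch")):
            sub = scored[scored["match"] == flag]
            confs = pd.concat([sub["confidence_a"], sub["confidence_b"]]).dropna()
            rows.append(
                {
                    "relation": rel,
                    "group": name,
                    "n_pairs": len(sub),
                    "mean_confidence": float(confs.mean()) if len(confs) else np.nan,
                    "sd_confidence": float(confs.std(ddof=1)) if len(confs) > 1 else np.nan,
                    "ratio": f"{int(scored['match'].sum())}:{int((~scored['match'].astype(bool)).sum())}",
                }
            )
    return pd.DataFrame(
        rows,
        columns=["relation", "group", "n_pairs", "mean_confidence", "sd_confidence", "ratio"],
    )
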