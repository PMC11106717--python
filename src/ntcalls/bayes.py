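"""Bayes-factor inference of how many transmitters a hemilineage expresses.

Model: every neuron of a hemilineage has one true transmitter drawn uniformly
from an unknown subset S of the six classes, |S| = m; the observed winner of
neuron j is then a draw from the confusion-matrix row of its true
transmitter, independently across neurons. Marginalizing the subset under a
flat prior over the C(6, m) subsets of size m gives

    p(yhat | m) = C(6,m)^-1  sum_{S, |S|=m}  prod_j ( sum_{y in S} C[y, yhat_j] / m ).

Competing transmitter counts m1, m2 are compared by the Bayes factor
K_{m1,m2} = p(yhat|m1) / p(yhat|m2); the overall summary is the one-vs-rest
factor K_{m,-m} = p(yhat|m) / sum_{n != m} p(yhat|n), classified on the
Jeffreys-style scale (substantial K >= 10^1/2, good >= 10, strong >= 10^3/2,
decisive >= 10^2).

To avoid trusting finite-test-set error rates literally, C is replaced
entrywise by its expectation under the additive-smoothing prior
(:func:`ntcalls.confusion.expected_confusion`) before evaluating the
likelihood. All accumulation is in natural-log space (per-neuron log terms,
log-sum-exp over subsets) so hemilineages of a thousand neurons do not
underflow.
"""

from __future__ import annotations

from dataclasses import dataclass
from itertools import combinations
from math import comb

import numpy as np
import pandas as pd
from scipy.special import logsumexp

from .confusion import ConfusionMatrix, SmoothingPrior, expected_confusion
from .labels import LABEL_INDEX, N_TRANSMITTERS, TRANSMITTERS, UNCERTAIN

__all__ = [
    "BayesResult",
    "EVIDENCE_THRESHOLDS",
    "log_marginal_likelihood",
    "pairwise_bayes_factor",
    "one_vs_rest",
    "classify_evidence",
    "rank_transmitters",
    "analyze_hemilineage",
    "analyze_hemilineages",
]

_K = N_TRANSMITTERS

#: Evidence scale: class name -> inclusive lower bound on K.
EVIDENCE_THRESHOLDS: tuple[tuple[str, float], ...] = (
    ("decisive", 10.0**2),
    ("strong", 10.0**1.5),
    ("good", 10.0**1),
    ("substantial", 10.0**0.5),
)


@dataclass(frozen=True)
class BayesResult:
    """Full hemilineage inference: marginals, Bayes factors, evidence class."""

    hemilineage_id: object
    n_neurons: int
    log_marginal: np.ndarray  # log p(yhat | m), m = 1..6
    pairwise_K: np.ndarray  # K[m1-1, m2-1]
    one_vs_rest_K: np.ndarray  # K_{m,-m}, m = 1..6
    best_m: int
    best_evidence: str
    ranked_transmitters: tuple[str, ...]
    ranked_counts: tuple[int, ...]
    rank_ties: bool
    n_uncertain_dropped: int


def _winner_counts(winners) -> np.ndarray:
    counts = np.zeros(_K, dtype=np.int64)
    for w in winners:
        counts[LABEL_INDEX[w]] += 1
    return counts


def log_marginal_likelihood(
    winners, C_eff: ConfusionMatrix, m: int
) -> float:
    """log p(yhat | m) for observed winners under the subset-mixture model.

    Because the likelihood depends on the winners only through their counts,
    each size-m subset S contributes

        sum_yhat  n_yhat * log( sum_{y in S} C[y, yhat] / m ),

    and subsets combine by log-sum-exp with the flat 1/C(6,m) subset prior.
    Returns -inf when every subset assigns probability zero to some observed
    winner.
    """
    if not (1 <= m <= _K):
        raise ValueError(f"m must be in 1..{_K}, got {m}")
    counts = _winner_counts(winners)
    n = int(counts.sum())
    if n == 0:
        raise ValueError("need at least one winner")
    C = C_eff.C
    subset_logs = []
    for S in combinations(range(_K), m):
        q = C[list(S), :].sum(axis=0) / m  # mixture row over the subset
        observed = counts > 0
        with np.errstate(divide="ignore"):
            logq = np.log(q[observed])
        # counts == 0 entries contribute 0 even when their logq = -inf
        subset_logs.append((counts[observed] * logq).sum())
    return float(logsumexp(subset_logs) - np.log(comb(_K, m)))


def pairwise_bayes_factor(
    winners, C_eff: ConfusionMatrix, m1: int, m2: int
) -> float:
    """K_{m1,m2} = p(yhat|m1) / p(yhat|m2); +inf when only m2 is impossible."""
    l1 = log_marginal_likelihood(winners, C_eff, m1)
    l2 = log_marginal_likelihood(winners, C_eff, m2)
    if np.isneginf(l1) and np.isneginf(l2):
        raise ValueError(
            f"both models m={m1} and m={m2} assign zero probability; "
            "the Bayes factor is undefined"
        )
    if np.isneginf(l2):
        return float("inf")
    return float(np.exp(l1 - l2))


def one_vs_rest(winners, C_eff: ConfusionMatrix, m: int) -> float:
    """K_{m,-m}: marginal of m against the summed marginals of all other m."""
    logs = np.array(
        [log_marginal_likelihood(winners, C_eff, k) for k in range(1, _K + 1)]
    )
    return _one_vs_rest_from_logs(logs, m)


def _one_vs_rest_from_logs(logs: np.ndarray, m: int) -> float:
    rest = np.delete(logs, m - 1)
    log_rest = logsumexp(rest)
    if np.isneginf(log_rest):
        return float("inf") if np.isfinite(logs[m - 1]) else float("nan")
    return float(np.exp(logs[m - 1] - log_rest))


def classify_evidence(K: float) -> str:
    """Evidence class for a Bayes factor on the Jeffreys-style scale."""
    if np.isnan(K) or K < 0:
        raise ValueError(f"Bayes factor must be non-negative, got {K}")
    for name, lo in EVIDENCE_THRESHOLDS:
        if K >= lo:
            return name
    return "none"


def rank_transmitters(winners) -> tuple[tuple[str, ...], tuple[int, ...], bool]:
    """Labels sorted by descending winner frequency.

    Ties are broken by canonical label order and flagged. Returns
    ``(labels, counts, had_ties)``; only labels that occur are listed.
    """
    counts = _winner_counts(winners)
    if counts.sum() == 0:
        raise ValueError("need at least one non-uncertain winner to rank")
    order = sorted(range(_K), key=lambda i: (-counts[i], i))
    order = [i for i in order if counts[i] > 0]
    ranked = tuple(TRANSMITTERS[i] for i in order)
    ranked_counts = tuple(int(counts[i]) for i in order)
    ties = len(set(ranked_counts)) < len(ranked_counts)
    return ranked, ranked_counts, ties


def analyze_hemilineage(
    winners,
    C: ConfusionMatrix,
    prior: SmoothingPrior,
    hemilineage_id=None,
    C_eff: ConfusionMatrix | None = None,
) -> BayesResult:
    """Full Bayes analysis of one hemilineage's neuron-level winners.

    "uncertain" winners are dropped (they are outside the label space);
    at least one usable winner is required. ``C_eff`` may be supplied to
    reuse a precomputed expected confusion matrix across hemilineages.
    """
    winners = list(winners)
    usable = [w for w in winners if w != UNCERTAIN]
    n_dropped = len(winners) - len(usable)
    if not usable:
        raise ValueError(
            f"hemilineage {hemilineage_id!r} has no usable (non-uncertain) calls"
        )
    if C_eff is None:
        C_eff = expected_confusion(C, prior)
    logs = np.array(
        [log_marginal_likelihood(usable, C_eff, m) for m in range(1, _K + 1)]
    )
    with np.errstate(over="ignore", invalid="ignore"):
        pairwise = np.exp(logs[:, None] - logs[None, :])
    ovr = np.array([_one_vs_rest_from_logs(logs, m) for m in range(1, _K + 1)])
    best_m = int(np.argmax(ovr) + 1)
    ranked, ranked_counts, ties = rank_transmitters(usable)
    return BayesResult(
        hemilineage_id=hemilineage_id,
        n_neurons=len(usable),
        log_marginal=logs,
        pairwise_K=pairwise,
        one_vs_rest_K=ovr,
        best_m=best_m,
        best_evidence=classify_evidence(float(ovr[best_m - 1])),
        ranked_transmitters=ranked,
        ranked_counts=ranked_counts,
        rank_ties=ties,
        n_uncertain_dropped=n_dropped,
    )


def analyze_hemilineages(
    calls: pd.DataFrame,
    neurons: pd.DataFrame,
    C: ConfusionMatrix,
    prior: SmoothingPrior,
) -> pd.DataFrame:
    """Run :func:`analyze_hemilineage` for every hemilineage in a call table.

    Hemilineages with no usable calls are skipped. The expected confusion
    matrix is computed once and shared.
    """
    C_eff = expected_confusion(C, prior)
    merged = calls.merge(
        neurons[["neuron_id", "hemilineage"]], on="neuron_id", how="left"
    )
    rows = []
    for h, group in merged.dropna(subset=["hemilineage"]).groupby("hemilineage", sort=True):
        usable = group.loc[group["winner"] != UNCERTAIN, "winner"]
        if len(usable) == 0:
            continue
        res = analyze_hemilineage(
            group["winner"], C, prior, hemilineage_id=h, C_eff=C_eff
        )
        rec = {
            "hemilineage": h,
            "n_neurons": res.n_neurons,
            "n_uncertain_dropped": res.n_uncertain_dropped,
            "best_m": res.best_m,
            "evidence": res.best_evidence,
            "ranked_transmitters": ";".join(res.ranked_transmitters),
            "lambda": prior.lambda_rate,
            "epsilon": prior.epsilon,
        }
        for m in range(1, _K + 1):
            rec[f"logp_m{m}"] = res.log_marginal[m - 1]
        for m in range(1, _K + 1):
            rec[f"K_{m}vr"] = res.one_vs_rest_K[m - 1]
        rows.append(rec)
    columns = (
        ["hemilineage", "n_neurons", "n_uncertain_dropped", "best_m", "evidence", "ranked_transmitters", "lambda", "epsilon"]
        + [f"logp_m{m}" for m in range(1, _K + 1)]
        + [f"K_{m}vr" for m in range(1, _K + 1)]
    )
    return pd.DataFrame(rows, columns=columns)
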