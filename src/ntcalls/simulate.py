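"""Synthetic classifier-output studies for end-to-end pipeline testing.

The generator emits the same tabular structure the pipeline consumes —
per-synapse predictions plus neuron metadata — with the statistical features
the analysis assumes:

* each neuron has one true transmitter; its per-synapse predicted labels are
  i.i.d. draws from the corresponding confusion-matrix row;
* hemilineages express 1-3 true transmitters, with neuron proportions per
  transmitter (optionally a single "first-born deviant" neuron);
* synapse counts per neuron are heavy-tailed (lognormal parameterized by
  median and log-SD, so the observed medians — 202 for the FAFB dialect, 386
  for HemiBrain — are direct inputs);
* a configurable fraction of emitted presynapses are false detections
  (default 32%, matching human-validated error rates for auto-detected
  presynapses); true and false detections draw detection scores from two
  truncated-normal mixtures calibrated so the standard score-50 cut removes
  about 13% of true and 60% of false detections;
* compartments and distance fields exercise every filter rule: true synapses
  sit on axons (share 0.76) or dendrites at legal distances, false ones
  preferentially violate compartment and distance rules.

Everything is driven by one integer seed; per-stage substreams are derived
deterministically, so identical configs give byte-identical tables.
"""

from __future__ import annotations

from dataclasses import dataclass, field

import numpy as np
import pandas as pd
from scipy.stats import truncnorm

from .confusion import ConfusionMatrix, diagonal_confusion
from .labels import LABEL_INDEX, N_TRANSMITTERS, TRANSMITTERS

__all__ = [
    "ScoreMixture",
    "SimConfig",
    "GroundTruth",
    "sample_synapse_labels",
    "sample_detection_scores",
    "simulate_study",
]


@dataclass(frozen=True)
class ScoreMixture:
    """Detection-score model: truncated normals for true and false detections.

    FAFB cleft-score dialect on [0, 250]. Defaults place 13.2% of true and
    60.1% of false detections at or below the standard threshold of 50.
    """

    true_mean: float = 95.0
    true_sd: float = 42.0
    false_mean: float = 30.0
    false_sd: float = 40.0
    lo: float = 0.0
    hi: float = 250.0

    def sample(self, is_false: np.ndarray, rng: np.random.Generator) -> np.ndarray:
        n = len(is_false)
        out = np.empty(n)
        for flag, mu, sd in (
            (False, self.true_mean, self.true_sd),
            (True, self.false_mean, self.false_sd),
        ):
            mask = is_false == flag
            k = int(mask.sum())
            if k == 0:
                continue
            a, b = (self.lo - mu) / sd, (self.hi - mu) / sd
            out[mask] = truncnorm.rvs(a, b, loc=mu, scale=sd, size=k, random_state=rng)
        return out


#: Default mixture over m_true in {1, 2, 3}: most hemilineages express a
#: single fast-acting transmitter, a minority two, very few three.
DEFAULT_M_PROBS: tuple[float, ...] = (0.88, 0.10, 0.02)

#: Neuron-share splits among a hemilineage's true transmitters, by m_true.
DEFAULT_SPLITS: dict[int, tuple[float, ...]] = {
    1: (1.0,),
    2: (0.7, 0.3),
    3: (0.6, 0.3, 0.1),
}


@dataclass(frozen=True)
class SimConfig:
    """Parameterization of one synthetic study.

    ``m_probs`` draws each hemilineage's number of true transmitters;
    ``splits`` fixes the neuron shares per transmitter. ``median_synapses``
    and ``synapse_log_sd`` parameterize the lognormal synapse-count law
    (median 202 mirrors the FAFB dialect; log-SD 0.9 gives the heavy tail).
    ``false_detection_rate`` 0.32 reproduces the validated error rate of
    auto-detected presynapses. ``axon_share`` 0.76 is the typical axonal
    share of presynapses. ``first_born_deviant`` makes the first neuron of
    each hemilineage express a transmitter outside the hemilineage's set.
    ``homolog_pairs`` emits a mirrored left-hemisphere copy of every neuron
    with independently resampled synapses.
    """

    seed: int
    n_hemilineages: int = 12
    neurons_per_hemilineage: int = 30
    m_probs: tuple[float, ...] = DEFAULT_M_PROBS
    splits: dict[int, tuple[float, ...]] = field(
        default_factory=lambda: dict(DEFAULT_SPLITS)
    )
    median_synapses: float = 202.0
    synapse_log_sd: float = 0.9
    min_synapses: int = 1
    C_syn: ConfusionMatrix = field(
        default_factory=lambda: diagonal_confusion(0.87, level="synapse")
    )
    false_detection_rate: float = 0.32
    score_mixture: ScoreMixture = ScoreMixture()
    contamination_probs: tuple[float, ...] = tuple([1.0 / N_TRANSMITTERS] * N_TRANSMITTERS)
    axon_share: float = 0.76
    first_born_deviant: bool = False
    homolog_pairs: bool = False
    emit_scores: bool = False
    cell_types_per_hemilineage: int = 5
    dataset: str = "synthetic"

    def __post_init__(self) -> None:
        if not np.isclose(sum(self.m_probs), 1.0):
            raise ValueError("m_probs must sum to 1")
        if not (0 <= self.false_detection_rate <= 1):
            raise ValueError("false_detection_rate must be in [0, 1]")
        if not np.isclose(sum(self.contamination_probs), 1.0):
            raise ValueError("contamination_probs must sum to 1")
        for m, split in self.splits.items():
            if not np.isclose(sum(split), 1.0):
                raise ValueError(f"split for m={m} must sum to 1")
            if len(split) != m:
                raise ValueError(f"split for m={m} must have {m} entries")


@dataclass(frozen=True)
class GroundTruth:
    """What the generator actually did, keyed to the emitted tables."""

    neuron_truth: pd.DataFrame  # neuron_id, true_transmitter, hemilineage
    synapse_truth: pd.DataFrame  # synapse_id, is_false_detection
    hemilineage_truth: pd.DataFrame  # hemilineage, m_true, transmitters


def sample_synapse_labels(
    true_label: str, n: int, C_syn: ConfusionMatrix, rng: np.random.Generator
) -> list[str]:
    """n i.i.d. predicted labels from the true transmitter's confusion row."""
    row = C_syn.C[LABEL_INDEX[true_label]]
    idx = rng.choice(N_TRANSMITTERS, size=n, p=row)
    return [TRANSMITTERS[i] for i in idx]


def sample_detection_scores(
    is_false: np.ndarray,
    mixture: ScoreMixture,
    rng: np.random.Generator,
) -> np.ndarray:
    """Detection scores from the true/false truncated-normal mixture."""
    return mixture.sample(np.asarray(is_false, dtype=bool), rng)


def _spawn(seed: int, *key: int) -> np.random.Generator:
    """Deterministic per-stage substream derived from the study seed."""
    return np.random.default_rng(np.random.SeedSequence(entropy=seed, spawn_key=key))


def _assign_transmitters(
    cfg: SimConfig, rng: np.random.Generator
) -> tuple[list[dict], list[dict]]:
    """Pick each hemilineage's transmitter set and per-neuron truths."""
    hl_rows, neuron_specs = [], []
    for h in range(cfg.n_hemilineages):
        m = int(rng.choice(len(cfg.m_probs), p=np.asarray(cfg.m_probs)) + 1)
        transmitters = [
            TRANSMITTERS[i]
            for i in rng.choice(N_TRANSMITTERS, size=m, replace=False)
        ]
        split = cfg.splits[m]
        n = cfg.neurons_per_hemilineage
        # deterministic largest-remainder allocation of neurons to transmitters
        raw = np.array(split) * n
        alloc = np.floor(raw).astype(int)
        for i in np.argsort(-(raw - alloc))[: n - alloc.sum()]:
            alloc[i] += 1
        truths: list[str] = []
        for t, k in zip(transmitters, alloc):
            truths.extend([t] * int(k))
        if cfg.first_born_deviant and n > 1:
            others = [t for t in TRANSMITTERS if t not in transmitters]
            if others:
                truths[0] = others[int(rng.integers(len(others)))]
        hl_id = f"hl{h:03d}"
        hl_rows.append(
            {
                "hemilineage": hl_id,
                "m_true": m,
                "transmitters": ";".join(transmitters),
            }
        )
        for j, t in enumerate(truths):
            neuron_specs.append(
                {"hemilineage": hl_id, "index": j, "true_transmitter": t}
            )
    return hl_rows, neuron_specs


def simulate_study(
    config: SimConfig,
) -> tuple[pd.DataFrame, pd.DataFrame, GroundTruth]:
    """Generate one synthetic study: (synapse table, neuron table, ground truth)."""
    cfg = config
    rng_structure = _spawn(cfg.seed, 1)
    rng_counts = _spawn(cfg.seed, 2)
    rng_labels = _spawn(cfg.seed, 3)
    rng_scores = _spawn(cfg.seed, 4)
    rng_fields = _spawn(cfg.seed, 5)

    hl_rows, neuron_specs = _assign_transmitters(cfg, rng_structure)

    if cfg.false_detection_rate >= 1.0:
        raise ValueError("false_detection_rate must be < 1 for a finite table")

    sides = ["right", "left"] if cfg.homolog_pairs else ["right"]
    neuron_rows = []
    neuron_truth_rows = []
    cols: dict[str, list[np.ndarray]] = {
        "neuron_id": [],
        "pred_label": [],
        "detection_score": [],
        "compartment": [],
        "dist_soma_um": [],
        "dist_primary_dendrite_um": [],
        "is_false": [],
    }
    for spec in neuron_specs:
        base_id = f"{spec['hemilineage']}_n{spec['index']:03d}"
        cell_type = (
            f"{spec['hemilineage']}_ct{spec['index'] % cfg.cell_types_per_hemilineage}"
        )
        for side in sides:
            nid = f"{base_id}_{side[0]}"
            homolog = (
                f"{base_id}_{'l' if side == 'right' else 'r'}"
                if cfg.homolog_pairs
                else ""
            )
            neuron_rows.append(
                {
                    "neuron_id": nid,
                    "hemilineage": spec["hemilineage"],
                    "cell_type": cell_type,
                    "side": side,
                    "dataset": cfg.dataset,
                    "homolog_id": homolog,
                }
            )
            neuron_truth_rows.append(
                {
                    "neuron_id": nid,
                    "true_transmitter": spec["true_transmitter"],
                    "hemilineage": spec["hemilineage"],
                }
            )
            n_true = max(
                cfg.min_synapses,
                int(
                    np.round(
                        rng_counts.lognormal(
                            mean=np.log(cfg.median_synapses), sigma=cfg.synapse_log_sd
                        )
                    )
                ),
            )
            # false detections contaminate the table at the configured share
            r = cfg.false_detection_rate
            n_false = int(np.round(n_true * r / (1.0 - r))) if r > 0 else 0
            row_p = cfg.C_syn.C[LABEL_INDEX[spec["true_transmitter"]]]
            idx_true = rng_labels.choice(N_TRANSMITTERS, size=n_true, p=row_p)
            idx_false = rng_labels.choice(
                N_TRANSMITTERS, size=n_false, p=np.asarray(cfg.contamination_probs)
            )
            label_idx = np.concatenate([idx_true, idx_false]).astype(int)
            is_false = np.zeros(n_true + n_false, dtype=bool)
            is_false[n_true:] = True
            scores = sample_detection_scores(is_false, cfg.score_mixture, rng_scores)

            n_all = n_true + n_false
            compartment = np.where(
                rng_fields.random(n_all) < cfg.axon_share, "axon", "dendrite"
            ).astype(object)
            # false detections land disproportionately on non-synaptic cable
            bad_comp = is_false & (rng_fields.random(n_all) < 0.4)
            compartment[bad_comp] = rng_fields.choice(
                ["soma", "primary_dendrite", "cell_body_fiber"], size=int(bad_comp.sum())
            )
            dist_soma = rng_fields.uniform(20.0, 150.0, size=n_all)
            dist_pd = rng_fields.uniform(0.5, 30.0, size=n_all)
            near_soma = is_false & (rng_fields.random(n_all) < 0.15)
            dist_soma[near_soma] = rng_fields.uniform(0.0, 15.0, size=int(near_soma.sum()))
            near_pd = is_false & (rng_fields.random(n_all) < 0.15)
            dist_pd[near_pd] = rng_fields.uniform(0.0, 0.1, size=int(near_pd.sum()))

            cols["neuron_id"].append(np.full(n_all, nid, dtype=object))
            cols["pred_label"].append(label_idx)
            cols["detection_score"].append(scores)
            cols["compartment"].append(compartment)
            cols["dist_soma_um"].append(dist_soma)
            cols["dist_primary_dendrite_um"].append(dist_pd)
            cols["is_false"].append(is_false)

    label_arr = np.concatenate(cols["pred_label"]) if cols["pred_label"] else np.array([], int)
    n_total = len(label_arr)
    synapse_ids = np.array([f"s{i:08d}" for i in range(n_total)], dtype=object)
    labels_named = np.array(TRANSMITTERS, dtype=object)[label_arr]
    synapses = pd.DataFrame(
        {
            "synapse_id": synapse_ids,
            "neuron_id": np.concatenate(cols["neuron_id"]) if n_total else np.array([], object),
            "pred_label": labels_named,
            "detection_score": np.concatenate(cols["detection_score"]) if n_total else np.array([]),
            "compartment": np.concatenate(cols["compartment"]) if n_total else np.array([], object),
            "dist_soma_um": np.concatenate(cols["dist_soma_um"]) if n_total else np.array([]),
            "dist_primary_dendrite_um": np.concatenate(cols["dist_primary_dendrite_um"]) if n_total else np.array([]),
        }
    )
    if cfg.emit_scores:
        base = np.full((n_total, N_TRANSMITTERS), 0.02)
        base[np.arange(n_total), label_arr] = 1.0
        base /= base.sum(axis=1, keepdims=True)
        for j, t in enumerate(TRANSMITTERS):
            synapses[f"score_{t}"] = base[:, j]
    is_false_all = (
        np.concatenate(cols["is_false"]) if n_total else np.array([], bool)
    )
    neurons = pd.DataFrame(neuron_rows)
    truth = GroundTruth(
        neuron_truth=pd.DataFrame(neuron_truth_rows),
        synapse_truth=pd.DataFrame(
            {"synapse_id": synapse_ids, "is_false_detection": is_false_all}
        ),
        hemilineage_truth=pd.DataFrame(hl_rows),
    )
    return synapses, neurons, truth
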