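"""Table schemas, readers/writers, run configuration, and the pipeline driver.

Interchange format is CSV (UTF-8, header row); Feather is accepted as an
optional columnar dialect when pyarrow is installed. Labels are normalized to
the canonical vocabulary on load, score vectors (when present) are projected
onto the simplex, and schema violations raise errors naming the offending
column or labels.

Per-neuron output follows the released-data convention of two call columns:
``top_nt`` — the majority vote after the detection-score threshold only —
and ``conf_nt`` — the vote after full filtering (compartment and distance
rules). The two differ for a small fraction of neurons; both are reported.
"""

from __future__ import annotations

import json
import logging
from dataclasses import asdict, dataclass, field
from pathlib import Path

import numpy as np
import pandas as pd
import yaml

from .aggregation import FilterPolicy, call_celltypes, call_neurons, filter_synapses
from .bayes import analyze_hemilineages
from .confusion import ConfusionMatrix, SmoothingPrior
from .consistency import mismatch_summary, pair_report
from .entropy import entropy_quadrants, hemilineage_entropies
from .labels import (
    COMPARTMENTS,
    SCORE_COLUMNS,
    TRANSMITTERS,
    VocabularyError,
    normalize_labels,
)

logger = logging.getLogger("ntcalls")

__all__ = [
    "SchemaError",
    "RunConfig",
    "read_tables",
    "validate_synapse_table",
    "validate_neuron_table",
    "write_outputs",
    "read_confusion_csv",
    "write_confusion_csv",
    "run_pipeline",
]

SYNAPSE_REQUIRED = ("synapse_id", "neuron_id", "detection_score")
NEURON_REQUIRED = ("neuron_id",)

#: Deterministic column order of the per-neuron output table.
NEURON_OUTPUT_COLUMNS = (
    ["neuron_id", "top_nt", "conf_nt", "margin", "confidence", "n_synapses_used"]
    + [f"frac_{t}" for t in TRANSMITTERS]
)


class SchemaError(ValueError):
    """A required column is missing or malformed."""


@dataclass
class RunConfig:
    """Everything one pipeline run depends on; serializable to YAML.

    ``dialect`` selects filter defaults ("fafb": cleft score > 50;
    "hemibrain": confidence > 0.5). The seed drives simulation only — the
    analysis stages are deterministic — but is recorded in every output.
    """

    seed: int = 0
    dialect: str = "fafb"
    detection_threshold: float | None = None  # None -> dialect default
    min_dist_soma_um: float = 15.0
    min_dist_primary_dendrite_um: float = 0.1
    min_presynapses: int = 100
    lambda_rate: float = 16.0
    epsilon: float = 1e-3
    confusion_csv: str | None = None
    synapse_path: str | None = None
    neuron_path: str | None = None
    out_dir: str = "results"

    def filter_policy(self) -> FilterPolicy:
        thr = self.detection_threshold
        if thr is None:
            thr = 0.5 if self.dialect == "hemibrain" else 50.0
        return FilterPolicy(
            detection_threshold=thr,
            min_dist_soma_um=self.min_dist_soma_um,
            min_dist_primary_dendrite_um=self.min_dist_primary_dendrite_um,
            min_presynapses=self.min_presynapses,
        )

    def prior(self) -> SmoothingPrior:
        return SmoothingPrior(self.lambda_rate, self.epsilon)

    @classmethod
    def from_yaml(cls, path) -> "RunConfig":
        with open(path) as fh:
            data = yaml.safe_load(fh) or {}
        return cls(**data)

    def to_yaml(self, path) -> None:
        with open(path, "w") as fh:
            yaml.safe_dump(asdict(self), fh, sort_keys=False)


def _read_any(path, dialect: str = "csv") -> pd.DataFrame:
    path = Path(path)
    if not path.exists():
        raise FileNotFoundError(path)
    if dialect == "feather" or path.suffix == ".feather":
        import pyarrow.feather as feather  # optional dependency

        return feather.read_feather(path)
    return pd.read_csv(path)


def validate_synapse_table(df: pd.DataFrame) -> pd.DataFrame:
    """Normalize and validate a synapse table; returns a clean copy.

    Labels are mapped to the canonical vocabulary; score vectors, when all
    six columns are present, are normalized to the simplex (a row summing to
    zero or containing negatives/non-finites is an error); a missing
    ``pred_label`` is filled from the score argmax; when both are present
    the label must equal the argmax label.
    """
    for col in SYNAPSE_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"synapse table is missing required column {col!r}")
    df = df.copy()
    if df["synapse_id"].duplicated().any():
        dupes = df.loc[df["synapse_id"].duplicated(), "synapse_id"].tolist()[:5]
        raise SchemaError(f"duplicate synapse_id values, e.g. {dupes}")

    has_scores = all(c in df.columns for c in SCORE_COLUMNS)
    if not has_scores and "pred_label" not in df.columns:
        raise SchemaError(
            "synapse table needs either a pred_label column or all six score columns"
        )
    if has_scores:
        S = df[list(SCORE_COLUMNS)].to_numpy(dtype=float)
        if not np.all(np.isfinite(S)) or np.any(S < 0):
            raise SchemaError("score columns must be finite and non-negative")
        totals = S.sum(axis=1)
        if np.any(totals <= 0):
            bad = df.loc[totals <= 0, "synapse_id"].tolist()[:5]
            raise SchemaError(f"score rows sum to zero for synapse_id {bad}")
        S = S / totals[:, None]
        df[list(SCORE_COLUMNS)] = S
        argmax_labels = [TRANSMITTERS[i] for i in S.argmax(axis=1)]
        if "pred_label" not in df.columns:
            df["pred_label"] = argmax_labels
    if "pred_label" in df.columns:
        df["pred_label"] = normalize_labels(df["pred_label"])
    if has_scores:
        mismatch = df["pred_label"].to_numpy() != np.asarray(argmax_labels)
        if mismatch.any():
            bad = df.loc[mismatch, "synapse_id"].tolist()[:5]
            raise SchemaError(
                f"pred_label disagrees with score argmax for synapse_id {bad}"
            )
    if "compartment" in df.columns:
        comp = df["compartment"].fillna("unknown").astype(str).str.strip().str.lower()
        unknown = set(comp) - COMPARTMENTS
        if unknown:
            raise VocabularyError(f"unknown compartment values: {sorted(unknown)}")
        df["compartment"] = comp
    for col in ("detection_score", "dist_soma_um", "dist_primary_dendrite_um"):
        if col in df.columns:
            df[col] = pd.to_numeric(df[col], errors="raise")
    return df


def validate_neuron_table(df: pd.DataFrame) -> pd.DataFrame:
    """Validate neuron metadata; enforces unique ids and symmetric homolog links."""
    for col in NEURON_REQUIRED:
        if col not in df.columns:
            raise SchemaError(f"neuron table is missing required column {col!r}")
    df = df.copy()
    if df["neuron_id"].duplicated().any():
        dupes = df.loc[df["neuron_id"].duplicated(), "neuron_id"].tolist()[:5]
        raise SchemaError(f"duplicate neuron_id values, e.g. {dupes}")
    if "side" in df.columns:
        df["side"] = df["side"].fillna("unknown")
    if "homolog_id" in df.columns:
        links = df.set_index("neuron_id")["homolog_id"]
        links = links[links.notna() & (links != "")]
        for nid, hid in links.items():
            if hid in links.index and links[hid] not in ("", nid):
                raise SchemaError(
                    f"asymmetric homolog link: {nid!r} -> {hid!r} -> {links[hid]!r}"
                )
    return df


def read_tables(
    synapse_path, neuron_path, dialect: str = "csv"
) -> tuple[pd.DataFrame, pd.DataFrame]:
    """Read and validate the synapse and neuron tables."""
    synapses = validate_synapse_table(_read_any(synapse_path, dialect))
    neurons = validate_neuron_table(_read_any(neuron_path, dialect))
    return synapses, neurons


def write_outputs(calls: pd.DataFrame, out_path, dialect: str = "csv") -> Path:
    """Write the per-neuron call table with deterministic column order."""
    out_path = Path(out_path)
    out_path.parent.mkdir(parents=True, exist_ok=True)
    cols = [c for c in NEURON_OUTPUT_COLUMNS if c in calls.columns]
    cols += [c for c in calls.columns if c not in cols]
    out = calls[cols]
    if dialect == "feather" or out_path.suffix == ".feather":
        import pyarrow.feather as feather

        feather.write_feather(out.reset_index(drop=True), out_path)
    else:
        out.to_csv(out_path, index=False)
    return out_path


def write_confusion_csv(C: ConfusionMatrix, path) -> None:
    C.to_frame().to_csv(path, index_label="true_label")


def read_confusion_csv(path, level: str = "neuron") -> ConfusionMatrix:
    df = pd.read_csv(path, index_col=0)
    df.index = normalize_labels(df.index)
    df.columns = normalize_labels(df.columns)
    df = df.loc[list(TRANSMITTERS), list(TRANSMITTERS)]
    return ConfusionMatrix(df.to_numpy(dtype=float), level=level)


def _homolog_pairs(neurons: pd.DataFrame) -> pd.DataFrame:
    """Derive one row per homolog pair (each unordered pair once)."""
    if "homolog_id" not in neurons.columns:
        return pd.DataFrame(columns=["neuron_a", "neuron_b", "relation"])
    links = neurons.set_index("neuron_id")["homolog_id"]
    links = links[links.notna() & (links != "")]
    seen, rows = set(), []
    datasets = (
        neurons.set_index("neuron_id")["dataset"]
        if "dataset" in neurons.columns
        else None
    )
    for a, b in links.items():
        if b not in links.index or (b, a) in seen or (a, b) in seen:
            continue
        seen.add((a, b))
        relation = "left_right"
        if datasets is not None and datasets.get(a) != datasets.get(b):
            relation = "cross_dataset"
        rows.append({"neuron_a": a, "neuron_b": b, "relation": relation})
    return pd.DataFrame(rows, columns=["neuron_a", "neuron_b", "relation"])


def run_pipeline(
    config: RunConfig,
    synapses: pd.DataFrame | None = None,
    neurons: pd.DataFrame | None = None,
    C: ConfusionMatrix | None = None,
    write: bool = True,
) -> dict:
    """Run filter -> vote -> confidence -> entropy -> Bayes -> consistency.

    Tables may be passed in memory (e.g. from ``simulate_study``) or read
    from the paths in ``config``. The confusion matrix is optional for
    voting but required for confidence and Bayes stages. Returns a dict of
    DataFrames ("calls", "celltypes", "entropy", "bayes", "pairs",
    "mismatch", plus "filter_report" and "quartiles"); with ``write=True``
    each table is also written under ``config.out_dir``.
    """
    if synapses is None or neurons is None:
        if not (config.synapse_path and config.neuron_path):
            raise ValueError("either pass tables in memory or set paths in the config")
        synapses, neurons = read_tables(config.synapse_path, config.neuron_path)
    else:
        synapses = validate_synapse_table(synapses)
        neurons = validate_neuron_table(neurons)
    if C is None and config.confusion_csv:
        C = read_confusion_csv(config.confusion_csv)

    policy = config.filter_policy()
    try:
        # stage 1: detection-score threshold only -> 'top_nt' votes
        thr_only = FilterPolicy(
            detection_threshold=policy.detection_threshold,
            allowed_compartments=frozenset(COMPARTMENTS),
            min_dist_soma_um=0.0,
            min_dist_primary_dendrite_um=0.0,
            min_presynapses=policy.min_presynapses,
        )
        syn_thr, rep_thr = filter_synapses(synapses, thr_only)
        top_calls = call_neurons(syn_thr, C=None, policy=policy)

        # stage 2: full filtering -> 'conf_nt' votes + confidence
        syn_full, rep_full = filter_synapses(synapses, policy)
        logger.info("threshold-only filter: %s", rep_thr)
        logger.info("full filter: %s", rep_full)
        calls = call_neurons(syn_full, C=C, policy=policy)
        calls = calls.rename(columns={"winner": "conf_nt"})
        calls = calls.merge(
            top_calls[["neuron_id", "winner"]].rename(columns={"winner": "top_nt"}),
            on="neuron_id",
            how="left",
        )
        calls["top_nt"] = calls["top_nt"].fillna("uncertain")
        n_changed = int((calls["top_nt"] != calls["conf_nt"]).sum())
        logger.info(
            "filtering changed the call of %d / %d neurons", n_changed, len(calls)
        )
    except Exception as err:  # pragma: no cover - stage tagging
        raise RuntimeError(f"aggregation stage failed: {err}") from err

    calls_std = calls.rename(columns={"conf_nt": "winner"})

    results: dict = {
        "calls": calls,
        "filter_report": {"threshold_only": rep_thr, "full": rep_full},
        "seed": config.seed,
    }

    try:
        if "cell_type" in neurons.columns:
            results["celltypes"] = call_celltypes(calls_std, neurons)
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"cell-type stage failed: {err}") from err

    try:
        if "hemilineage" in neurons.columns:
            ent = hemilineage_entropies(syn_full, calls_std, neurons)
            results["entropy"] = ent
            eligible = ent[ent["eligible"]]
            if len(eligible.dropna(subset=["H_neuron", "H_synapse_mean"])) >= 4:
                labeled, quartiles = entropy_quadrants(eligible)
                results["entropy"] = ent.merge(
                    labeled[["hemilineage", "quadrant"]], on="hemilineage", how="left"
                )
                results["quartiles"] = quartiles
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"entropy stage failed: {err}") from err

    try:
        if "hemilineage" in neurons.columns and C is not None:
            results["bayes"] = analyze_hemilineages(
                calls_std, neurons, C, config.prior()
            )
        elif "hemilineage" in neurons.columns:
            raise ValueError(
                "hemilineage Bayes analysis requires a confusion matrix; "
                "set confusion_csv in the config or pass C"
            )
    except ValueError as err:
        raise RuntimeError(f"bayes stage failed: {err}") from err

    try:
        pairs = _homolog_pairs(neurons)
        if len(pairs):
            rep = pair_report(pairs, calls_std, syn_full)
            results["pairs"] = rep
            results["mismatch"] = mismatch_summary(rep)
    except Exception as err:  # pragma: no cover
        raise RuntimeError(f"consistency stage failed: {err}") from err

    if write:
        out = Path(config.out_dir)
        out.mkdir(parents=True, exist_ok=True)
        write_outputs(calls, out / "neuron_calls.csv")
        for name in ("celltypes", "entropy", "bayes", "pairs", "mismatch"):
            if name in results:
                results[name].to_csv(out / f"{name}.csv", index=False)
        meta = {
            "seed": config.seed,
            "dialect": config.dialect,
            "lambda": config.lambda_rate,
            "epsilon": config.epsilon,
            "filter_threshold_only": rep_thr.removed | {"retained": rep_thr.n_retained},
            "filter_full": rep_full.removed | {"retained": rep_full.n_retained},
        }
        with open(out / "run_meta.json", "w") as fh:
            json.dump(meta, fh, indent=2)
    return results
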