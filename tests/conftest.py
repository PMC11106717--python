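import numpy as np
import pandas as pd
import pytest

from ntcalls import SimConfig, diagonal_confusion, simulate_study, uniform_confusion
from ntcalls.labels import TRANSMITTERS


@pytest.fixture(scope="session")
def identity_C():
    return diagonal_confusion(1.0)


@pytest.fixture(scope="session")
def uniform_C():
    return uniform_confusion()


@pytest.fixture(scope="session")
def diag9_C():
    return diagonal_confusion(0.9)


@pytest.fixture(scope="session")
def random_C():
    """A fixed, generic row-stochastic confusion matrix (diagonal-dominant)."""
    rng = np.random.default_rng(2024)
    C = rng.dirichlet(np.ones(6), size=6) + 2.0 * np.eye(6)
    C /= C.sum(axis=1, keepdims=True)
    from ntcalls import ConfusionMatrix

    return ConfusionMatrix(C, level="neuron")


@pytest.fixture(scope="session")
def small_study():
    """A small synthetic study with contamination and homolog pairs."""
    cfg = SimConfig(
        seed=11,
        n_hemilineages=4,
        neurons_per_hemilineage=15,
        median_synapses=120,
        homolog_pairs=True,
    )
    return cfg, simulate_study(cfg)


def make_synapse_table(rows):
    """Build a synapse table from (neuron_id, label, score, compartment, d_soma, d_pd)."""
    recs = []
    for i, (nid, label, score, comp, dsoma, dpd) in enumerate(rows):
        recs.append(
            {
                "synapse_id": f"s{i}",
                "neuron_id": nid,
                "pred_label": label,
                "detection_score": score,
                "compartment": comp,
                "dist_soma_um": dsoma,
                "dist_primary_dendrite_um": dpd,
            }
        )
    return pd.DataFrame(recs)


@pytest.fixture
def ten_row_table():
    """Ten synapses; three violate exactly one filter rule each.

    Row 3 sits exactly at the detection threshold (score 50 -> removed,
    strict inequality), row 5 is somatic, row 7 is 10 um from the soma.
    """
    ok = ("n1", "acetylcholine", 120.0, "axon", 30.0, 5.0)
    rows = [ok, ok, ok]
    rows.append(("n1", "acetylcholine", 50.0, "axon", 30.0, 5.0))
    rows.append(ok)
    rows.append(("n1", "gaba", 120.0, "soma", 30.0, 5.0))
    rows.append(ok)
    rows.append(("n1", "gaba", 120.0, "axon", 10.0, 5.0))
    rows.append(ok)
    rows.append(ok)
    return make_synapse_table(rows)


def labels_from_counts(**counts):
    out = []
    for name, k in counts.items():
        assert name in TRANSMITTERS
        out.extend([name] * k)
    return out
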