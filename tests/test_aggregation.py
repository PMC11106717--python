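"""Presynapse filtering, majority voting, and confidence scoring."""

import numpy as np
import pandas as pd
import pytest

from ntcalls import (
    FilterPolicy,
    diagonal_confusion,
    filter_synapses,
    neuron_call,
    neuron_confidence,
    vote_fractions,
)
from ntcalls.aggregation import call_neurons, celltype_call
from ntcalls.labels import TRANSMITTERS, UNCERTAIN

from conftest import labels_from_counts, make_synapse_table


class TestFilter:
    def test_ten_row_fixture_ledger(self, ten_row_table):
        policy = FilterPolicy(min_presynapses=1)
        kept, report = filter_synapses(ten_row_table, policy)
        assert len(kept) == 7
        assert report.n_input == 10
        assert report.removed == {
            "detection_score": 1,
            "compartment": 1,
            "dist_soma": 1,
            "dist_primary_dendrite": 0,
        }

    def test_score_at_threshold_removed(self):
        # "above 50" is strict: a score of exactly 50 does not survive
        t = make_synapse_table([("n", "gaba", 50.0, "axon", 30.0, 5.0)])
        kept, _ = filter_synapses(t, FilterPolicy())
        assert len(kept) == 0

    def test_distance_thresholds_inclusive(self):
        t = make_synapse_table(
            [
                ("n", "gaba", 120.0, "axon", 15.0, 0.1),  # exactly at bounds: kept
                ("n", "gaba", 120.0, "axon", 14.999, 0.1),
                ("n", "gaba", 120.0, "axon", 15.0, 0.0999),
            ]
        )
        kept, report = filter_synapses(t, FilterPolicy())
        assert len(kept) == 1
        assert report.removed["dist_soma"] == 1
        assert report.removed["dist_primary_dendrite"] == 1

    def test_missing_optional_columns_pass(self):
        t = pd.DataFrame(
            {
                "synapse_id": ["a", "b"],
                "neuron_id": ["n", "n"],
                "pred_label": ["gaba", "gaba"],
                "detection_score": [120.0, 30.0],
            }
        )
        kept, report = filter_synapses(t, FilterPolicy())
        assert len(kept) == 1
        assert report.removed["compartment"] == 0

    def test_strict_mode_rejects_missing_columns(self):
        t = pd.DataFrame(
            {
                "synapse_id": ["a"],
                "neuron_id": ["n"],
                "pred_label": ["gaba"],
                "detection_score": [120.0],
            }
        )
        kept, _ = filter_synapses(t, FilterPolicy(strict=True))
        assert len(kept) == 0

    def test_row_order_invariance(self, ten_row_table):
        shuffled = ten_row_table.sample(frac=1.0, random_state=3)
        kept_a, _ = filter_synapses(ten_row_table, FilterPolicy(min_presynapses=1))
        kept_b, _ = filter_synapses(shuffled, FilterPolicy(min_presynapses=1))
        assert sorted(kept_a["synapse_id"]) == sorted(kept_b["synapse_id"])


class TestVote:
    def test_counting(self):
        labels = labels_from_counts(acetylcholine=60, gaba=40)
        f = vote_fractions(labels)
        assert f[TRANSMITTERS.index("gaba")] == pytest.approx(0.4)
        assert f[TRANSMITTERS.index("acetylcholine")] == pytest.approx(0.6)
        assert f.sum() == pytest.approx(1.0)

    def test_one_hot(self):
        f = vote_fractions(["serotonin"] * 10)
        assert f[TRANSMITTERS.index("serotonin")] == 1.0

    def test_permutation_invariance(self):
        labels = labels_from_counts(gaba=3, dopamine=5, glutamate=2)
        rng = np.random.default_rng(0)
        shuffled = list(labels)
        rng.shuffle(shuffled)
        np.testing.assert_array_equal(vote_fractions(labels), vote_fractions(shuffled))

    def test_empty_errors(self):
        with pytest.raises(ValueError):
            vote_fractions([])


class TestNeuronCall:
    def test_margin_below_ten_points_is_uncertain(self):
        labels = labels_from_counts(acetylcholine=52, gaba=48)
        call = neuron_call(labels)
        assert call.winner == UNCERTAIN
        assert call.margin == pytest.approx(0.04)

    def test_clear_margin_wins(self):
        labels = labels_from_counts(acetylcholine=60, gaba=40)
        assert neuron_call(labels).winner == "acetylcholine"

    def test_too_few_synapses_uncertain(self):
        labels = ["acetylcholine"] * 99
        assert neuron_call(labels).winner == UNCERTAIN
        assert neuron_call(labels, policy=FilterPolicy(min_presynapses=30)).winner == "acetylcholine"

    def test_exact_tie_uncertain(self):
        labels = labels_from_counts(acetylcholine=50, gaba=50)
        call = neuron_call(labels)
        assert call.winner == UNCERTAIN
        assert call.margin == 0.0


class TestConfidence:
    def test_homogeneous_row_value(self):
        C = diagonal_confusion(0.95, level="synapse")
        labels = ["acetylcholine"] * 120
        call = neuron_call(labels)
        assert neuron_confidence(call, labels, C) == pytest.approx(0.95)

    def test_identity_homogeneous_is_one(self):
        C = diagonal_confusion(1.0, level="synapse")
        labels = ["gaba"] * 150
        assert neuron_confidence(neuron_call(labels), labels, C) == pytest.approx(1.0)

    def test_mixed_average(self):
        # 3 ACh + 1 GABA, C[ACh,ACh]=0.95, C[ACh,GABA]=0.02 -> 0.7175
        C = np.full((6, 6), 1 / 6)
        # canonical order: (gaba, acetylcholine, glutamate, serotonin, octopamine, dopamine)
        C[1] = [0.02, 0.95, 0.0075, 0.0075, 0.0075, 0.0075]
        from ntcalls import ConfusionMatrix

        cm = ConfusionMatrix(C, level="synapse")
        labels = ["acetylcholine"] * 3 + ["gaba"]
        call = neuron_call(labels, policy=FilterPolicy(min_presynapses=1))
        assert call.winner == "acetylcholine"
        assert neuron_confidence(call, labels, cm) == pytest.approx(
            (3 * 0.95 + 0.02) / 4
        )

    def test_uncertain_has_no_confidence(self):
        C = diagonal_confusion(0.9, level="synapse")
        labels = labels_from_counts(acetylcholine=50, gaba=50)
        with pytest.raises(ValueError):
            neuron_confidence(neuron_call(labels), labels, C)

    def test_brute_force_oracle(self, random_C):
        """Confidence equals the direct per-synapse average C[winner, label_s]
        on 1,000 random instances, and equals the vote-fraction identity
        c(n) = sum_y p_n(y) C[winner, y]."""
        rng = np.random.default_rng(42)
        policy = FilterPolicy(min_presynapses=1)
        for _ in range(1000):
            n = rng.integers(1, 40)
            labels = [TRANSMITTERS[i] for i in rng.integers(0, 6, size=n)]
            call = neuron_call(labels, policy=policy)
            if call.is_uncertain:
                continue
            got = neuron_confidence(call, labels, random_C)
            i_win = TRANSMITTERS.index(call.winner)
            direct = np.mean(
                [random_C.C[i_win, TRANSMITTERS.index(lab)] for lab in labels]
            )
            assert got == pytest.approx(direct, abs=1e-12)
            identity = float(call.fractions @ random_C.C[i_win])
            assert got == pytest.approx(identity, abs=1e-12)


class TestCellType:
    @pytest.mark.parametrize(
        "winners, expect_winner, expect_conflict",
        [
            (["acetylcholine", "acetylcholine", "gaba"], "acetylcholine", True),
            (["acetylcholine", "acetylcholine"], "acetylcholine", False),
            (["acetylcholine", "gaba"], UNCERTAIN, True),
            (["acetylcholine", UNCERTAIN, UNCERTAIN], "acetylcholine", False),
            ([UNCERTAIN, UNCERTAIN], UNCERTAIN, False),
        ],
    )
    def test_mode_rule(self, winners, expect_winner, expect_conflict):
        winner, conflicted, _ = celltype_call(winners)
        assert winner == expect_winner
        assert conflicted is expect_conflict


class TestCallNeurons:
    def test_groups_and_columns(self):
        rows = []
        for nid, label in (("a", "gaba"), ("a", "gaba"), ("b", "dopamine")):
            rows.append((nid, label, 120.0, "axon", 30.0, 5.0))
        t = make_synapse_table(rows)
        calls = call_neurons(t, policy=FilterPolicy(min_presynapses=1))
        assert list(calls["neuron_id"]) == ["a", "b"]
        assert list(calls["winner"]) == ["gaba", "dopamine"]
        assert calls["confidence"].isna().all()  # no confusion matrix given
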