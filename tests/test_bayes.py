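"""Bayes-factor model comparison for the number of transmitters per hemilineage."""

from itertools import product
from math import comb

import numpy as np
import pytest

from ntcalls import (
    SmoothingPrior,
    analyze_hemilineage,
    classify_evidence,
    diagonal_confusion,
    expected_confusion,
    log_marginal_likelihood,
    one_vs_rest,
    pairwise_bayes_factor,
    rank_transmitters,
)
from ntcalls.labels import TRANSMITTERS, UNCERTAIN

ACH = "acetylcholine"


class TestMarginalLikelihood:
    @pytest.mark.parametrize("m", range(1, 7))
    def test_single_observation_identity_C(self, identity_C, m):
        # one observation cannot distinguish m: C(5, m-1) / (C(6, m) m) = 1/6
        lp = log_marginal_likelihood([ACH], identity_C, m)
        assert np.exp(lp) == pytest.approx(1 / 6, abs=1e-12)

    def test_two_identical_identity_C(self, identity_C):
        assert np.exp(log_marginal_likelihood([ACH, ACH], identity_C, 1)) == pytest.approx(1 / 6)
        assert np.exp(log_marginal_likelihood([ACH, ACH], identity_C, 2)) == pytest.approx(1 / 12)

    @pytest.mark.parametrize("m", range(1, 7))
    def test_uniform_C_gives_one_sixth_power_n(self, uniform_C, m):
        winners = ["gaba", ACH, "dopamine"]
        lp = log_marginal_likelihood(winners, uniform_C, m)
        assert lp == pytest.approx(3 * np.log(1 / 6), abs=1e-12)

    @pytest.mark.parametrize("m", range(1, 7))
    @pytest.mark.parametrize("n", [1, 2, 3])
    def test_normalization_by_exhaustive_enumeration(self, random_C, m, n):
        """sum over all 6^n winner configurations of p(yhat|m) equals 1."""
        total = 0.0
        for config in product(TRANSMITTERS, repeat=n):
            total += np.exp(log_marginal_likelihood(list(config), random_C, m))
        assert total == pytest.approx(1.0, abs=1e-10)

    def test_exchangeability(self, random_C):
        winners = ["gaba", ACH, ACH, "dopamine", "serotonin"]
        rng = np.random.default_rng(1)
        shuffled = list(winners)
        rng.shuffle(shuffled)
        for m in (1, 2, 3):
            assert log_marginal_likelihood(winners, random_C, m) == pytest.approx(
                log_marginal_likelihood(shuffled, random_C, m)
            )

    def test_matches_bruteforce_subset_enumeration(self, random_C):
        """Log-space implementation agrees with a direct product-of-sums oracle."""
        winners = ["gaba", ACH, ACH, "glutamate"]
        idx = [TRANSMITTERS.index(w) for w in winners]
        from itertools import combinations

        for m in range(1, 7):
            total = 0.0
            for S in combinations(range(6), m):
                prod = 1.0
                for j in idx:
                    prod *= sum(random_C.C[y, j] for y in S) / m
                total += prod
            total /= comb(6, m)
            assert log_marginal_likelihood(winners, random_C, m) == pytest.approx(
                np.log(total), abs=1e-10
            )

    def test_impossible_data_is_neg_inf(self, identity_C):
        lp = log_marginal_likelihood(list(TRANSMITTERS), identity_C, 1)
        assert np.isneginf(lp)

    def test_large_n_no_underflow(self, diag9_C):
        winners = [ACH] * 1000
        lp = log_marginal_likelihood(winners, diag9_C, 1)
        assert np.isfinite(lp)
        assert lp < -100  # far below double-precision direct products

    def test_m_out_of_range(self, identity_C):
        with pytest.raises(ValueError):
            log_marginal_likelihood([ACH], identity_C, 0)
        with pytest.raises(ValueError):
            log_marginal_likelihood([ACH], identity_C, 7)


class TestBayesFactors:
    def test_uniform_C_indifference(self, uniform_C):
        winners = ["gaba", ACH, "dopamine", "serotonin"]
        for m1 in range(1, 7):
            for m2 in range(1, 7):
                assert pairwise_bayes_factor(winners, uniform_C, m1, m2) == pytest.approx(1.0)
            assert one_vs_rest(winners, uniform_C, m1) == pytest.approx(1 / 5)

    def test_two_identical_identity_K12(self, identity_C):
        assert pairwise_bayes_factor([ACH, ACH], identity_C, 1, 2) == pytest.approx(2.0)

    def test_two_different_identity_K21_infinite(self, identity_C):
        K = pairwise_bayes_factor([ACH, "gaba"], identity_C, 2, 1)
        assert np.isposinf(K)

    def test_antisymmetry(self, random_C):
        winners = ["gaba", "gaba", ACH, "dopamine"]
        for m1, m2 in ((1, 2), (2, 3), (1, 6)):
            K = pairwise_bayes_factor(winners, random_C, m1, m2)
            Kinv = pairwise_bayes_factor(winners, random_C, m2, m1)
            assert np.log(K) == pytest.approx(-np.log(Kinv), abs=1e-10)

    def test_one_vs_rest_single_observation(self, identity_C):
        for m in range(1, 7):
            assert one_vs_rest([ACH], identity_C, m) == pytest.approx(1 / 5)

    def test_homogeneous_hemilineage_decisive_for_one(self, diag9_C):
        K = one_vs_rest([ACH] * 50, diag9_C, 1)
        assert K > 100

    def test_evidence_growth_with_n(self, diag9_C):
        Ks = [one_vs_rest([ACH] * n, diag9_C, 1) for n in (5, 20, 50, 200)]
        assert all(np.diff(Ks) > 0)


class TestEvidenceScale:
    @pytest.mark.parametrize(
        "K, expected",
        [
            (150.0, "decisive"),
            (100.0, "decisive"),
            (10**1.5, "strong"),
            (40.0, "strong"),
            (10.0, "good"),
            (10**0.5, "substantial"),
            (3.0, "none"),
            (1.0, "none"),
            (0.0, "none"),
        ],
    )
    def test_thresholds(self, K, expected):
        assert classify_evidence(K) == expected

    def test_negative_rejected(self):
        with pytest.raises(ValueError):
            classify_evidence(-1.0)


class TestRanking:
    def test_frequency_order(self):
        winners = [ACH] * 30 + ["gaba"] * 10 + ["glutamate"] * 2
        ranked, counts, ties = rank_transmitters(winners)
        assert ranked == (ACH, "gaba", "glutamate")
        assert counts == (30, 10, 2)
        assert not ties

    def test_unanimity(self):
        ranked, counts, ties = rank_transmitters(["dopamine"] * 4)
        assert ranked == ("dopamine",)

    def test_tie_canonical_order_flagged(self):
        winners = ["dopamine"] * 5 + ["gaba"] * 5
        ranked, _, ties = rank_transmitters(winners)
        assert ranked == ("gaba", "dopamine")  # canonical tiebreak
        assert ties


class TestAnalyze:
    def test_m1_simulation_recovers_one(self, diag9_C):
        rng = np.random.default_rng(17)
        winners = [
            TRANSMITTERS[i]
            for i in rng.choice(6, size=40, p=diag9_C.C[TRANSMITTERS.index(ACH)])
        ]
        res = analyze_hemilineage(winners, diag9_C, SmoothingPrior(16.0, 1e-3), "h1")
        assert res.best_m == 1
        assert res.ranked_transmitters[0] == ACH

    def test_balanced_m2_simulation_recovers_two(self, diag9_C):
        rng = np.random.default_rng(23)
        winners = []
        for true in (ACH, "gaba"):
            row = diag9_C.C[TRANSMITTERS.index(true)]
            winners += [TRANSMITTERS[i] for i in rng.choice(6, size=20, p=row)]
        res = analyze_hemilineage(winners, diag9_C, SmoothingPrior(16.0, 1e-3), "h2")
        assert res.best_m == 2
        assert set(res.ranked_transmitters[:2]) == {ACH, "gaba"}

    def test_uncertain_dropped_and_counted(self, diag9_C):
        winners = [ACH] * 10 + [UNCERTAIN] * 4
        res = analyze_hemilineage(winners, diag9_C, SmoothingPrior(16.0, 1e-3))
        assert res.n_neurons == 10
        assert res.n_uncertain_dropped == 4

    def test_no_usable_calls_errors(self, diag9_C):
        with pytest.raises(ValueError):
            analyze_hemilineage([UNCERTAIN], diag9_C, SmoothingPrior(16.0))

    def test_best_m_is_argmax_one_vs_rest(self, random_C):
        rng = np.random.default_rng(3)
        winners = [TRANSMITTERS[i] for i in rng.integers(0, 6, size=25)]
        prior = SmoothingPrior(16.0, 1e-3)
        res = analyze_hemilineage(winners, random_C, prior)
        C_eff = expected_confusion(random_C, prior)
        ovr = [one_vs_rest(winners, C_eff, m) for m in range(1, 7)]
        assert res.best_m == int(np.argmax(ovr)) + 1
        np.testing.assert_allclose(res.one_vs_rest_K, ovr, rtol=1e-12)
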