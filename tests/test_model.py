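"""Permutation likelihood, exact order search, ILP, entropy."""
import itertools
import math

import numpy as np
import pytest

from spliceorder.matrix import PairCountMatrix, frequency_matrix
from spliceorder.model import (
    SplicingOrder,
    SplicingOrderModel,
    exhaustive_most_likely,
    ilp_most_likely,
    log_likelihood,
    most_unlikely_order,
    normalized_entropy,
    relative_log_likelihood,
)


def random_freq(rng, n):
    """A continuous random frequency matrix (ties have measure zero)."""
    D = np.zeros((n, n))
    for i in range(n):
        for j in range(i + 1, n):
            p = rng.uniform(0.02, 0.98)
            D[i, j], D[j, i] = p, 1.0 - p
    return D


def brute_force_best(D):
    """Independent oracle: literal enumeration of all n! orders."""
    n = D.shape[0]
    best, best_perm = -np.inf, None
    for perm in itertools.permutations(range(1, n + 1)):
        ll = log_likelihood(D, SplicingOrder(perm))
        if ll > best + 1e-12:
            best, best_perm = ll, perm
    return best, best_perm


class TestSplicingOrder:
    def test_rank_is_inverse(self):
        theta = SplicingOrder((1, 4, 2, 3))
        assert theta.rank == (1, 3, 4, 2)
        assert tuple(theta.sequence[r - 1] for r in range(1, 5)) == (1, 4, 2, 3)

    def test_reversal(self):
        theta = SplicingOrder((1, 4, 2, 3))
        assert most_unlikely_order(theta).sequence == (3, 2, 4, 1)
        assert most_unlikely_order(most_unlikely_order(theta)) == theta

    def test_not_a_permutation_rejected(self):
        with pytest.raises(ValueError):
            SplicingOrder((1, 1, 2))

    def test_string_round_trip(self):
        assert str(SplicingOrder.from_string("1->4->2->3")) == "1->4->2->3"


class TestLogLikelihood:
    def test_two_intron_examples(self):
        D = np.array([[0.0, 0.9], [0.1, 0.0]])
        assert log_likelihood(D, (1, 2)) == pytest.approx(math.log(0.9))
        assert log_likelihood(D, (2, 1)) == pytest.approx(math.log(0.1))

    def test_uninformative_matrix(self):
        D = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
        for perm in itertools.permutations(range(1, 5)):
            assert log_likelihood(D, perm) == pytest.approx(6 * math.log(0.5))

    def test_no_evidence_pairs_contribute_nothing(self):
        D = np.zeros((3, 3))
        D[0, 1], D[1, 0] = 0.8, 0.2
        assert log_likelihood(D, (1, 2, 3)) == pytest.approx(math.log(0.8))

    def test_non_permutation_rejected(self):
        with pytest.raises(ValueError):
            log_likelihood(np.zeros((3, 3)), (1, 2))


class TestExhaustive:
    def test_transitive_three_introns(self):
        A = np.zeros((3, 3))
        A[2, 0], A[2, 1], A[0, 1] = 9, 8, 7
        res = exhaustive_most_likely(frequency_matrix(PairCountMatrix(A)))
        assert res.theta_star.sequence == (3, 1, 2)
        assert res.unique

    def test_uninformative_matrix_ties(self):
        D = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
        res = exhaustive_most_likely(D)
        assert not res.unique
        assert res.n_optima == math.factorial(4)
        assert res.theta_star.sequence == (1, 2, 3, 4)  # lexicographically smallest

    def test_two_introns(self):
        res = exhaustive_most_likely(np.array([[0.0, 0.9], [0.1, 0.0]]))
        assert res.theta_star.sequence == (1, 2) and res.unique

    @pytest.mark.parametrize("n", [3, 4, 5, 6, 7])
    def test_matches_literal_enumeration(self, rng, n):
        for _ in range(8):
            D = random_freq(rng, n)
            res = exhaustive_most_likely(D)
            best, best_perm = brute_force_best(D)
            assert res.llf == pytest.approx(best, abs=1e-9)
            assert res.theta_star.sequence == best_perm
            assert res.unique

    @pytest.mark.parametrize("n", [3, 5, 6])
    def test_reverse_order_attains_minimum(self, rng, n):
        """The least likely order is exactly the reversal of the most likely one."""
        D = random_freq(rng, n)
        res = exhaustive_most_likely(D)
        lls = {perm: log_likelihood(D, SplicingOrder(perm))
               for perm in itertools.permutations(range(1, n + 1))}
        worst = min(lls, key=lls.get)
        assert worst == res.theta_star.reverse().sequence

    def test_relabeling_invariance(self, rng):
        """Permuting intron labels relabels theta* but preserves llf, R, entropy."""
        n = 5
        D = random_freq(rng, n)
        sigma = rng.permutation(n)
        P = np.eye(n)[sigma]
        D2 = P @ D @ P.T  # intron sigma[i]+1 renamed to i+1
        r1, r2 = exhaustive_most_likely(D), exhaustive_most_likely(D2)
        assert r2.llf == pytest.approx(r1.llf)
        mapped = tuple(int(np.where(sigma == i - 1)[0][0]) + 1 for i in r1.theta_star.sequence)
        assert r2.theta_star.sequence == mapped
        assert normalized_entropy(D2) == pytest.approx(normalized_entropy(D))

    def test_out_of_range_n(self):
        with pytest.raises(ValueError):
            exhaustive_most_likely(np.zeros((12, 12)))


class TestILP:
    def test_matches_exhaustive_on_random_instances(self, rng):
        for n in (4, 5, 6, 7, 8):
            for _ in range(4):
                D = random_freq(rng, n)
                e, i = exhaustive_most_likely(D), ilp_most_likely(D)
                assert i.llf == pytest.approx(e.llf, abs=1e-9)
                assert i.theta_star.sequence == e.theta_star.sequence
                assert i.unique == e.unique

    def test_recovers_strict_total_order(self):
        n = 6
        D = np.zeros((n, n))
        for i in range(n):
            for j in range(i + 1, n):
                D[i, j], D[j, i] = 0.9, 0.1
        res = ilp_most_likely(D)
        assert res.theta_star.sequence == tuple(range(1, n + 1))
        assert res.unique

    def test_uninformative_matrix_reported_non_unique(self):
        D = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
        assert not ilp_most_likely(D).unique

    def test_handles_twelve_introns(self, rng):
        """The regime the exhaustive path cannot reach."""
        D = random_freq(rng, 12)
        res = ilp_most_likely(D)
        assert res.method == "ilp"
        # optimum must be at least as good as the identity and a random order
        assert res.llf >= log_likelihood(D, tuple(range(1, 13))) - 1e-9


class TestRelativeLikelihood:
    def test_identity_optimum_gives_zero(self):
        D = np.array([[0.0, 0.9], [0.1, 0.0]])
        res = exhaustive_most_likely(D)
        assert res.relative_log_likelihood == 0.0

    def test_two_intron_value(self):
        D = np.array([[0.0, 0.1], [0.9, 0.0]])
        res = exhaustive_most_likely(D)
        assert res.theta_star.sequence == (2, 1)
        assert res.relative_log_likelihood == pytest.approx(math.log(0.1) - math.log(0.9))

    def test_always_nonpositive_and_monotone(self, rng):
        D = random_freq(rng, 4)
        base = relative_log_likelihood(D, exhaustive_most_likely(D).theta_star)
        assert base <= 1e-12
        # strengthening evidence for 4 before 1 cannot raise R
        D2 = D.copy()
        D2[3, 0], D2[0, 3] = 0.99, 0.01
        strengthened = relative_log_likelihood(D2, exhaustive_most_likely(D2).theta_star)
        assert strengthened <= base + 1e-12


class TestEntropy:
    @pytest.mark.parametrize("n", [2, 3, 4, 5])
    def test_uniform_matrix_is_maximal(self, n):
        D = np.full((n, n), 0.5) - 0.5 * np.eye(n)
        assert normalized_entropy(D) == pytest.approx(1.0)

    def test_two_intron_value(self):
        D = np.array([[0.0, 0.99], [0.01, 0.0]])
        p, q = 0.99, 0.01
        expected = -(p * math.log2(p) + q * math.log2(q))
        assert normalized_entropy(D) == pytest.approx(expected)

    def test_strictly_decreasing_as_one_pair_sharpens(self):
        previous = 1.0
        for p in (0.6, 0.7, 0.8, 0.9, 0.99):
            D = np.full((4, 4), 0.5) - 0.5 * np.eye(4)
            D[0, 1], D[1, 0] = p, 1 - p
            h = normalized_entropy(D)
            assert 0.0 <= h < previous
            previous = h

    def test_undefined_for_large_n(self):
        with pytest.raises(ValueError):
            normalized_entropy(np.zeros((12, 12)))


class TestModelResults:
    def test_fit_dispatch_and_summary(self, rng):
        res = SplicingOrderModel(np.zeros((12, 12)) + np.triu(rng.poisson(9, (12, 12)), 1),
                                 transcript_id="tx").fit()
        assert res.method == "ilp"
        assert res.normalized_entropy is None
        assert "tx" in res.summary()

    def test_small_n_uses_exhaustive(self):
        A = np.zeros((3, 3))
        A[0, 1] = 5
        res = SplicingOrderModel(A).fit()
        assert res.method == "exhaustive"
        assert 0.0 <= res.normalized_entropy <= 1.0
        assert res.retention == pytest.approx(1 / 3)

    def test_too_many_introns_rejected(self):
        with pytest.raises(ValueError):
            SplicingOrderModel(np.zeros((100, 100))).fit()

    def test_from_dataframe(self):
        import pandas as pd

        df = pd.DataFrame(
            {"transcript_id": ["t", "t"], "earlier_intron": [4, 1],
             "later_intron": [1, 4], "read_count": [12, 1]}
        )
        m = SplicingOrderModel.from_dataframe(df, "t")
        assert m.freq[4, 1] == pytest.approx(12.1 / 13.2)
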