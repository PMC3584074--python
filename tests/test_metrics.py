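"""Metric tests, including brute-force oracle cross-checks.

The oracles here recompute each score from first principles (explicit
pair enumeration, direct rank arithmetic) independently of the library
code paths they validate.
"""

import itertools

import numpy as np
import pytest

from nicheweb import (
    BipartiteNetwork, BPNMParams, ProbabilityMatrix,
    c_dispersion, connectance_empirical, connectance_from_probabilities,
    continuous_overlap, degree_r_rank_correlation, fraction_links_predicted,
    generate_nested_matrix, nodf_consumers, paired_overlap, r_interval,
)
from conftest import random_network


def nodf_oracle(a: np.ndarray) -> float | None:
    """Independent consumer-NODF: enumerate every column pair directly."""
    col_deg = a.sum(axis=0)
    scores = []
    for i, j in itertools.combinations(range(a.shape[1]), 2):
        d_i, d_j = col_deg[i], col_deg[j]
        wide, narrow = (i, j) if d_i >= d_j else (j, i)
        d_w, d_n = max(d_i, d_j), min(d_i, d_j)
        if d_w == d_n or d_n == 0:
            continue
        shared = sum(1 for row in range(a.shape[0]) if a[row, wide] and a[row, narrow])
        scores.append(100.0 * shared / d_n)
    return float(np.mean(scores)) if scores else None


def spearman_oracle(x, y) -> float:
    """Rank-then-Pearson with average ranks, written out by hand."""
    def avg_ranks(v):
        v = np.asarray(v, dtype=float)
        order = np.argsort(v, kind="stable")
        ranks = np.empty(len(v))
        i = 0
        sorted_v = v[order]
        while i < len(v):
            j = i
            while j < len(v) and sorted_v[j] == sorted_v[i]:
                j += 1
            ranks[order[i:j]] = (i + j - 1) / 2 + 1
            i = j
        return ranks

    rx, ry = avg_ranks(x), avg_ranks(y)
    rx -= rx.mean()
    ry -= ry.mean()
    return float((rx * ry).sum() / np.sqrt((rx ** 2).sum() * (ry ** 2).sum()))


class TestPairedOverlap:
    def test_subset(self):
        assert paired_overlap({1, 2, 3}, {2, 3}) == 1.0

    def test_disjoint(self):
        assert paired_overlap({1, 2}, {3}) == 0.0

    def test_partial(self):
        assert paired_overlap({1, 2, 3, 4}, {3, 4, 5}) == pytest.approx(2 / 3)

    def test_empty_narrow_undefined(self):
        assert paired_overlap({1, 2}, set()) is None


class TestNodfConsumers:
    def test_strict_triangular_is_100(self):
        net = generate_nested_matrix(10)
        score, n_pairs = nodf_consumers(net)
        assert score == 100.0
        assert n_pairs == 45

    def test_identity_matrix_undefined(self):
        """All consumer degrees equal: every pair excluded."""
        net = BipartiteNetwork(np.eye(4, dtype=int))
        score, n_pairs = nodf_consumers(net)
        assert score is None and n_pairs == 0

    def test_equal_degree_pairs_scored_zero_under_original_flag(self):
        net = BipartiteNetwork(np.eye(4, dtype=int))
        score, n_pairs = nodf_consumers(net, score_equal_degrees_zero=True)
        assert score == 0.0 and n_pairs == 6

    def test_matches_brute_force_oracle(self, rng):
        for _ in range(100):
            net = random_network(rng, 6, 6, p=float(rng.uniform(0.2, 0.8)))
            score, _ = nodf_consumers(net)
            expected = nodf_oracle(net.adjacency)
            if expected is None:
                assert score is None
            else:
                assert score == pytest.approx(expected, abs=1e-12)

    def test_permutation_invariant(self, rng):
        for _ in range(30):
            net = random_network(rng, 5, 5)
            score, _ = nodf_consumers(net)
            perm = BipartiteNetwork(
                net.adjacency[np.ix_(rng.permutation(5), rng.permutation(5))])
            score_p, _ = nodf_consumers(perm)
            if score is None:
                assert score_p is None
            else:
                assert score == pytest.approx(score_p, abs=1e-12)


class TestRInterval:
    def test_centered(self):
        assert r_interval(0.5, 0.2) == pytest.approx((0.4, 0.6))

    def test_width_preserved_and_unclipped(self):
        lo, hi = r_interval(0.05, 0.2)
        assert hi - lo == pytest.approx(0.2)
        assert lo == pytest.approx(-0.05)

    def test_nonpositive_width(self):
        with pytest.raises(ValueError):
            r_interval(0.5, 0.0)


class TestContinuousOverlap:
    def test_concentric_is_100(self):
        params = BPNMParams(n=[0.5] * 3, c=[0.5] * 10,
                            r=np.arange(1, 11) * 0.05)
        score, n_pairs = continuous_overlap(params)
        assert score == 100.0
        assert n_pairs == 45

    def test_disjoint_is_0(self):
        params = BPNMParams(n=[0.5], c=[0.1, 0.5, 0.9], r=[0.10, 0.12, 0.14])
        score, _ = continuous_overlap(params)
        assert score == 0.0

    def test_hand_case(self):
        # wider [0.0,0.4] vs narrower [0.3,0.5] -> overlap 0.1 / 0.2 = 50
        params = BPNMParams(n=[0.5], c=[0.2, 0.4], r=[0.4, 0.2])
        score, _ = continuous_overlap(params)
        assert score == pytest.approx(50.0)

    def test_all_equal_widths_undefined(self):
        params = BPNMParams(n=[0.5], c=[0.2, 0.4, 0.6], r=[0.3, 0.3, 0.3])
        score, n_pairs = continuous_overlap(params)
        assert score is None and n_pairs == 0


class TestFractionLinksPredicted:
    def test_perfect_model(self, small_net):
        mat = ProbabilityMatrix(small_net.adjacency.astype(float))
        assert fraction_links_predicted(small_net, mat) == pytest.approx(1.0, abs=1e-9)

    def test_constant_matrix_gives_p(self):
        net = BipartiteNetwork(np.array([[1, 0], [0, 1]]))
        mat = ProbabilityMatrix(np.full((2, 2), 0.5))
        assert fraction_links_predicted(net, mat) == pytest.approx(0.5)

    def test_direct_sum(self):
        net = BipartiteNetwork(np.array([[1, 0], [0, 1]]))
        mat = ProbabilityMatrix(np.array([[0.9, 0.1], [0.1, 0.7]]))
        with pytest.warns(UserWarning):  # expected links 1.8 vs observed 2
            assert fraction_links_predicted(net, mat) == pytest.approx(0.8)

    def test_monotone_in_link_probability(self):
        net = BipartiteNetwork(np.array([[1, 0], [0, 1]]))
        lo = ProbabilityMatrix(np.array([[0.5, 0.5], [0.5, 0.5]]))
        hi = ProbabilityMatrix(np.array([[0.7, 0.5], [0.5, 0.5]]))
        with pytest.warns(UserWarning):
            assert (fraction_links_predicted(net, hi)
                    > fraction_links_predicted(net, lo))


class TestConnectanceFromProbabilities:
    def test_constant(self):
        assert connectance_from_probabilities(
            ProbabilityMatrix(np.full((3, 4), 0.3))) == pytest.approx(0.3)

    def test_equals_empirical_for_binary_matrix(self, small_net):
        mat = ProbabilityMatrix(small_net.adjacency.astype(float))
        assert connectance_from_probabilities(mat) == pytest.approx(
            connectance_empirical(small_net), abs=1e-8)


class TestDegreeRRankCorrelation:
    def _net(self):
        a = np.zeros((5, 4), dtype=int)
        a[:1, 0] = 1
        a[:2, 1] = 1
        a[:3, 2] = 1
        a[:4, 3] = 1
        return BipartiteNetwork(a)

    def test_perfectly_aligned(self):
        net = self._net()
        params = BPNMParams(n=np.linspace(0, 1, 5), c=[0.5] * 4,
                            r=[0.1, 0.2, 0.3, 0.4])
        assert degree_r_rank_correlation(net, params) == pytest.approx(1.0)

    def test_reversed(self):
        net = self._net()
        params = BPNMParams(n=np.linspace(0, 1, 5), c=[0.5] * 4,
                            r=[0.4, 0.3, 0.2, 0.1])
        assert degree_r_rank_correlation(net, params) == pytest.approx(-1.0)

    def test_matches_rank_oracle_with_ties(self, rng):
        for _ in range(100):
            deg = rng.integers(0, 5, 8)
            widths = rng.choice([0.1, 0.2, 0.3], 8)
            a = np.zeros((5, 8), dtype=int)
            for i, d in enumerate(deg):
                a[:d, i] = 1
            a[0, 0] = 1  # guarantee a link
            net = BipartiteNetwork(a)
            params = BPNMParams(n=np.linspace(0, 1, 5), c=[0.5] * 8, r=widths)
            rho = degree_r_rank_correlation(net, params)
            if len(set(net.consumer_degrees.tolist())) < 2 or len(set(widths)) < 2:
                assert rho is None
            else:
                expected = spearman_oracle(net.consumer_degrees, widths)
                assert rho == pytest.approx(expected, abs=1e-12)


class TestCDispersion:
    def test_constant_centers(self):
        params = BPNMParams(n=[0.5], c=[0.3, 0.3, 0.3], r=[0.2] * 3)
        assert c_dispersion(params) == 0.0

    def test_two_point_sample_sd(self):
        params = BPNMParams(n=[0.5], c=[0.0, 1.0], r=[0.2, 0.2])
        assert c_dispersion(params) == pytest.approx(np.sqrt(0.5))

    def test_reflection_invariant(self, rng):
        c = rng.uniform(0, 1, 10)
        a = BPNMParams(n=[0.5], c=c, r=[0.2] * 10)
        b = BPNMParams(n=[0.5], c=1 - c, r=[0.2] * 10)
        assert c_dispersion(a) == pytest.approx(c_dispersion(b), abs=1e-12)
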