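"""Euclidean and editing-penalty-cost distances.

The penalty-cost implementation is checked against two independent
routes: a naive recursive enumeration of edit scripts (exponential, no
memoization — the brute-force oracle), and edlib's C implementation of
Levenshtein distance at unit costs.
"""

from itertools import product

import edlib
import numpy as np
import pytest
from hypothesis import given
from hypothesis import strategies as st

import ethoseq as e
from ethoseq.distance import default_decimation, distance_summary
from ethoseq.errors import InsufficientData, InvalidDecimation, LengthMismatch

from conftest import make_subsequence

short_seqs = st.text(alphabet="ABC", max_size=8)


def brute_cost(a: str, b: str, sub: float = 1.0, ind: float = 1.0) -> float:
    """Exponential enumeration of all edit scripts; minimal total cost."""
    if not a:
        return len(b) * ind
    if not b:
        return len(a) * ind
    match = brute_cost(a[1:], b[1:], sub, ind) + (sub if a[0] != b[0] else 0.0)
    delete = brute_cost(a[1:], b, sub, ind) + ind
    insert = brute_cost(a, b[1:], sub, ind) + ind
    return min(match, delete, insert)


class TestEuclideanDistance:
    def test_self_distance_zero(self, rng):
        v = rng.random(144)
        assert e.euclidean_distance(v, v) == 0.0

    def test_unit_basis_vectors(self):
        a, b = np.zeros(144), np.zeros(144)
        a[0], b[1] = 1.0, 1.0
        assert e.euclidean_distance(a, b) == pytest.approx(np.sqrt(2))

    def test_matches_naive_loop(self, rng):
        for _ in range(50):
            a, b = rng.random(144), rng.random(144)
            naive = np.sqrt(sum((x - y) ** 2 for x, y in zip(a, b)))
            assert abs(e.euclidean_distance(a, b) - naive) < 1e-12

    def test_triangle_inequality(self, rng):
        for _ in range(200):
            a, b, c = rng.random((3, 20))
            assert e.euclidean_distance(a, c) <= (
                e.euclidean_distance(a, b) + e.euclidean_distance(b, c) + 1e-12
            )

    def test_length_mismatch(self):
        with pytest.raises(LengthMismatch):
            e.euclidean_distance(np.zeros(3), np.zeros(4))


class TestPenaltyCost:
    def test_worked_example_totals_17(self):
        res = e.penalty_cost("555444455555", "88886666666666666")
        assert res.cost == 17
        assert res.n_substitutions == 12
        assert res.n_indels == 5

    @given(s=short_seqs)
    def test_identity(self, s):
        assert e.penalty_cost(s, s).cost == 0

    def test_empty_sequences(self):
        assert e.penalty_cost("", "ABCA").cost == 4
        assert e.penalty_cost("AB", "").cost == 2
        assert e.penalty_cost("", "").cost == 0

    def test_exhaustive_vs_brute_force_short(self):
        # every pair of sequences of length <= 3 over a 3-letter alphabet
        seqs = ["".join(t) for n in range(4) for t in product("ABC", repeat=n)]
        for a in seqs:
            for b in seqs:
                assert e.penalty_cost(a, b).cost == brute_cost(a, b)

    def test_random_pairs_vs_brute_force(self, rng):
        for _ in range(150):
            a = "".join(rng.choice(list("ABC"), rng.integers(4, 7)))
            b = "".join(rng.choice(list("ABC"), rng.integers(4, 7)))
            assert e.penalty_cost(a, b).cost == brute_cost(a, b)

    def test_weighted_costs_vs_brute_force(self, rng):
        for _ in range(60):
            a = "".join(rng.choice(list("ABC"), rng.integers(0, 6)))
            b = "".join(rng.choice(list("ABC"), rng.integers(0, 6)))
            got = e.penalty_cost(a, b, sub_cost=2.0, indel_cost=1.0)
            assert got.cost == brute_cost(a, b, sub=2.0, ind=1.0)
            # reported script reproduces the reported cost
            assert got.cost == got.n_substitutions * 2.0 + got.n_indels * 1.0

    def test_unit_costs_match_edlib(self, rng):
        for _ in range(1000):
            a = "".join(rng.choice(list("ABCDE"), rng.integers(0, 30)))
            b = "".join(rng.choice(list("ABCDE"), rng.integers(0, 30)))
            expected = edlib.align(a, b)["editDistance"]
            assert e.penalty_cost(a, b).cost == expected

    def test_metric_axioms_random_pairs(self, rng):
        # identity, symmetry, triangle inequality at unit costs
        def rand_seq():
            return "".join(rng.choice(list("ABCD"), rng.integers(0, 10)))

        for _ in range(1000):
            a, b = rand_seq(), rand_seq()
            dab = e.penalty_cost(a, b).cost
            assert dab == e.penalty_cost(b, a).cost
            assert (dab == 0) == (a == b)
        for _ in range(300):
            a, b, c = rand_seq(), rand_seq(), rand_seq()
            assert e.penalty_cost(a, c).cost <= (
                e.penalty_cost(a, b).cost + e.penalty_cost(b, c).cost
            )

    def test_cost_bounded_by_longer_length(self, rng):
        for _ in range(100):
            a = "".join(rng.choice(list("AB"), rng.integers(0, 12)))
            b = "".join(rng.choice(list("AB"), rng.integers(0, 12)))
            assert e.penalty_cost(a, b).cost <= max(len(a), len(b))


class TestEncodeForPC:
    def test_per_bout_collapses_runs(self):
        sub = make_subsequence(["SM"] * 5 + ["SR"] * 3)
        assert e.encode_for_pc(sub, mode="per_bout") == ["SM", "SR"]

    def test_decimate_1_equals_per_frame(self):
        sub = make_subsequence(["SM", "SM", "GM", "SR"])
        assert e.encode_for_pc(sub, mode="decimate", k=1) == e.encode_for_pc(
            sub, mode="per_frame"
        )

    def test_decimate_window_count(self):
        sub = make_subsequence(["GM"] * 100)
        assert len(e.encode_for_pc(sub, mode="decimate", k=10)) == 10

    def test_decimate_majority_label(self):
        sub = make_subsequence(["GM", "GM", "SM", "GM", "SR", "SR", "SR", "SM"])
        assert e.encode_for_pc(sub, mode="decimate", k=4) == ["GM", "SR"]

    def test_decimate_tie_takes_earliest(self):
        sub = make_subsequence(["SM", "GM", "SM", "GM"])
        assert e.encode_for_pc(sub, mode="decimate", k=4) == ["SM"]

    def test_invalid_k(self):
        sub = make_subsequence(["GM"])
        with pytest.raises(InvalidDecimation):
            e.encode_for_pc(sub, mode="decimate", k=0)

    def test_default_decimation_bounds_length(self, small_subsequences):
        k = default_decimation(small_subsequences, max_symbols=500)
        assert all(
            len(e.encode_for_pc(s, mode="decimate", k=k)) <= 500
            for s in small_subsequences
        )


class TestDistanceDistributions:
    def test_identical_vectors_intra_zero(self):
        v = np.full(144, 1 / 144)
        pairs = e.pairwise_distance_distributions({0: [v.copy() for _ in range(4)]})
        intra = pairs[pairs["group_pair"] == "0:0"]
        assert len(intra) == 6  # k(k-1)/2
        assert np.all(intra["value"] == 0)

    def test_pair_counts_combinatorial(self, rng):
        groups = {0: [rng.random(10) for _ in range(4)], 1: [rng.random(10) for _ in range(3)]}
        pairs = e.pairwise_distance_distributions(groups)
        n = pairs.groupby("group_pair").size()
        assert n["0:0"] == 6 and n["1:1"] == 3 and n["0:1"] == 12

    def test_disjoint_support_inter_exceeds_intra(self, rng):
        a = [np.concatenate([rng.random(5), np.zeros(5)]) for _ in range(5)]
        b = [np.concatenate([np.zeros(5), rng.random(5)]) for _ in range(5)]
        summary = distance_summary(
            e.pairwise_distance_distributions({0: a, 1: b})
        ).set_index("group_pair")["mean"]
        assert summary["0:1"] > summary["0:0"]
        assert summary["0:1"] > summary["1:1"]

    def test_insufficient_group(self, rng):
        with pytest.raises(InsufficientData):
            e.pairwise_distance_distributions({0: [rng.random(5)]})

    def test_pc_identical_subsequences_zero(self):
        subs = [make_subsequence(["SM", "GM", "SM"]) for _ in range(3)]
        pairs = e.pc_distributions({0: subs}, mode="per_bout")
        assert np.all(pairs["value"] == 0)

    def test_pc_symmetric(self, rng):
        subs = [
            make_subsequence(list(rng.choice(["SM", "GM", "SR"], rng.integers(3, 15))))
            for _ in range(8)
        ]
        for _ in range(100):
            i, j = rng.integers(0, 8, 2)
            a = e.encode_for_pc(subs[i], mode="per_bout")
            b = e.encode_for_pc(subs[j], mode="per_bout")
            assert e.penalty_cost(a, b).cost == e.penalty_cost(b, a).cost

    def test_normalized_pc_in_unit_range(self, small_subsequences):
        by_state = {}
        for s in small_subsequences:
            by_state.setdefault(s.feed_state, []).append(s)
        by_state = {k: v[:4] for k, v in by_state.items() if len(v) >= 2}
        pairs = e.pc_distributions(by_state, mode="per_bout", normalize=True)
        assert pairs["value"].between(0, 1).all()
        assert (pairs["metric"] == "penalty_cost_normalized").all()
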