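"""Transition matrices, vectorization, regime blocks and densities."""

import numpy as np
import pytest
from scipy import stats

import ethoseq as e
from ethoseq.errors import InsufficientData, WrongLength
from ethoseq.vocab import CODES, HUNTING, INDEX, N_BEHAVIORS

from conftest import make_subsequence


def naive_pair_counts(behaviors):
    """Independent O(n) oracle: count consecutive pairs of a bout list."""
    m = np.zeros((N_BEHAVIORS, N_BEHAVIORS), dtype=int)
    for a, b in zip(behaviors, behaviors[1:]):
        m[INDEX[a], INDEX[b]] += 1
    return m


class TestCountTransitions:
    def test_three_bout_example(self):
        sub = make_subsequence(["SM", "SM", "SR", "SM"])
        counts = e.count_transitions(sub, include_reset=False)
        expected = np.zeros((12, 12), dtype=int)
        expected[INDEX["SM"], INDEX["SR"]] = 1
        expected[INDEX["SR"], INDEX["SM"]] = 1
        assert np.array_equal(counts, expected)

    def test_capture_adds_reset_transition(self):
        sub = make_subsequence(["SM", "SS"])
        sub.termination = "capture"
        counts = e.count_transitions(sub, include_reset=True)
        assert counts[INDEX["SM"], INDEX["SS"]] == 1
        assert counts[INDEX["SS"], INDEX["RESET"]] == 1
        assert counts.sum() == 2

    def test_timeout_adds_no_reset(self):
        sub = make_subsequence(["SM", "GM"])
        counts = e.count_transitions(sub, include_reset=True)
        assert counts[:, INDEX["RESET"]].sum() == 0

    def test_single_bout_zero_matrix(self):
        sub = make_subsequence(["GM"] * 5)
        assert e.count_transitions(sub, include_reset=False).sum() == 0

    def test_matches_naive_oracle_on_synthetic(self, small_subsequences):
        for sub in small_subsequences:
            bouts = [b.behavior for b in e.run_length_encode(sub)]
            counts = e.count_transitions(sub, include_reset=False)
            assert np.array_equal(counts, naive_pair_counts(bouts))
            # count conservation: transitions = bouts - 1
            assert counts.sum() == len(bouts) - 1

    def test_default_diagonal_is_zero(self, small_subsequences):
        for sub in small_subsequences:
            counts = e.count_transitions(sub, include_reset=True)
            assert np.diag(counts).sum() == 0

    def test_per_frame_mode_counts_dwell(self):
        sub = make_subsequence(["GM", "GM", "GM", "SM"])
        counts = e.count_transitions(sub, include_reset=False, per_frame=True)
        assert counts[INDEX["GM"], INDEX["GM"]] == 2
        assert counts[INDEX["GM"], INDEX["SM"]] == 1
        assert counts.sum() == 3


class TestNormalize:
    def test_row_division(self):
        counts = np.zeros((12, 12))
        counts[0, 1] = 2
        counts[0, 11] = 2
        probs = e.normalize(counts)
        assert probs[0, 1] == 0.5
        assert probs[0, 11] == 0.5

    def test_zero_rows_stay_zero(self):
        probs = e.normalize(np.zeros((12, 12)))
        assert np.all(probs == 0)

    def test_row_sums_binary(self, small_subsequences):
        for sub in small_subsequences:
            probs = e.normalize(e.count_transitions(sub))
            sums = probs.sum(axis=1)
            assert np.all((np.abs(sums - 1) < 1e-9) | (sums == 0))


class TestVectorize:
    def test_round_trip_random(self, rng):
        for _ in range(100):
            m = rng.random((12, 12))
            assert np.array_equal(e.unvectorize(e.vectorize(m)), m)

    def test_fixed_index_position(self):
        # P(ST -> SS) sits at row-major index 2*12 + 0 = 24
        m = np.zeros((12, 12))
        m[INDEX["ST"], INDEX["SS"]] = 0.7
        v = e.vectorize(m)
        assert v[24] == 0.7
        assert np.count_nonzero(v) == 1

    def test_zero_matrix(self):
        assert np.all(e.vectorize(np.zeros((12, 12))) == 0)

    def test_wrong_length_rejected(self):
        with pytest.raises(WrongLength):
            e.unvectorize(np.zeros(143))
        with pytest.raises(WrongLength):
            e.vectorize(np.zeros((11, 12)))


class TestRegimeBlocks:
    def test_sizes_and_disjointness(self):
        blocks = e.regime_blocks()
        sizes = {k: len(v) for k, v in blocks.items()}
        # 5 hunting codes; nonhunting side = GM + 5 nonhunting codes
        assert sizes == {"HH": 25, "HN": 30, "NH": 30, "NN": 36}
        allidx = np.concatenate(list(blocks.values()))
        assert len(np.unique(allidx)) == len(allidx)
        # the 23 excluded cells are exactly the RESET row and column
        excluded = set(range(144)) - set(allidx.tolist())
        reset = INDEX["RESET"]
        expected = {reset * 12 + j for j in range(12)} | {i * 12 + reset for i in range(12)}
        assert excluded == expected

    def test_gm_side_is_configurable(self):
        blocks = e.regime_blocks(gm_as_nonhunting=False)
        assert {k: len(v) for k, v in blocks.items()} == {"HH": 25, "HN": 25, "NH": 25, "NN": 25}

    def test_pure_hunting_mass_in_hh(self):
        sub = make_subsequence(["SM", "SR", "ST", "SM", "SR"])
        v = e.vectorize(e.normalize(e.count_transitions(sub, include_reset=False)))
        vals = e.block_values(v)
        assert vals["HH"].sum() > 0
        for name in ("HN", "NH", "NN"):
            assert vals[name].sum() == 0

    def test_sated_states_shift_mass_out_of_hunting(self):
        # simulated sated datasets put more mass in hunting->nonhunting
        # cells than starved datasets (heat-map trend on known truth)
        ds = e.simulate_dataset(n_animals=3, seed=2, trial_duration_s=180.0)
        vecs = e.feature_vectors_by_state(ds.subsequences())
        hn0 = np.mean(e.pooled_block_values(vecs[0])["HN"])
        hn4 = np.mean(e.pooled_block_values(vecs[4])["HN"])
        assert hn4 > hn0

    def test_nh_mass_near_zero_on_defaults(self, small_subsequences):
        # regime re-entry from nonhunting behaviors proper (GM excluded:
        # neutral monitoring is allowed to lead back into hunting) is
        # rare, and the full NH distribution concentrates at zero
        vecs = e.feature_vectors_by_state(small_subsequences)
        blocks_no_gm = e.regime_blocks(gm_as_nonhunting=False)
        pure, full = [], []
        for state_vecs in vecs.values():
            for v in state_vecs:
                pure.append(e.block_values(v, blocks_no_gm)["NH"])
                full.append(e.block_values(v)["NH"])
        assert np.mean(np.concatenate(pure)) < 0.01
        full = np.concatenate(full)
        assert np.median(full) == 0.0
        assert np.mean(full < 0.1) > 0.9


class TestBlockDensity:
    def test_integral_is_one(self, rng):
        for vals in (rng.random(200), rng.beta(0.3, 3, 300), np.array([0.25] * 50)):
            grid, dens = e.block_density(vals)
            assert np.trapezoid(dens, grid) == pytest.approx(1.0, abs=1e-3)

    def test_concentrates_at_common_value(self):
        grid, dens = e.block_density(np.full(40, 0.3))
        assert abs(grid[np.argmax(dens)] - 0.3) < 0.02

    def test_uniform_sample_roughly_flat(self, rng):
        vals = rng.random(10_000)
        grid, dens = e.block_density(vals)
        # empirical CDF from the density vs the uniform CDF
        cdf = np.concatenate(([0.0], np.cumsum((dens[1:] + dens[:-1]) / 2 * np.diff(grid))))
        assert np.max(np.abs(cdf - grid)) < 0.05

    def test_insufficient_data(self):
        with pytest.raises(InsufficientData):
            e.block_density([0.5])


class TestTransitionsInto:
    def test_single_subsequence_column_sums(self):
        sub = make_subsequence(["SM", "SM", "SR", "SM"])
        into = e.transitions_into([e.count_transitions(sub, include_reset=False)])
        assert into["SM"] == 1
        assert into["SR"] == 1
        assert into.sum() == 2

    def test_totals_conserved(self, small_subsequences):
        counts = [e.count_transitions(s) for s in small_subsequences]
        into = e.transitions_into(counts)
        assert into.sum() == sum(c.sum() for c in counts)
        assert list(into.index) == list(CODES)

    def test_matches_naive_oracle(self, small_subsequences):
        counts = [e.count_transitions(s, include_reset=False) for s in small_subsequences]
        into = e.transitions_into(counts)
        naive = np.zeros(N_BEHAVIORS, dtype=int)
        for sub in small_subsequences:
            bouts = [b.behavior for b in e.run_length_encode(sub)]
            for b in bouts[1:]:
                naive[INDEX[b]] += 1
        assert np.array_equal(into.to_numpy(), naive)


class TestEstimatorConsistency:
    def test_pooled_normalized_counts_recover_generator(self):
        p = e.default_params(1)
        rng = np.random.default_rng(13)
        counts = np.zeros((12, 12), dtype=np.int64)
        nbouts = 0
        while nbouts < 300:
            sub = e.simulate_subsequence(p, rng)
            counts += e.count_transitions(sub, include_reset=True)
            nbouts += len(e.run_length_encode(sub))
        est = e.normalize(counts)
        true = p.observed_transition_matrix(include_reset=True)
        off = ~np.eye(12, dtype=bool)
        assert np.abs(est - true)[off].mean() < 0.05
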