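"""State assignment, transition counting, matrix estimation and MC sampling."""

import io

import numpy as np
import pytest
import scipy.sparse as sp
from hypothesis import given, strategies as st

from ionmdmc.markov import (MarkovChain, StateGrid, assign_states,
                            chain_occupancy, count_transitions,
                            estimate_matrix, load_matrix, run_mc,
                            save_matrix, stationary_distribution)
from ionmdmc.trajectory import Trajectory


def matrix_from_rows(rows, grid=None, lag=1):
    rows = np.asarray(rows, dtype=float)
    n = rows.shape[0]
    if grid is None:
        grid = StateGrid((2,), 1.0, (1.0, 1.0, float(n)))
    counts = sp.csr_matrix(rows)
    from ionmdmc.markov import TransitionCounts
    return estimate_matrix(TransitionCounts(grid, lag, counts))


def brute_force_counts(seqs, n, lag=1):
    """Independent double-loop pair enumeration oracle."""
    out = np.zeros((n, n), dtype=int)
    for seq in np.atleast_2d(seqs):
        for t in range(len(seq) - lag):
            out[seq[t], seq[t + lag]] += 1
    return out


class TestAssignStates:
    def test_static_particle_constant_sequence(self):
        grid = StateGrid((2,), 0.5, (10.0, 10.0, 10.0))
        pos = np.tile(np.array([[[1.0, 1.0, 3.3]]]), (5, 1, 1))
        traj = Trajectory(pos, ["A"], (10.0, 10.0, 10.0))
        seq = assign_states(traj, grid)
        assert seq.shape == (1, 5)
        assert np.all(seq == 6)  # floor(3.3 / 0.5)

    def test_exact_bin_edge_rounds_up(self):
        grid = StateGrid((2,), 0.5, (10.0, 10.0, 10.0))
        pos = np.array([[[0.0, 0.0, 2.5]]])
        traj = Trajectory(pos, ["A"], (10.0, 10.0, 10.0))
        assert assign_states(traj, grid)[0, 0] == 5

    def test_hand_built_toy_sequences(self, toy_trajectory):
        # 1D grid on x, bin 0.5: floor(x / 0.5) per frame per particle
        grid = StateGrid((0,), 0.5, toy_trajectory.box)
        seq = assign_states(traj=toy_trajectory, grid=grid)
        assert seq.tolist() == [[0, 1, 1, 0], [10, 10, 10, 10]]

    def test_2d_grid_row_major_indexing(self, toy_trajectory):
        grid = StateGrid((2, 0), 0.5, toy_trajectory.box)
        seq = assign_states(toy_trajectory, grid)
        # particle 0 frame 0: z-bin 0, x-bin 0 -> 0*20 + 0
        assert seq[0, 0] == 0
        # particle 1 frame 0: z-bin 10, x-bin 10 -> 10*20 + 10
        assert seq[1, 0] == 210

    def test_out_of_box_coordinate_rejected(self):
        grid = StateGrid((2,), 0.5, (10.0, 10.0, 10.0))
        pos = np.array([[[0.0, 0.0, 12.5]]])
        traj = Trajectory(pos, ["A"], (10.0, 10.0, 10.0))
        with pytest.raises(ValueError, match="outside"):
            assign_states(traj, grid)


class TestCountTransitions:
    GRID = StateGrid((2,), 1.0, (1.0, 1.0, 5.0))

    def test_single_recorded_transition(self):
        c = count_transitions(np.array([[1, 2]]), self.GRID)
        assert c.counts[1, 2] == 1
        assert c.total == 1

    def test_constant_sequence_self_transitions(self):
        c = count_transitions(np.full((1, 7), 3), self.GRID)
        assert c.counts[3, 3] == 6
        assert c.total == 6

    def test_total_equals_particles_times_frames_minus_lag(self):
        rng = np.random.default_rng(0)
        seqs = rng.integers(0, 5, size=(4, 50))
        for lag in (1, 3):
            c = count_transitions(seqs, self.GRID, lag=lag)
            assert c.total == 4 * (50 - lag)

    @given(st.integers(0, 2 ** 31 - 1), st.integers(1, 3))
    def test_matches_brute_force_enumeration(self, seed, lag):
        rng = np.random.default_rng(seed)
        seqs = rng.integers(0, 5, size=(2, 200))
        c = count_transitions(seqs, self.GRID, lag=lag)
        assert np.array_equal(c.counts.toarray(),
                              brute_force_counts(seqs, 5, lag))


class TestEstimateMatrix:
    def test_row_normalization(self):
        T = matrix_from_rows([[2, 2, 0, 4], [1, 0, 0, 0],
                              [0, 0, 1, 1], [1, 1, 1, 1]])
        assert T.probabilities[0].toarray().ravel().tolist() == \
            [0.25, 0.25, 0.0, 0.5]

    def test_unvisited_row_self_loop(self):
        T = matrix_from_rows([[1, 1, 0], [0, 0, 0], [0, 1, 1]])
        assert T.probabilities[1, 1] == 1.0
        assert not T.visited[1]

    def test_restrict_policy_compacts_indices(self):
        rows = np.zeros((4, 4))
        rows[0, 2] = 3
        rows[2, 0] = 2
        from ionmdmc.markov import TransitionCounts
        grid = StateGrid((2,), 1.0, (1.0, 1.0, 4.0))
        T = estimate_matrix(TransitionCounts(grid, 1, sp.csr_matrix(rows)),
                            empty_policy="restrict")
        assert T.n == 2
        assert T.active.tolist() == [0, 2]
        assert T.probabilities[0, 1] == 1.0

    def test_all_zero_counts_rejected(self):
        from ionmdmc.markov import TransitionCounts
        grid = StateGrid((2,), 1.0, (1.0, 1.0, 3.0))
        with pytest.raises(ValueError, match="zero"):
            estimate_matrix(TransitionCounts(grid, 1,
                                             sp.csr_matrix((3, 3))))

    @given(st.integers(0, 2 ** 31 - 1))
    def test_rows_sum_to_one(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.integers(0, 10, size=(8, 8))
        if rows.sum() == 0:
            rows[0, 0] = 1
        T = matrix_from_rows(rows)
        assert T.row_sum_error() < 1e-12


class TestRunMc:
    def test_deterministic_two_cycle(self):
        T = matrix_from_rows([[0, 1], [1, 0]])
        chain = run_mc(T, 100, initial=0, seed=0)
        assert np.array_equal(chain.states[::2], np.zeros(51))
        assert np.array_equal(chain.states[1::2], np.ones(50))
        occ = np.bincount(chain.states[:-1], minlength=2) / 100
        assert occ.tolist() == [0.5, 0.5]

    def test_absorbing_state(self):
        T = matrix_from_rows([[1, 0], [0.5, 0.5]])
        chain = run_mc(T, 50, initial=0, seed=1)
        assert np.all(chain.states == 0)

    def test_two_state_occupancy_closed_form(self):
        a, b = 0.2, 0.1
        T = matrix_from_rows([[1 - a, a], [b, 1 - b]])
        chain = run_mc(T, 1_000_000, initial=0, seed=2)
        occ1 = (chain.states == 1).mean()
        assert occ1 == pytest.approx(a / (a + b), abs=0.01)

    def test_seed_determinism_and_length(self):
        T = matrix_from_rows([[1, 2, 3], [3, 2, 1], [1, 1, 1]])
        c1 = run_mc(T, 1000, initial=1, seed=5)
        c2 = run_mc(T, 1000, initial=1, seed=5)
        assert np.array_equal(c1.states, c2.states)
        assert len(c1.states) == 1001

    def test_restricted_initial_state_must_be_active(self):
        rows = np.zeros((3, 3))
        rows[0, 0] = 1
        from ionmdmc.markov import TransitionCounts
        grid = StateGrid((2,), 1.0, (1.0, 1.0, 3.0))
        T = estimate_matrix(TransitionCounts(grid, 1, sp.csr_matrix(rows)),
                            empty_policy="restrict")
        with pytest.raises(ValueError, match="removed"):
            run_mc(T, 10, initial=2, seed=0)


class TestStationary:
    def test_identity_matrix_uniform_start_stays_uniform(self):
        T = matrix_from_rows(np.eye(4))
        pi = stationary_distribution(T)
        assert pi == pytest.approx(np.full(4, 0.25))

    def test_two_state_closed_form(self):
        a, b = 0.2, 0.1
        T = matrix_from_rows([[1 - a, a], [b, 1 - b]])
        pi = stationary_distribution(T)
        assert pi == pytest.approx([b / (a + b), a / (a + b)], abs=1e-10)

    def test_periodic_chain_converges_via_damping(self):
        T = matrix_from_rows([[0, 1], [1, 0]])
        pi = stationary_distribution(T)
        assert pi == pytest.approx([0.5, 0.5], abs=1e-10)

    @pytest.mark.parametrize("seed", range(10))
    def test_fixed_point_residual_random_matrices(self, seed):
        rng = np.random.default_rng(seed)
        rows = rng.random((12, 12)) + 0.01
        T = matrix_from_rows(rows)
        pi = stationary_distribution(T)
        residual = np.abs(T.probabilities.T @ pi - pi).sum()
        assert residual < 1e-10


class TestChainOccupancy:
    def test_alternating_chain_split(self):
        grid = StateGrid((2,), 1.0, (1.0, 1.0, 2.0))
        states = np.tile([0, 1], 51)[:101]  # 100 steps
        chain = MarkovChain(states, step_time=1.0)
        f = chain_occupancy(chain, grid)
        assert f.mode == "accumulated"
        assert sorted(f.values.tolist()) == [50, 51]

    def test_zero_step_chain_counts_initial_state(self):
        grid = StateGrid((2,), 1.0, (1.0, 1.0, 3.0))
        chain = MarkovChain(np.array([2]), step_time=1.0)
        f = chain_occupancy(chain, grid)
        assert f.values.tolist() == [0, 0, 1]

    def test_layout_matches_density_fields(self, free_trajectory):
        from ionmdmc.fields import density
        grid = StateGrid((2,), 1.0, free_trajectory.box)
        seq = assign_states(free_trajectory, grid, "X")
        counts = np.bincount(seq.ravel(), minlength=grid.n_states)
        d = density(free_trajectory, "X", axes=2, bin_size=1.0)
        assert np.array_equal(counts.astype(float), d.values)


class TestPersistence:
    def test_matrix_roundtrip(self):
        rng = np.random.default_rng(3)
        rows = rng.integers(0, 5, size=(6, 6))
        rows[2] = 0  # leave an unvisited state
        T = matrix_from_rows(rows, grid=StateGrid((2, 0), 0.5,
                                                  (3.0, 1.0, 3.0)))
        buf = io.StringIO()
        save_matrix(T, buf)
        buf.seek(0)
        back = load_matrix(buf)
        assert back.grid.axes == T.grid.axes
        assert back.grid.bin_size == T.grid.bin_size
        assert back.lag == T.lag
        assert np.allclose(back.probabilities.toarray(),
                           T.probabilities.toarray())
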