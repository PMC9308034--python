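"""Displacement engine: picking, rounds, removals and the two scenarios."""

import numpy as np
import pytest
from scipy import stats

import carenet as cn
from carenet.errors import ConfigurationError, ValidationError
from carenet.simulation import LOST, PLACED, SEARCHING
from conftest import make_system


def line_system(C, N, weights=None):
    """Path graph a-b-c-... with given capacities/loads, co-located."""
    n = len(C)
    W = np.zeros((n, n))
    for i in range(n - 1):
        W[i, i + 1] = W[i + 1, i] = (weights[i] if weights else 1)
    return make_system(W, C, N)


class TestInitialize:
    def test_counts_and_free_capacity(self):
        system = line_system(C=[5], N=[3])
        state = cn.initialize(system)
        assert state.n_located() == 3
        assert state.free_capacity_by_state().sum() == 2

    def test_total_patients_conserved_at_start(self):
        system = line_system(C=[5, 6, 7], N=[2, 3, 4])
        state = cn.initialize(system)
        assert state.n_located() == 9
        assert state.n_searching() == state.n_lost() == 0

    def test_empty_network_rejected(self):
        import networkx as nx
        import pandas as pd
        system = cn.compile_system(
            nx.Graph(),
            pd.DataFrame(columns=["physician_id", "N", "C"]),
            pd.DataFrame({"municipality_id": ["10001"],
                          "lat": [47.0], "lon": [13.0]}))
        with pytest.raises(ValidationError):
            cn.initialize(system)

    def test_overfull_physician_rejected(self):
        system = line_system(C=[2], N=[3])
        with pytest.raises(ValidationError):
            cn.initialize(system)


class TestPickNewPhysician:
    def setup_state(self, alpha=0.0, W=None, C=(5, 5, 5), N=(1, 1, 1)):
        if W is None:
            W = [[0, 3, 1], [3, 0, 0], [1, 0, 0]]
        system = make_system(np.array(W, dtype=float), list(C), list(N))
        state = cn.initialize(system)
        params = cn.SimulationParams(alpha=alpha)
        return system, state, params

    def test_weight_proportional_sampling(self):
        # neighbours of node 0 have weights {1: 3, 2: 1} -> P = 0.75 / 0.25
        system, state, params = self.setup_state()
        cn.remove_physician(state, 0)
        rng = np.random.default_rng(12345)
        patient = int(np.flatnonzero(state.pat_status == SEARCHING)[0])
        draws = np.array([cn.pick_new_physician(state, patient, params, rng)
                          for _ in range(10000)])
        counts = np.bincount(draws, minlength=3)[1:]
        p = stats.chisquare(counts, f_exp=[7500, 2500]).pvalue
        assert p > 0.001

    def test_single_available_neighbour_is_certain(self):
        system, state, params = self.setup_state(W=[[0, 2, 0], [2, 0, 0],
                                                    [0, 0, 0]])
        cn.remove_physician(state, 0)
        rng = np.random.default_rng(0)
        patient = int(np.flatnonzero(state.pat_status == SEARCHING)[0])
        assert all(cn.pick_new_physician(state, patient, params, rng) == 1
                   for _ in range(50))

    def test_alpha_one_uniform_regardless_of_weights(self):
        system, state, params = self.setup_state(alpha=1.0)
        cn.remove_physician(state, 0)
        rng = np.random.default_rng(99)
        patient = int(np.flatnonzero(state.pat_status == SEARCHING)[0])
        draws = np.array([cn.pick_new_physician(state, patient, params, rng)
                          for _ in range(10000)])
        counts = np.bincount(draws, minlength=3)[1:]
        # uniform over the two remaining available physicians
        p = stats.chisquare(counts, f_exp=[5000, 5000]).pvalue
        assert p > 0.001

    def test_no_available_neighbour_returns_no_candidate(self):
        system, state, params = self.setup_state(W=[[0, 2, 0], [2, 0, 0],
                                                    [0, 0, 0]])
        cn.remove_physician(state, 1)   # node 0's only neighbour
        cn.remove_physician(state, 0)
        rng = np.random.default_rng(0)
        patient = 0   # recent physician is 0, whose neighbour 1 is gone
        assert cn.pick_new_physician(state, patient, params, rng) == -1

    def test_distance_rule_keeps_last_candidate_after_retries(self):
        # the only neighbour is 200 km away with d=100: ten redraws fail,
        # the last candidate is kept anyway
        W = np.array([[0, 1], [1, 0]], dtype=float)
        system = make_system(
            W, C=[5, 5], N=[1, 0], munis=["10001", "20001"],
            coords={"10001": (47.0, 13.0), "20001": (47.0, 15.64)})
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        params = cn.SimulationParams(d=100.0)
        rng = np.random.default_rng(0)
        assert cn.pick_new_physician(state, 0, params, rng) == 1


class TestDisplacementRound:
    def test_hand_simulated_bottleneck(self):
        # ten searching patients, a single neighbour with free capacity 3,
        # s=2: three are placed, the rest lost after two rounds
        system = line_system(C=[10, 5], N=[10, 2])
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        params = cn.SimulationParams(s=2)
        rng = np.random.default_rng(4)
        cn.run_to_quiescence(state, params, rng)
        assert state.n_located() == 2 + 3
        assert state.n_lost() == 7

    def test_no_searching_patients_is_fixed_point(self):
        system = line_system(C=[5, 5], N=[2, 2])
        state = cn.initialize(system)
        before = (state.count.copy(), state.pat_status.copy())
        cn.displacement_round(state, cn.SimulationParams(),
                              np.random.default_rng(0))
        assert np.array_equal(state.count, before[0])
        assert np.array_equal(state.pat_status, before[1])

    def test_ample_capacity_places_everyone_in_one_round(self):
        system = line_system(C=[10, 20], N=[8, 2])
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        cn.displacement_round(state, cn.SimulationParams(),
                              np.random.default_rng(0))
        assert state.n_searching() == 0 and state.n_lost() == 0
        assert state.count[1] == 10

    def test_rejection_counter_resets_after_placement(self):
        system = line_system(C=[10, 20], N=[5, 2])
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        cn.run_to_quiescence(state, cn.SimulationParams(),
                             np.random.default_rng(0))
        placed = state.pat_status == PLACED
        assert (state.pat_rejections[placed] == 0).all()


class TestRemovePhysician:
    def test_removing_empty_physician_drops_free_capacity_only(self):
        system = line_system(C=[5, 5], N=[0, 3])
        state = cn.initialize(system)
        fc0 = state.free_capacity_by_state().sum()
        cn.remove_physician(state, 0)
        assert state.n_searching() == 0
        assert state.free_capacity_by_state().sum() == fc0 - 5

    def test_removal_sets_patients_searching(self):
        system = line_system(C=[5, 5], N=[4, 0])
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        assert state.n_searching() == 4

    def test_double_removal_rejected(self):
        system = line_system(C=[5, 5], N=[1, 1])
        state = cn.initialize(system)
        cn.remove_physician(state, 0)
        with pytest.raises(ValidationError):
            cn.remove_physician(state, 0)


class TestIterativeRemoval:
    def small_system(self):
        W = np.array([[0, 2, 1, 0], [2, 0, 3, 1], [1, 3, 0, 2],
                      [0, 1, 2, 0]], dtype=float)
        return make_system(W, C=[6, 6, 6, 6], N=[3, 4, 2, 3])

    def test_trajectory_length_until_one_remains(self):
        traj = cn.run_iterative_removal(self.small_system(),
                                        cn.SimulationParams(seed=1))
        assert traj.frac_removed.size == 4          # initial + 3 removals
        assert traj.frac_removed[-1] == pytest.approx(3 / 4)

    def test_complete_removal_loses_every_patient(self):
        traj = cn.run_iterative_removal(self.small_system(),
                                        cn.SimulationParams(seed=1),
                                        remove_all=True)
        assert traj.lost[-1].sum() == traj.total_patients

    def test_seeded_runs_identical(self):
        runs = [cn.run_iterative_removal(self.small_system(),
                                         cn.SimulationParams(seed=5))
                for _ in range(2)]
        assert np.array_equal(runs[0].lost, runs[1].lost)
        assert runs[0].removed_ids == runs[1].removed_ids

    def test_conservation_and_monotonicity(self):
        traj = cn.run_iterative_removal(self.small_system(),
                                        cn.SimulationParams(seed=3),
                                        remove_all=True)
        total = traj.total_patients
        assert all(traj.located[k].sum() + traj.lost[k].sum() == total
                   for k in range(traj.frac_removed.size))
        assert (np.diff(traj.lost.sum(axis=1)) >= 0).all()
        assert (np.diff(traj.free_capacity.sum(axis=1)) <= 0).all()

    def test_ensemble_replicates_differ_but_are_reproducible(self):
        system = self.small_system()
        params = cn.SimulationParams(seed=7)
        ens1 = cn.run_removal_ensemble(system, params, n_replicates=3)
        ens2 = cn.run_removal_ensemble(system, params, n_replicates=3)
        for a, b in zip(ens1, ens2):
            assert np.array_equal(a.lost, b.lost)
        assert any(not np.array_equal(ens1[0].lost, t.lost)
                   for t in ens1[1:])


class TestShock:
    def test_zero_shock_keeps_curve_constant(self):
        system = make_system(np.ones((3, 3)) - np.eye(3),
                             C=[5, 5, 5], N=[3, 3, 3])
        res = cn.run_shock(system, cn.SimulationParams(seed=1), 0.0)
        assert (res.located == 9).all()
        assert res.n_removed == 0

    def test_step_zero_accounting_identity(self):
        system = make_system(np.ones((4, 4)) - np.eye(4),
                             C=[5, 5, 5, 5], N=[2, 3, 4, 5])
        params = cn.SimulationParams(seed=2)
        res = cn.run_shock(system, params, 50.0)   # floor(0.5*4) = 2 removed
        assert res.n_removed == 2
        assert res.located[0] + res.searching[0] == res.total_patients

    def test_survivor_with_ample_capacity_absorbs_in_one_round(self):
        # fully connected triangle, every physician could hold everyone:
        # whichever two are removed, all patients are placed in round one
        system = make_system(np.ones((3, 3)) - np.eye(3),
                             C=[30, 30, 30], N=[4, 4, 4])
        res = cn.run_shock(system, cn.SimulationParams(seed=3), 70.0)
        assert res.n_removed == 2
        assert res.located[1] == res.total_patients
        assert res.lost[-1] == 0

    def test_searching_after_s_rounds_become_lost(self):
        # one remaining physician with a single free slot and s=3
        system = line_system(C=[9, 3], N=[8, 2])
        res = cn.run_shock(system, cn.SimulationParams(s=3, seed=1), 50.0)
        assert res.searching[-1] == 0
        assert res.located[-1] + res.lost[-1] == res.total_patients

    def test_full_fraction_rejected(self):
        system = line_system(C=[5, 5], N=[1, 1])
        with pytest.raises(ConfigurationError):
            cn.run_shock(system, cn.SimulationParams(), 100.0)


class TestInvariantsOnRandomSystems:
    @pytest.mark.parametrize("seed", range(10))
    def test_conservation_capacity_and_monotonicity(self, seed):
        rng = np.random.default_rng(seed)
        n = int(rng.integers(2, 8))
        W = np.triu(rng.integers(0, 4, (n, n)), 1).astype(float)
        W = W + W.T
        C = rng.integers(1, 8, n)
        N = rng.integers(0, C + 1)
        system = make_system(W, C, N)
        params = cn.SimulationParams(
            s=int(rng.integers(1, 5)), alpha=float(rng.choice([0.0, 0.3])),
            seed=seed)
        state = cn.initialize(system)
        total = system.total_patients
        run_rng = np.random.default_rng(seed + 1000)
        order = run_rng.permutation(n)
        lost_prev = 0
        for victim in order:
            cn.remove_physician(state, int(victim))
            while state.n_searching() > 0:
                cn.displacement_round(state, params, run_rng)
                assert (state.n_located() + state.n_searching()
                        + state.n_lost()) == total
                avail = state.available
                assert (state.count[avail] <= system.C[avail]).all()
            assert state.n_lost() >= lost_prev
            lost_prev = state.n_lost()
        assert state.n_lost() == total
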