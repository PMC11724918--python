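import numpy as np
import pytest

import spherogen as sg
from spherogen._cpm_kernels import neighbor_offsets
from spherogen.cpm import delta_h
from spherogen.volumes import LabelVolume

from conftest import brute_force_counts


class TestNeighborOffsets:
    @pytest.mark.parametrize("order,count", [(1, 6), (2, 18), (3, 26), (4, 32)])
    def test_shell_sizes_follow_squared_distance_convention(self, order, count):
        offs = neighbor_offsets(order)
        assert len(offs) == count
        d2 = (offs**2).sum(axis=1)
        assert d2.min() >= 1 and d2.max() <= order


class TestAssignTargets:
    def test_two_cells_swap(self):
        data = np.zeros((3, 3, 3), dtype=np.int64)
        data[0, 0, 0] = 1
        data[2, 2, 2] = 2
        data[2, 2, 1] = 2
        state = sg.CPMState(data)
        v0, a0 = state.V.copy(), state.A.copy()
        sg.assign_targets(state, seed=0)
        assert state.Vt[1] == v0[2] and state.Vt[2] == v0[1]
        assert state.At[1] == a0[2] and state.At[2] == a0[1]

    def test_targets_are_a_derangement_preserving_the_multiset(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        v0, a0 = state.V.copy(), state.A.copy()
        sg.assign_targets(state, seed=5)
        cells = state.cell_labels()
        # no cell keeps its own (V, A) pair
        assert not np.any(
            (state.Vt[cells] == v0[cells]) & (state.At[cells] == a0[cells])
        )
        assert sorted(state.Vt[cells]) == sorted(v0[cells])
        assert sorted(state.At[cells]) == sorted(a0[cells])

    def test_single_cell_warns_identity(self):
        data = np.zeros((3, 3, 3), dtype=np.int64)
        data[1, 1, 1] = 1
        state = sg.CPMState(data)
        with pytest.warns(UserWarning):
            sg.assign_targets(state, seed=0)
        assert state.Vt[1] == 1


class TestHamiltonian:
    def test_single_voxel_cell_contact_energy_by_hand(self):
        # 1-voxel cell, contact order 1: 6 cell-medium face pairs
        data = np.zeros((5, 5, 5), dtype=np.int64)
        data[2, 2, 2] = 1
        state = sg.CPMState(data, contact_neighbor_order=1)
        params = sg.CPMParams(lambda_V=1.0, lambda_A=0.0, J_cc=0.0, J_cm=2.0,
                              T=1.0, contact_neighbor_order=1)
        assert sg.hamiltonian(state, params) == pytest.approx(12.0)

    def test_zero_at_targets_with_zero_contact_energies(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        params = sg.CPMParams(J_cc=0.0, J_cm=0.0)
        assert sg.hamiltonian(state, params) == 0.0

    def test_cell_medium_term_scales_linearly(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        p0 = sg.CPMParams(lambda_V=0, lambda_A=0, J_cc=0.0, J_cm=3.0)
        p1 = sg.CPMParams(lambda_V=0, lambda_A=0, J_cc=0.0, J_cm=6.0)
        assert sg.hamiltonian(state, p1) == pytest.approx(2 * sg.hamiltonian(state, p0))

    def test_cached_equals_scratch(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        params = sg.CPMParams()
        assert sg.hamiltonian(state, params) == pytest.approx(
            sg.hamiltonian(state, params, from_scratch=True)
        )


class TestMetropolis:
    def test_incremental_delta_matches_full_recompute(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        sg.assign_targets(state, seed=2)
        params = sg.CPMParams(lambda_V=3.0, lambda_A=0.5, J_cc=2.0, J_cm=7.0)
        rng = np.random.default_rng(0)
        checked = 0
        while checked < 200:
            site = tuple(int(rng.integers(n)) for n in state.lattice.shape)
            b = int(rng.integers(state.n_labels))
            if state.lattice[site] == b:
                continue
            h0 = sg.hamiltonian(state, params, from_scratch=True)
            dh = delta_h(state, params, site, b)
            after = state.copy()
            after.lattice[site] = b
            h1 = sg.hamiltonian(after, params, from_scratch=True)
            assert dh == pytest.approx(h1 - h0, rel=1e-9, abs=1e-9)
            checked += 1

    def test_caches_track_brute_force_recount(self):
        rng = np.random.default_rng(4)
        lattice = rng.integers(0, 4, size=(8, 8, 8))
        state = sg.CPMState(lattice, contact_neighbor_order=2)
        params = sg.CPMParams(lambda_V=0.5, lambda_A=0.01, J_cc=1.0, J_cm=2.0,
                              T=20.0, contact_neighbor_order=2)
        for _ in range(1500):
            sg.propose_and_apply(state, params, rng)
        offs = [tuple(o) for o in neighbor_offsets(2)]
        V, A, cc, cm = brute_force_counts(state.lattice, offs)
        assert np.array_equal(V[: state.n_labels], state.V)
        assert np.array_equal(A[: state.n_labels], state.A)
        assert cc == state.cc2 / 2
        assert cm == state.cm2 / 2
        assert state.check_consistency()

    def test_zero_delta_always_accepted(self):
        # two identical isolated cells far apart: swapping nothing relevant;
        # craft a flip with dH == 0 via symmetric configuration
        data = np.zeros((3, 3, 5), dtype=np.int64)
        data[1, 1, 1] = 1
        data[1, 1, 3] = 2
        state = sg.CPMState(data, contact_neighbor_order=1)
        params = sg.CPMParams(lambda_V=0.0, lambda_A=0.0, J_cc=0.0, J_cm=0.0,
                              T=1e-6, potts_neighbor_order=1, contact_neighbor_order=1)
        # with all weights zero every dH is 0 -> always accepted
        rng = np.random.default_rng(0)
        accepted = 0
        for _ in range(200):
            _, acc, dh = sg.propose_and_apply(state, params, rng)
            if acc:
                assert dh == 0.0
                accepted += 1
        assert accepted > 0

    def test_huge_penalty_rarely_accepted_at_low_temperature(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        params = sg.CPMParams(lambda_V=1e6, lambda_A=0.0, J_cc=0.0, J_cm=0.0, T=0.1)
        rng = np.random.default_rng(1)
        accepted = sum(
            sg.propose_and_apply(state, params, rng)[1] for _ in range(10_000)
        )
        # every real flip costs >= lambda_V; acceptance should be essentially 0
        assert accepted == 0

    def test_total_voxel_count_conserved(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        sg.assign_targets(state, seed=1)
        params = sg.CPMParams(mcs=3, seed=9)
        before = state.lattice.size
        state, _ = sg.run_mcs(state, params)
        assert state.lattice.size == before
        assert state.V.sum() == (state.lattice > 0).sum()


class TestRunMCS:
    def test_zero_mcs_is_identity(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        params = sg.CPMParams(mcs=0)
        state, snaps = sg.run_mcs(state, params, snapshot_at=[0])
        assert np.array_equal(state.lattice, small_phantom.data)
        assert snaps[0][0] == 0

    def test_reproducible_given_seed(self, small_phantom):
        results = []
        for _ in range(2):
            state = sg.CPMState.from_labels(small_phantom)
            sg.assign_targets(state, seed=3)
            state, _ = sg.run_mcs(state, sg.CPMParams(mcs=3, seed=11))
            results.append(state.lattice.copy())
        assert np.array_equal(results[0], results[1])

    def test_caches_consistent_after_run(self, small_phantom):
        state = sg.CPMState.from_labels(small_phantom)
        sg.assign_targets(state, seed=3)
        state, _ = sg.run_mcs(state, sg.CPMParams(mcs=5, seed=2))
        assert state.check_consistency()

    def test_near_minimum_start_stays_put(self, small_phantom):
        # targets = initial actuals, small J and T: the start is near an
        # energy minimum and 20 MCS barely move the cells
        state = sg.CPMState.from_labels(small_phantom)
        params = sg.CPMParams(lambda_V=2.0, lambda_A=0.1, J_cc=0.1, J_cm=0.1,
                              T=0.5, mcs=20, seed=1)
        state, _ = sg.run_mcs(state, params)
        end = state.to_labels()
        ious = [sg.cell_iou(small_phantom, end, int(l)) for l in small_phantom.labels()]
        assert np.mean(ious) > 0.95


class TestExports:
    def test_borders_are_the_label_volume(self, small_phantom):
        out = sg.export_borders(small_phantom)
        assert np.array_equal(out.data, small_phantom.data)
        assert out.data is not small_phantom.data

    def test_border_export_is_relabeling_equivariant(self, small_phantom):
        perm = {int(l): int(l) + 100 for l in small_phantom.labels()}
        remapped = small_phantom.data.copy()
        for old, new in perm.items():
            remapped[small_phantom.data == old] = new
        out = sg.export_borders(LabelVolume(remapped))
        assert np.array_equal(out.data, remapped)

    def test_membrane_of_two_touching_single_voxels(self):
        data = np.zeros((3, 3, 4), dtype=np.int64)
        data[1, 1, 1] = 1
        data[1, 1, 2] = 2
        mem = sg.rasterize_membrane(LabelVolume(data))
        assert mem.data[1, 1, 1] == 1 and mem.data[1, 1, 2] == 1
        assert mem.data.sum() == 2

    def test_membrane_of_solid_block_is_its_shell(self):
        data = np.zeros((5, 5, 5), dtype=np.int64)
        data[1:4, 1:4, 1:4] = 7
        mem = sg.rasterize_membrane(LabelVolume(data))
        assert mem.data[2, 2, 2] == 0
        assert mem.data.sum() == 26

    def test_membrane_of_medium_is_empty(self):
        mem = sg.rasterize_membrane(LabelVolume(np.zeros((4, 4, 4), int)))
        assert mem.data.sum() == 0
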