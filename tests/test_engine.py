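"""Stochastic assembly engine: conservation, exclusion, reproducibility."""

import numpy as np
import pytest

from pscapsid import (
    KineticParams,
    MoveSet,
    RNAVariant,
    SimState,
    eligible_events,
    extract_path,
    is_pseudo_hamiltonian,
    run_assembly,
)
from pscapsid._kernels import _rna_propensity


@pytest.fixture(scope="module")
def small_run(lattice):
    params = KineticParams(t_max=4.0e5, quiesce_window=1.0e5)
    return run_assembly(
        RNAVariant.uniform(-9.0), params, MoveSet([2, 3, 4, 5]),
        seed=11, n_rna=60, lattice=lattice,
    )


class TestRunAssembly:
    def test_cp_conservation(self, small_run):
        state = small_run.final_state
        assert state.cp_accounted() == 60 * 60  # cp_per_rna * n_rna

    def test_partial_paths_contiguous_and_exclusion_free(self, lattice, small_run):
        state = small_run.final_state
        excl = lattice.exclusion_partner
        for r in range(state.n_rna):
            ivl = state.interval(r)  # raises if non-contiguous
            if ivl is None:
                continue
            placed = [int(p) for p in state.ps_pos[r][state.ps_state[r] == 2]]
            assert len(set(placed)) == len(placed)
            assert not any(int(excl[p]) in placed for p in placed)

    def test_completed_paths_pass_oracle_and_census(
        self, lattice, small_run, census_2345
    ):
        assert small_run.n_cap > 0
        labels = census_2345.labels()
        for path in small_run.paths:
            assert is_pseudo_hamiltonian(lattice, path)
            assert ".".join(map(str, path.moves)) in labels

    def test_same_seed_bit_identical(self, lattice):
        params = KineticParams(t_max=1.0e5, quiesce_window=2.5e4)
        runs = [
            run_assembly(
                RNAVariant.uniform(-9.0), params, MoveSet([2, 3, 4, 5]),
                seed=5, n_rna=20, lattice=lattice,
            )
            for _ in range(2)
        ]
        assert runs[0].n_cap == runs[1].n_cap
        assert runs[0].t_end == runs[1].t_end
        assert runs[0].event_counts == runs[1].event_counts
        assert (runs[0].final_state.ps_pos == runs[1].final_state.ps_pos).all()

    def test_zero_cp_pool(self, lattice):
        params = KineticParams(cp_total=0, t_max=1e4, quiesce_window=1e3)
        res = run_assembly(
            RNAVariant.uniform(-9.0), params, MoveSet([2, 3, 4, 5]),
            seed=1, n_rna=5, lattice=lattice,
        )
        assert res.n_cap == 0
        assert res.event_counts["bind"] == 0

    @pytest.mark.parametrize("moves", [(2, 5, 6, 7), (2, 5, 8, 9), (6, 7, 8, 9)])
    def test_no_contact_moves_zero_yield(self, lattice, moves, fast_kinetics):
        """Move sets lacking 1 and {3,4} cannot nucleate: exactly zero
        capsids for any profile and seed."""
        res = run_assembly(
            RNAVariant.uniform(-9.0), fast_kinetics, MoveSet(moves),
            seed=3, n_rna=50, lattice=lattice,
        )
        assert res.n_cap == 0
        assert res.event_counts["nucleate"] == 0

    def test_mixed_ensemble_accepted(self, lattice, fast_kinetics):
        variants = [RNAVariant.uniform(-9.0), RNAVariant.uniform(-5.0)] * 5
        res = run_assembly(
            variants, fast_kinetics, MoveSet([2, 3, 4, 5]), seed=2,
            lattice=lattice,
        )
        assert res.n_rna == 10


class TestEligibleEvents:
    def test_fresh_state_only_binding(self, lattice):
        params = KineticParams()
        state = SimState(
            ps_state=np.zeros((2, 30), np.int8),
            ps_pos=np.full((2, 30), -1, np.int8),
            free_cp=120,
        )
        events = eligible_events(
            state, lattice, MoveSet([2, 3, 4, 5]), params,
            np.full((2, 30), -9.0), cp_total=120,
        )
        assert {e.kind for e in events} == {"bind"}
        assert len(events) == 60

    def test_no_contact_moves_never_nucleates(self, lattice):
        """All PSs CP-bound, yet no nucleation/elongation for {2,5,6,7}."""
        params = KineticParams()
        state = SimState(
            ps_state=np.ones((1, 30), np.int8),
            ps_pos=np.full((1, 30), -1, np.int8),
            free_cp=30,
        )
        events = eligible_events(
            state, lattice, MoveSet([2, 5, 6, 7]), params,
            np.full((1, 30), -9.0), cp_total=60,
        )
        assert {e.kind for e in events} == {"unbind"}

    def test_all_bound_nucleation_via_contact_moves(self, lattice):
        params = KineticParams()
        state = SimState(
            ps_state=np.ones((1, 30), np.int8),
            ps_pos=np.full((1, 30), -1, np.int8),
            free_cp=30,
        )
        events = eligible_events(
            state, lattice, MoveSet([2, 3, 4, 5]), params,
            np.full((1, 30), -9.0), cp_total=60,
        )
        nucs = [e for e in events if e.kind == "nucleate"]
        assert len(nucs) == 29  # every adjacent CP-bound pair
        for e in nucs:
            # placements only via the contact moves 3 and 4 from position 0
            assert set(e.targets) == {
                lattice.apply_move(3, 0), lattice.apply_move(4, 0)
            }

    def test_python_reference_matches_kernel_propensity(self, lattice, small_run):
        """The pure-Python event enumerator and the compiled kernel agree
        on each RNA's total non-binding propensity in a real mid-run state."""
        params = KineticParams(t_max=4.0e5, quiesce_window=1.0e5)
        state = small_run.final_state
        n = state.n_rna
        dg = np.full((n, 30), -9.0)
        events = eligible_events(
            state, lattice, MoveSet([2, 3, 4, 5]), params, dg,
            cp_total=60 * n,
        )
        py_tot = np.zeros(n)
        for e in events:
            if e.kind != "bind":
                py_tot[e.rna] += e.propensity

        # rebuild kernel-side state arrays
        cmask5, cmask2 = lattice.contact_masks_by_type()
        excl = lattice.exclusion_partner
        lo = np.full(n, -1, np.int64)
        hi = np.full(n, -1, np.int64)
        n_in = np.zeros(n, np.int64)
        occ = np.zeros(n, np.uint64)
        blk = np.zeros(n, np.uint64)
        for r in range(n):
            ivl = state.interval(r)
            if ivl is None:
                continue
            lo[r], hi[r] = ivl
            n_in[r] = hi[r] - lo[r] + 1
            for p in state.ps_pos[r][state.ps_state[r] == 2]:
                occ[r] |= np.uint64(1) << np.uint64(int(p))
                blk[r] |= (np.uint64(1) << np.uint64(int(p))) | (
                    np.uint64(1) << np.uint64(int(excl[int(p)]))
                )
        koff = params.k_bind * np.exp(dg / params.rt)
        moves = np.array([2, 3, 4, 5], np.int64)
        detach_rate = np.empty(6)
        capture_w = np.empty(6)
        for c5 in range(3):
            for c2 in range(2):
                e = params.dg_cs * c5 + params.dg_cs_two * c2
                detach_rate[c5 * 2 + c2] = params.k_attach * np.exp(e / params.rt)
                capture_w[c5 * 2 + c2] = np.exp(-params.phi * e / params.rt)
        for r in range(n):
            if n_in[r] == 30:
                continue  # frozen completed capsid
            kern = _rna_propensity(
                r, state.ps_state, state.ps_pos, lo, hi, n_in, occ, blk, koff,
                np.ascontiguousarray(lattice.move_maps.astype(np.int64)),
                moves, cmask5, cmask2, 2,
                params.k_attach, params.k_nucleate, detach_rate, capture_w,
            )
            assert kern == pytest.approx(py_tot[r], rel=1e-9)

    def test_conflicting_state_rejected(self, lattice):
        params = KineticParams()
        excl = lattice.exclusion_partner
        ps_state = np.zeros((1, 30), np.int8)
        ps_pos = np.full((1, 30), -1, np.int8)
        ps_state[0, 10] = ps_state[0, 11] = 2
        ps_pos[0, 10] = 0
        ps_pos[0, 11] = int(excl[0])  # partner conflict
        state = SimState(ps_state=ps_state, ps_pos=ps_pos, free_cp=28)
        with pytest.raises(ValueError, match="exclusion"):
            eligible_events(
                state, lattice, MoveSet([2, 3, 4, 5]), params,
                np.full((1, 30), -9.0), cp_total=60,
            )


class TestExtractPath:
    def test_positions_ordered_by_ps_index(self, lattice, small_run):
        state = small_run.final_state
        done = np.flatnonzero(small_run.completed)
        r = int(done[0])
        path = extract_path(state.ps_pos[r], lattice, MoveSet([2, 3, 4, 5]))
        assert path.positions == tuple(int(p) for p in state.ps_pos[r])
        assert all(m in (2, 3, 4, 5) for m in path.moves)

    def test_incomplete_rejected(self, lattice):
        with pytest.raises(ValueError, match="incomplete"):
            extract_path(np.full(30, -1), lattice, MoveSet([2, 3, 4, 5]))


class TestParams:
    def test_invalid_params_rejected(self):
        with pytest.raises(ValueError):
            KineticParams(k_bind=0)
        with pytest.raises(ValueError):
            KineticParams(dg_cs=1.0)
        with pytest.raises(ValueError):
            KineticParams(phi=1.5)

    def test_variant_bounds(self):
        with pytest.raises(ValueError):
            RNAVariant.uniform(-13.0)
        v = RNAVariant.uniform(-9.0)
        assert v.dg_ps.shape == (30,)
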