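"""Path enumeration, validity oracle, canonical labels, classification."""

import itertools

import numpy as np
import pytest

from pscapsid import (
    INVERSE_MOVE,
    MoveSet,
    RNAPath,
    canonical_label,
    classify_paths,
    count_paths,
    is_pseudo_hamiltonian,
)


class TestCountPaths:
    @pytest.mark.parametrize(
        "moves,expected",
        [
            ((2, 3, 4, 5), 64),
            ((3, 4, 6, 7), 826),
            ((2, 5, 6, 7), 1342),
            ((3, 4, 8, 9), 0),  # confined to one five-fold ring
            ((2, 5), 0),  # confined to one three-fold triangle
        ],
    )
    def test_known_counts(self, lattice, moves, expected):
        census = count_paths(lattice, MoveSet(moves))
        assert census.complete
        assert census.n_path == expected

    @pytest.mark.parametrize("start", [0, 17, 59])
    def test_start_vertex_independence(self, lattice, start):
        """All positions are symmetry-equivalent, so the count cannot
        depend on the DFS start position."""
        census = count_paths(lattice, MoveSet([2, 3, 4, 5]), start=start)
        assert census.n_path == 64

    def test_enumeration_matches_count(self, census_2345):
        assert census_2345.n_path == 64
        assert len(census_2345.paths) == 64

    def test_every_enumerated_path_is_valid(self, lattice, census_2345):
        for path in census_2345.paths:
            assert is_pseudo_hamiltonian(lattice, path)

    def test_subset_monotonicity(self, lattice, census_2345):
        """A superset move set admits every path of the subset, so counts
        are monotone and the subset's paths stay valid in the superset."""
        big = MoveSet([1, 2, 3, 4, 5])
        n_big = count_paths(lattice, big).n_path
        assert n_big >= census_2345.n_path
        for path in census_2345.paths[:8]:
            assert is_pseudo_hamiltonian(lattice, path, big)

    def test_large_set_requires_budget(self, lattice):
        with pytest.raises(ValueError, match="prohibitive"):
            count_paths(lattice, MoveSet(range(1, 10)))
        partial = count_paths(lattice, MoveSet(range(1, 10)), limit=20_000)
        assert not partial.complete

    def test_budget_flags_incomplete(self, lattice):
        partial = count_paths(lattice, MoveSet([2, 3, 4, 5]), limit=50)
        assert not partial.complete
        assert partial.n_path <= 64

    def test_dfs_matches_bruteforce_on_toy_lattice(self):
        """Independent oracle: on a 6-cycle with an artificial 3-pair
        exclusion, exhaustive permutation checking must agree with the
        same pruned-DFS counting rule."""
        n = 6
        nxt = [(i + 1) % n for i in range(n)]
        prv = [(i - 1) % n for i in range(n)]
        excl = [(i + 3) % n for i in range(n)]  # antipodal pairing

        def count_dfs(start):
            total = 0
            stack = [(start, 1 << start | 1 << excl[start], (start,))]
            while stack:
                v, blocked, path = stack.pop()
                if len(path) == 3:  # one vertex per exclusion pair
                    total += 1
                    continue
                for q in (nxt[v], prv[v]):
                    if not blocked >> q & 1:
                        stack.append(
                            (q, blocked | 1 << q | 1 << excl[q], path + (q,))
                        )
            return total

        def count_brute(start):
            total = 0
            for perm in itertools.permutations(range(n), 3):
                if perm[0] != start:
                    continue
                if any(b not in (nxt[a], prv[a]) for a, b in zip(perm, perm[1:])):
                    continue
                if len({min(v, excl[v]) for v in perm}) != 3:
                    continue
                total += 1
            return total

        for start in range(n):
            assert count_dfs(start) == count_brute(start)


class TestPathValidity:
    def test_reversal_is_valid(self, lattice, census_2345):
        """Reading a path 3'->5' with inverted moves is again a valid path."""
        for path in census_2345.paths[:10]:
            rev = path.reversed()
            assert rev.moves == tuple(
                INVERSE_MOVE[m] for m in path.moves[::-1]
            )
            assert is_pseudo_hamiltonian(lattice, rev)

    def test_exclusion_violation_detected(self, lattice, census_2345):
        path = census_2345.paths[0]
        excl = lattice.exclusion_partner
        bad_positions = list(path.positions)
        bad_positions[5] = int(excl[bad_positions[4]])  # both members of a pair
        bad = RNAPath(
            positions=tuple(bad_positions), moves=path.moves,
            move_set=path.move_set,
        )
        assert not is_pseudo_hamiltonian(lattice, bad)

    def test_foreign_move_detected(self, lattice, census_2345):
        path = census_2345.paths[0]
        assert not is_pseudo_hamiltonian(lattice, path, MoveSet([1]))


class TestCanonicalLabel:
    def test_symmetry_invariance(self, lattice, census_2345):
        """A path and its image under any lattice rotation share a label."""
        path = census_2345.paths[3]
        perm = lattice.position_permutation(lattice.group.matrices[31])
        moved = RNAPath.from_positions(
            lattice, [int(perm[p]) for p in path.positions], path.move_set
        )
        assert canonical_label(moved) == canonical_label(path)

    def test_census_labels_distinct(self, census_2345):
        assert len(census_2345.labels()) == 64

    def test_shared_prefix_structure(self, census_2345):
        """Paths differing only near one end share a long move prefix."""
        labels = sorted(census_2345.labels())
        a, b = labels[0].split("."), labels[1].split(".")
        shared = sum(1 for x, y in zip(a, b) if x == y)
        assert shared >= 20


class TestClassification:
    def test_single_path_repeated(self, census_2345):
        path = census_2345.paths[0]
        cls = classify_paths([path] * 7, census=census_2345)
        assert len(cls.table) == 1
        assert cls.table.loc[0, "frequency"] == 1.0
        assert cls.all_in_census

    def test_frequencies_sum_to_one(self, census_2345):
        cls = classify_paths(census_2345.paths, census=census_2345)
        assert np.isclose(cls.table["frequency"].sum(), 1.0)
        assert cls.n_paths == 64

    def test_empty_input(self):
        cls = classify_paths([])
        assert cls.n_paths == 0
        assert cls.table.empty
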