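"""Enumeration and classification of pseudo-Hamiltonian RNA paths.

An RNA threading 30 packaging signals through the shell traces a path on
the 60-site lattice that visits exactly one member of each of the 30
mutual-exclusion pairs: a pseudo-Hamiltonian path.  Paths are enumerated by
exhaustive depth-first search under a move set, pruning any step onto an
occupied site or onto the exclusion partner of an occupied site.

Counting convention (frozen as ``directed-fixed-start``): the group of 60
lattice rotations acts freely and transitively on positions, so every
symmetry orbit of directed paths contains exactly one path starting at any
chosen position.  Counting directed move sequences from one fixed start
position therefore counts paths up to lattice symmetry, without identifying
a path with its reversal.  This convention reproduces the published census
(64 paths for move set {2,3,4,5}).
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Iterable, Sequence

import numpy as np
import pandas as pd

from . import _kernels
from .lattice import INVERSE_MOVE, CapsidLattice, MoveSet

COUNTING_CONVENTION = "directed-fixed-start"

#: refuse exhaustive counts above this size without an explicit budget
LARGE_MOVE_SET_SIZE = 8


@dataclass(frozen=True)
class RNAPath:
    """A 5'->3' RNA path: 30 lattice positions joined by 29 move labels."""

    positions: tuple[int, ...]
    moves: tuple[int, ...]
    move_set: MoveSet

    def __post_init__(self):
        if len(self.positions) != 30 or len(self.moves) != 29:
            raise ValueError("an RNA path has 30 positions and 29 moves")

    @classmethod
    def from_positions(
        cls, lattice: CapsidLattice, positions: Sequence[int], move_set: MoveSet
    ) -> "RNAPath":
        """Build a path from its position sequence, inferring move labels."""
        positions = tuple(int(p) for p in positions)
        moves = []
        for a, b in zip(positions, positions[1:]):
            m = lattice.move_between(a, b)
            if m is None:
                raise ValueError(f"positions {a}->{b} are not related by any move")
            moves.append(m)
        return cls(positions=positions, moves=tuple(moves), move_set=move_set)

    def reversed(self) -> "RNAPath":
        """The 3'->5' reading: reversed positions, inverse moves."""
        return RNAPath(
            positions=self.positions[::-1],
            moves=tuple(INVERSE_MOVE[m] for m in self.moves[::-1]),
            move_set=self.move_set,
        )


def is_pseudo_hamiltonian(
    lattice: CapsidLattice, path: RNAPath, move_set: MoveSet | None = None
) -> bool:
    """Validity oracle for a candidate path.

    True iff consecutive positions are related by the stated moves, every
    move belongs to the move set, all positions are distinct, and exactly
    one member of each of the 30 exclusion pairs is visited.  Checked
    directly from the definitions, independent of the DFS enumerator.
    """
    move_set = move_set or path.move_set
    if len(path.positions) != 30 or len(path.moves) != 29:
        return False
    if len(set(path.positions)) != 30:
        return False
    for m, a, b in zip(path.moves, path.positions, path.positions[1:]):
        if m not in move_set:
            return False
        if lattice.apply_move(m, a) != b:
            return False
    excl = lattice.exclusion_partner
    pair_ids = {min(p, int(excl[p])) for p in path.positions}
    if len(pair_ids) != 30:
        return False
    return True


def canonical_label(path: RNAPath) -> str:
    """Symmetry-invariant label of a path.

    Because the rotation group acts freely and transitively, two paths are
    related by a lattice symmetry iff their move sequences coincide; the
    label is therefore the dot-joined move sequence.  Under the frozen
    counting convention a path and its reversal are distinct path types and
    carry distinct labels.
    """
    if len(path.moves) != 29:
        raise ValueError("canonical_label requires a complete 30-position path")
    return ".".join(str(m) for m in path.moves)


@dataclass
class PathCensus:
    """Result of an exhaustive path enumeration for one move set."""

    move_set: MoveSet
    n_path: int
    complete: bool
    nodes_expanded: int
    counting_convention: str = COUNTING_CONVENTION
    start: int = 0
    paths: list[RNAPath] | None = None

    def labels(self) -> set[str]:
        if self.paths is None:
            raise ValueError("census was built without path enumeration")
        return {canonical_label(p) for p in self.paths}

    def __contains__(self, item) -> bool:
        if self.paths is None:
            raise ValueError("census was built without path enumeration")
        label = item if isinstance(item, str) else canonical_label(item)
        return label in self.labels()


def count_paths(
    lattice: CapsidLattice,
    move_set: MoveSet,
    limit: int | None = None,
    start: int = 0,
    enumerate_paths: bool = False,
    max_paths: int = 2_000_000,
) -> PathCensus:
    """Exhaustively count pseudo-Hamiltonian paths for a move set.

    DFS from `start` (all positions are symmetry-equivalent), moves tried in
    ascending label order.  `limit` bounds node expansions; if exceeded the
    census is flagged incomplete.  Move sets of 8 or more moves are refused
    unless a `limit` is given, as their exhaustive census is computationally
    prohibitive.  With `enumerate_paths` the paths themselves (up to
    `max_paths`) are attached to the census.
    """
    if move_set.size >= LARGE_MOVE_SET_SIZE and limit is None:
        raise ValueError(
            f"exhaustive census for {move_set} ({move_set.size} moves) is "
            "computationally prohibitive; pass an explicit node-expansion limit"
        )
    moves = np.array(move_set.sorted(), dtype=np.int64)
    mm = np.ascontiguousarray(lattice.move_maps.astype(np.int64))
    excl = np.ascontiguousarray(lattice.exclusion_partner.astype(np.int64))
    if enumerate_paths:
        out_pos, out_mov, count, ok = _kernels.dfs_enumerate(
            mm, excl, moves, start, max_paths
        )
        paths = [
            RNAPath(
                positions=tuple(int(p) for p in out_pos[i]),
                moves=tuple(int(m) for m in out_mov[i]),
                move_set=move_set,
            )
            for i in range(count)
        ]
        return PathCensus(
            move_set=move_set,
            n_path=int(count),
            complete=bool(ok),
            nodes_expanded=-1,
            start=start,
            paths=paths,
        )
    count, nodes, ok = _kernels.dfs_count(mm, excl, moves, start, limit or 0)
    return PathCensus(
        move_set=move_set,
        n_path=int(count),
        complete=bool(ok),
        nodes_expanded=int(nodes),
        start=start,
    )


@dataclass
class PathClassification:
    """Frequency table of path types observed in assembled capsids."""

    table: pd.DataFrame  # columns: label, count, frequency
    n_paths: int
    top_shared_prefix: str  # longest common move-prefix of the top path types
    top_shared_prefix_len: int
    all_in_census: bool | None = None

    def top_fraction(self, k: int = 2) -> float:
        """Combined relative frequency of the k most frequent path types."""
        return float(self.table["frequency"].head(k).sum())


def classify_paths(
    paths: Iterable[RNAPath],
    census: PathCensus | None = None,
    top: int = 2,
) -> PathClassification:
    """Tally canonical path labels from simulated capsids.

    Returns the label frequency table sorted descending, the longest common
    move-prefix among the `top` most frequent types (the published dominant
    path pair differs only in the final moves around the last five-fold),
    and, when an enumerated census is supplied, whether every observed path
    is a member of it.
    """
    labels = [canonical_label(p) for p in paths]
    if not labels:
        return PathClassification(
            table=pd.DataFrame(columns=["label", "count", "frequency"]),
            n_paths=0,
            top_shared_prefix="",
            top_shared_prefix_len=0,
            all_in_census=None if census is None else True,
        )
    counts = pd.Series(labels).value_counts()
    table = pd.DataFrame(
        {
            "label": counts.index,
            "count": counts.values,
            "frequency": counts.values / len(labels),
        }
    ).reset_index(drop=True)
    top_seqs = [lbl.split(".") for lbl in table["label"].head(top)]
    prefix_len = 0
    if top_seqs:
        for i in range(min(len(s) for s in top_seqs)):
            if len({s[i] for s in top_seqs}) == 1:
                prefix_len += 1
            else:
                break
    prefix = ".".join(top_seqs[0][:prefix_len]) if top_seqs else ""
    in_census = None
    if census is not None:
        members = census.labels()
        in_census = all(lbl in members for lbl in set(labels))
    return PathClassification(
        table=table,
        n_paths=len(labels),
        top_shared_prefix=prefix,
        top_shared_prefix_len=prefix_len,
        all_in_census=in_census,
    )
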