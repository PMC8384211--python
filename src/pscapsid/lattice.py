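"""T=1 icosahedral capsid lattice: positions, symmetry group, local moves.

The capsid shell is modelled as the 60-point orbit of a generic reference
point under the proper rotation group of the icosahedron.  Each point stands
for one coat-protein (CP) binding site for an RNA packaging-signal hairpin.
Nine "moves" connect a site to the sites reachable by rotating about its
nearest symmetry axes:

* move 1: 180 deg about the nearest two-fold axis (self-inverse),
* moves 2/5: +/-120 deg about the nearest three-fold axis,
* moves 6/7: +/-120 deg about the second-nearest three-fold axis,
* moves 3/4: +/-72 deg and moves 8/9: +/-144 deg about the nearest five-fold
  axis.

Two hairpin orientations flanking one two-fold axis clash sterically; the
resulting mutual-exclusion pairing partitions the 60 sites into 30 pairs of
which an RNA may occupy at most one member.  CP-CP contacts correspond to
the edges generated by moves {1, 3, 4}: the truncated-icosahedron graph.
"""

from __future__ import annotations

import itertools
import json
from dataclasses import dataclass, field, replace

import networkx as nx
import numpy as np

PHI = (1.0 + np.sqrt(5.0)) / 2.0

#: move label -> inverse move label
INVERSE_MOVE = {1: 1, 2: 5, 5: 2, 3: 4, 4: 3, 6: 7, 7: 6, 8: 9, 9: 8}

#: moves whose edges are CP-CP contacts (a new CP must touch the shell)
CONTACT_MOVES = frozenset({1, 3, 4})

_ROUND = 6  # decimals used to identify orbit points and order position ids


class LatticeConstructionError(ValueError):
    """Raised when a frame configuration yields a degenerate lattice."""


def rotation_matrix(axis: np.ndarray, angle: float) -> np.ndarray:
    """Proper rotation by `angle` (radians) about `axis` (Rodrigues form)."""
    axis = np.asarray(axis, dtype=float)
    axis = axis / np.linalg.norm(axis)
    k = np.array(
        [
            [0.0, -axis[2], axis[1]],
            [axis[2], 0.0, -axis[0]],
            [-axis[1], axis[0], 0.0],
        ]
    )
    return np.eye(3) + np.sin(angle) * k + (1.0 - np.cos(angle)) * (k @ k)


def icosahedron() -> tuple[np.ndarray, list[tuple[int, int, int]], list[tuple[int, int]]]:
    """Vertices, faces and edges of the standard icosahedron.

    Vertices are the cyclic permutations of (0, +/-1, +/-phi), normalised to
    the unit sphere.  Faces are returned as sorted vertex triples, edges as
    sorted vertex pairs.
    """
    verts = []
    for a, b in itertools.product((1.0, -1.0), repeat=2):
        for perm in range(3):
            v = np.zeros(3)
            v[perm] = 0.0
            v[(perm + 1) % 3] = a
            v[(perm + 2) % 3] = b * PHI
            verts.append(v)
    verts = np.asarray(verts)
    verts /= np.linalg.norm(verts[0])
    d2 = ((verts[:, None, :] - verts[None, :, :]) ** 2).sum(-1)
    edge2 = np.sort(np.unique(np.round(d2, 8)))[1]
    adj = np.isclose(d2, edge2)
    faces = []
    for i in range(12):
        for j in range(i + 1, 12):
            if not adj[i, j]:
                continue
            for k in range(j + 1, 12):
                if adj[i, k] and adj[j, k]:
                    faces.append((i, j, k))
    edges = [(i, j) for i in range(12) for j in range(i + 1, 12) if adj[i, j]]
    return verts, faces, edges


@dataclass(frozen=True)
class RotationSet:
    """The 60 proper rotations of the icosahedral group as 3x3 matrices."""

    matrices: np.ndarray  # (60, 3, 3)
    identity_index: int

    def __len__(self) -> int:
        return len(self.matrices)

    def element_orders(self) -> np.ndarray:
        """Order of each element (1, 2, 3 or 5 in the icosahedral group)."""
        orders = np.zeros(len(self.matrices), dtype=int)
        for i, m in enumerate(self.matrices):
            acc = np.eye(3)
            for n in range(1, 11):
                acc = m @ acc
                if np.allclose(acc, np.eye(3), atol=1e-9):
                    orders[i] = n
                    break
        return orders


def build_rotation_group(max_products: int = 10_000) -> RotationSet:
    """Generate the icosahedral rotation group by closure.

    Generators: a 72 deg rotation about one vertex axis and a 120 deg
    rotation about an adjacent face axis.  Raises
    :class:`LatticeConstructionError` if closure is not reached within
    `max_products` compositions (which would indicate bad generators).
    """
    verts, faces, _ = icosahedron()
    g5 = rotation_matrix(verts[0], 2.0 * np.pi / 5.0)
    face = next(f for f in faces if 0 in f)
    g3 = rotation_matrix(verts[list(face)].mean(axis=0), 2.0 * np.pi / 3.0)

    def key(m: np.ndarray) -> tuple:
        return tuple(np.round(m, 8).ravel())

    elems: list[np.ndarray] = [np.eye(3)]
    seen = {key(elems[0])}
    frontier = [elems[0]]
    products = 0
    while frontier:
        nxt = []
        for m in frontier:
            for g in (g5, g3):
                products += 1
                if products > max_products:
                    raise LatticeConstructionError(
                        "group closure not reached; bad generator choice"
                    )
                p = g @ m
                k = key(p)
                if k not in seen:
                    seen.add(k)
                    elems.append(p)
                    nxt.append(p)
        frontier = nxt
    matrices = np.asarray(elems)
    idx = next(
        i for i, m in enumerate(matrices) if np.allclose(m, np.eye(3), atol=1e-9)
    )
    return RotationSet(matrices=matrices, identity_index=idx)


@dataclass(frozen=True)
class FrameConfig:
    """Reference-point and chirality conventions used to build a lattice.

    weights
        Convex-combination weights of (vertex, adjacent face centroid,
        adjacent edge midpoint) defining the generic representative point.
        All three must be positive and pairwise distinct so the point is
        strictly off every symmetry axis.
    five_fold_sign, three_fold_sign, second_three_fold_sign
        Which sense of rotation is labelled move 3 (vs 4), move 2 (vs 5)
        and move 6 (vs 7).  The defaults are the calibrated convention that
        reproduces the published path census (64 paths for moves {2,3,4,5},
        826 for {3,4,6,7}); flipping all signs together yields the mirror
        lattice with identical counts.
    swap_three_folds
        Exchange which of the two flanking three-fold axes carries moves 2/5
        versus 6/7.  The default (False) assigns moves 2/5 to the
        geometrically nearest face axis.
    """

    weights: tuple[float, float, float] = (0.55, 0.30, 0.15)
    five_fold_sign: int = -1
    three_fold_sign: int = 1
    second_three_fold_sign: int = 1
    swap_three_folds: bool = False

    def to_dict(self) -> dict:
        return {
            "weights": list(self.weights),
            "five_fold_sign": self.five_fold_sign,
            "three_fold_sign": self.three_fold_sign,
            "second_three_fold_sign": self.second_three_fold_sign,
            "swap_three_folds": self.swap_three_folds,
        }


DEFAULT_FRAME = FrameConfig()


@dataclass(frozen=True)
class MoveSet:
    """An inverse-closed subset of the nine local moves.

    The icosahedral symmetry of the shell demands that if a move is allowed
    so is its inverse: 2 with 5, 3 with 4, 6 with 7, 8 with 9 (move 1 is
    self-inverse).  Physically meaningful sets have 4-9 moves; smaller
    inverse-closed sets (e.g. {2,5}) are accepted for analysis since their
    path census is well defined (and empty).
    """

    moves: frozenset[int]

    def __init__(self, moves) -> None:
        ms = frozenset(int(m) for m in moves)
        if not ms or not ms <= set(range(1, 10)):
            raise ValueError(f"moves must be a non-empty subset of 1..9, got {sorted(ms)}")
        for m in ms:
            if INVERSE_MOVE[m] not in ms:
                raise ValueError(
                    f"move set {sorted(ms)} is not closed under inverses "
                    f"(move {m} requires move {INVERSE_MOVE[m]})"
                )
        object.__setattr__(self, "moves", ms)

    @classmethod
    def parse(cls, text: str) -> "MoveSet":
        """Parse '2,3,4,5' or '2345' into a move set."""
        text = text.strip()
        if "," in text:
            labels = [int(t) for t in text.split(",") if t.strip()]
        else:
            labels = [int(c) for c in text]
        return cls(labels)

    @property
    def size(self) -> int:
        return len(self.moves)

    @property
    def contact_moves(self) -> frozenset[int]:
        """Moves in the set whose edges are CP-CP contacts."""
        return self.moves & CONTACT_MOVES

    def sorted(self) -> tuple[int, ...]:
        return tuple(sorted(self.moves))

    def __contains__(self, m: int) -> bool:
        return m in self.moves

    def __iter__(self):
        return iter(sorted(self.moves))

    def __str__(self) -> str:
        return "{" + ",".join(str(m) for m in self) + "}"


@dataclass(frozen=True)
class CapsidLattice:
    """The 60-position lattice with move permutations and exclusion pairing.

    move_maps[k-1, v] is the position reached from position v by move k.
    exclusion_partner[v] is the position whose hairpin orientation clashes
    with v's.  contact_edges are the CP-CP contact pairs (moves 1, 3, 4).
    """

    rep_points: np.ndarray  # (60, 3) unit vectors
    move_maps: np.ndarray  # (9, 60) int
    exclusion_partner: np.ndarray  # (60,) int
    nearest_five: np.ndarray  # (60,) vertex index 0..11
    nearest_three: np.ndarray  # (60,) face index 0..19
    second_three: np.ndarray  # (60,) face index 0..19
    nearest_two: np.ndarray  # (60,) two-fold axis index 0..14
    frame: FrameConfig
    group: RotationSet = field(repr=False)

    # ------------------------------------------------------------------ basics
    @property
    def n_positions(self) -> int:
        return self.move_maps.shape[1]

    @property
    def positions(self) -> np.ndarray:
        return np.arange(self.n_positions)

    def apply_move(self, move: int, position: int) -> int:
        """Position reached from `position` by move label `move` (1..9)."""
        return int(self.move_maps[move - 1, position])

    @property
    def contact_edges(self) -> frozenset[tuple[int, int]]:
        edges = set()
        for m in CONTACT_MOVES:
            mm = self.move_maps[m - 1]
            for v in range(self.n_positions):
                edges.add(tuple(sorted((v, int(mm[v])))))
        return frozenset(edges)

    def contact_graph(self) -> nx.Graph:
        """CP-CP contact graph (3-regular, 90 edges, truncated icosahedron)."""
        g = nx.Graph()
        g.add_nodes_from(range(self.n_positions))
        g.add_edges_from(self.contact_edges)
        return g

    def move_between(self, a: int, b: int) -> int | None:
        """The unique move label mapping position a to b, or None."""
        hits = [m for m in range(1, 10) if self.move_maps[m - 1, a] == b]
        if not hits:
            return None
        if len(hits) > 1:  # geometrically impossible on a valid lattice
            raise LatticeConstructionError(f"ambiguous move {a}->{b}: {hits}")
        return hits[0]

    def contact_masks(self) -> np.ndarray:
        """Per-position uint64 bitmask of contact-graph neighbours."""
        masks = np.zeros(self.n_positions, dtype=np.uint64)
        for a, b in self.contact_edges:
            masks[a] |= np.uint64(1) << np.uint64(b)
            masks[b] |= np.uint64(1) << np.uint64(a)
        return masks

    def contact_masks_by_type(self) -> tuple[np.ndarray, np.ndarray]:
        """Neighbour bitmasks split by interface type.

        Returns (five_fold_mask, two_fold_mask): move-3/4 edges are pentamer
        interfaces, move-1 edges dimer interfaces across the two-fold axis.
        """
        m5 = np.zeros(self.n_positions, dtype=np.uint64)
        m2 = np.zeros(self.n_positions, dtype=np.uint64)
        for move, masks in ((3, m5), (4, m5), (1, m2)):
            mm = self.move_maps[move - 1]
            for v in range(self.n_positions):
                w = int(mm[v])
                masks[v] |= np.uint64(1) << np.uint64(w)
                masks[w] |= np.uint64(1) << np.uint64(v)
        return m5, m2

    def position_permutation(self, g: np.ndarray) -> np.ndarray:
        """Permutation of position ids induced by group element matrix g."""
        pts = self.rep_points
        out = np.empty(self.n_positions, dtype=int)
        for v in range(self.n_positions):
            q = g @ pts[v]
            d = ((pts - q) ** 2).sum(axis=1)
            i = int(np.argmin(d))
            if d[i] > 1e-10:
                raise LatticeConstructionError("matrix does not permute the orbit")
            out[v] = i
        return out

    # ------------------------------------------------------------------ export
    def to_json_dict(self) -> dict:
        return {
            "frame": self.frame.to_dict(),
            "positions": self.n_positions,
            "rep_points": np.round(self.rep_points, 8).tolist(),
            "move_maps": {str(k): self.move_maps[k - 1].tolist() for k in range(1, 10)},
            "exclusion_partner": self.exclusion_partner.tolist(),
            "nearest_axes": {
                "five_fold": self.nearest_five.tolist(),
                "three_fold": self.nearest_three.tolist(),
                "second_three_fold": self.second_three.tolist(),
                "two_fold": self.nearest_two.tolist(),
            },
            "contact_edges": sorted(list(e) for e in self.contact_edges),
        }

    def to_json(self, path) -> None:
        with open(path, "w") as fh:
            json.dump(self.to_json_dict(), fh, indent=1)

    def to_move_graph(self) -> nx.MultiDiGraph:
        """Directed multigraph with one edge per (position, move)."""
        g = nx.MultiDiGraph()
        excl = self.exclusion_partner
        contact = self.contact_edges
        for v in range(self.n_positions):
            g.add_node(
                v,
                five_fold=int(self.nearest_five[v]),
                three_fold=int(self.nearest_three[v]),
                second_three_fold=int(self.second_three[v]),
                two_fold=int(self.nearest_two[v]),
                exclusion_partner=int(excl[v]),
            )
        for m in range(1, 10):
            mm = self.move_maps[m - 1]
            for v in range(self.n_positions):
                w = int(mm[v])
                g.add_edge(
                    v,
                    w,
                    move=m,
                    contact=tuple(sorted((v, w))) in contact,
                    exclusion_pair=bool(excl[v] == w),
                )
        return g

    def to_graphml(self, path) -> None:
        nx.write_graphml(self.to_move_graph(), path)


def _nearest_axes(dirs: np.ndarray, point: np.ndarray, n: int, tie_tol: float = 1e-9):
    """Indices of the n nearest directions by angular distance; tie -> error."""
    dots = dirs @ point
    order = np.argsort(-dots)
    for rank in range(n):
        if rank + 1 < len(order) and dots[order[rank]] - dots[order[rank + 1]] < tie_tol:
            raise LatticeConstructionError(
                "representative point equidistant to two symmetry axes; "
                "perturb the frame weights"
            )
    return order[:n]


def build_lattice(frame: FrameConfig = DEFAULT_FRAME) -> CapsidLattice:
    """Construct the 60-position lattice for a frame configuration.

    The representative point is a generic convex combination of one vertex,
    an adjacent face centroid and an adjacent edge midpoint; its orbit under
    the rotation group gives the 60 CP positions.  Per-position axes are
    assigned by angular distance and each move is a rotation about the
    position's own axis.  Raises :class:`LatticeConstructionError` for
    degenerate frames (point on an axis, axis ties, ambiguous moves).
    """
    verts, faces, edges = icosahedron()
    group = build_rotation_group()

    face_c = np.array([verts[list(f)].mean(axis=0) for f in faces])
    face_c /= np.linalg.norm(face_c, axis=1)[:, None]
    # antipodal edges share a two-fold axis: 30 edges -> 15 axes, canonical sign
    edge_m = np.array([(verts[i] + verts[j]) / 2.0 for i, j in edges])
    edge_m /= np.linalg.norm(edge_m, axis=1)[:, None]
    seen_axes: list[np.ndarray] = []
    for m in edge_m:
        if not any(np.allclose(m, a) or np.allclose(-m, a) for a in seen_axes):
            seen_axes.append(m)
    two_fold_axes = np.asarray(seen_axes)  # (15, 3)

    w = frame.weights
    if len(w) != 3 or min(w) <= 0:
        raise LatticeConstructionError("frame weights must be three positive numbers")
    face0 = next(f for f in faces if 0 in f)
    fc0 = face_c[faces.index(face0)]
    other = next(v for v in face0 if v != 0)
    em0 = (verts[0] + verts[other]) / 2.0
    em0 /= np.linalg.norm(em0)
    p0 = w[0] * verts[0] + w[1] * fc0 + w[2] * em0
    p0 /= np.linalg.norm(p0)

    pts = np.einsum("gij,j->gi", group.matrices, p0)
    keys = {tuple(r) for r in np.round(pts, _ROUND)}
    if len(keys) != 60:
        raise LatticeConstructionError(
            f"orbit has {len(keys)} distinct points (reference point on an axis?)"
        )
    rpts = np.round(pts, _ROUND)
    order = np.lexsort((rpts[:, 2], rpts[:, 1], rpts[:, 0]))
    pts = pts[order]

    def pos_index(q: np.ndarray) -> int:
        d = ((pts - q) ** 2).sum(axis=1)
        i = int(np.argmin(d))
        if d[i] > 1e-10:
            raise LatticeConstructionError("rotation image is not an orbit point")
        return i

    n5 = np.empty(60, dtype=int)
    n3 = np.empty(60, dtype=int)
    s3 = np.empty(60, dtype=int)
    n2 = np.empty(60, dtype=int)
    move_maps = np.empty((9, 60), dtype=np.int64)
    a72 = frame.five_fold_sign * 2.0 * np.pi / 5.0
    a120a = frame.three_fold_sign * 2.0 * np.pi / 3.0
    a120b = frame.second_three_fold_sign * 2.0 * np.pi / 3.0

    for v in range(60):
        p = pts[v]
        iv = _nearest_axes(verts, p, 1)[0]
        if1, if2 = _nearest_axes(face_c, p, 2)
        if frame.swap_three_folds:
            if1, if2 = if2, if1
        # two-fold axes are unsigned; nearest by |cos| (180 deg rotation)
        adots = np.abs(two_fold_axes @ p)
        aord = np.argsort(-adots)
        if adots[aord[0]] - adots[aord[1]] < 1e-9:
            raise LatticeConstructionError(
                "representative point equidistant to two symmetry axes; "
                "perturb the frame weights"
            )
        ie = int(aord[0])
        n5[v], n3[v], s3[v], n2[v] = iv, if1, if2, ie
        axis5, axis3a, axis3b, axis2 = verts[iv], face_c[if1], face_c[if2], two_fold_axes[ie]
        for m, (axis, ang) in {
            1: (axis2, np.pi),
            2: (axis3a, a120a),
            5: (axis3a, -a120a),
            3: (axis5, a72),
            4: (axis5, -a72),
            8: (axis5, 2 * a72),
            9: (axis5, -2 * a72),
            6: (axis3b, a120b),
            7: (axis3b, -a120b),
        }.items():
            move_maps[m - 1, v] = pos_index(rotation_matrix(axis, ang) @ p)
        if len(set(move_maps[:, v])) != 9 or v in move_maps[:, v]:
            raise LatticeConstructionError("moves are not distinct at a position")

    # exclusion pairing: apply move 4 then move 2 (equals move 5 then move 3)
    exclusion = move_maps[1][move_maps[3]]
    return CapsidLattice(
        rep_points=pts,
        move_maps=move_maps,
        exclusion_partner=exclusion.astype(np.int64),
        nearest_five=n5,
        nearest_three=n3,
        second_three=s3,
        nearest_two=n2,
        frame=frame,
        group=group,
    )


# ---------------------------------------------------------------- validation
@dataclass
class ValidationReport:
    """Pass/fail record for every structural invariant of a lattice."""

    checks: dict[str, bool]

    @property
    def passed(self) -> bool:
        return all(self.checks.values())

    def failures(self) -> list[str]:
        return [k for k, ok in self.checks.items() if not ok]


def _cycle_lengths(perm: np.ndarray) -> list[int]:
    seen = np.zeros(len(perm), dtype=bool)
    out = []
    for start in range(len(perm)):
        if seen[start]:
            continue
        n, v = 0, start
        while not seen[v]:
            seen[v] = True
            v = int(perm[v])
            n += 1
        out.append(n)
    return out


def validate_lattice(lattice: CapsidLattice) -> ValidationReport:
    """Check every structural invariant of a constructed lattice.

    Purely a reporting operation: a correct lattice passes all checks, a
    corrupted one is diagnosed check by check.
    """
    mm = lattice.move_maps
    ident = np.arange(lattice.n_positions)
    m = {k: mm[k - 1] for k in range(1, 10)}
    checks: dict[str, bool] = {}

    checks["moves_are_permutations"] = all(
        len(set(m[k])) == lattice.n_positions for k in m
    )
    checks["move1_self_inverse"] = bool((m[1][m[1]] == ident).all())
    checks["move5_inverse_of_2"] = bool((m[2][m[5]] == ident).all())
    checks["move4_inverse_of_3"] = bool((m[3][m[4]] == ident).all())
    checks["move7_inverse_of_6"] = bool((m[6][m[7]] == ident).all())
    checks["move9_inverse_of_8"] = bool((m[8][m[9]] == ident).all())
    checks["move2_order_3"] = bool((m[2][m[2][m[2]]] == ident).all())
    checks["move6_order_3"] = bool((m[6][m[6][m[6]]] == ident).all())
    checks["move3_order_5"] = bool((m[3][m[3][m[3][m[3][m[3]]]]] == ident).all())
    checks["move8_is_move3_squared"] = bool((m[8] == m[3][m[3]]).all())
    checks["move9_is_move4_squared"] = bool((m[9] == m[4][m[4]]).all())
    checks["move3_twelve_5_cycles"] = sorted(_cycle_lengths(m[3])) == [5] * 12
    checks["move2_twenty_3_cycles"] = sorted(_cycle_lengths(m[2])) == [3] * 20

    excl = lattice.exclusion_partner
    checks["exclusion_fixed_point_free"] = bool((excl != ident).all())
    checks["exclusion_involution"] = bool((excl[excl] == ident).all())
    checks["exclusion_is_m2_after_m4"] = bool((excl == m[2][m[4]]).all())
    checks["exclusion_is_m3_after_m5"] = bool((excl == m[3][m[5]]).all())

    g = lattice.contact_graph()
    checks["contact_graph_90_edges"] = g.number_of_edges() == 90
    checks["contact_graph_3_regular"] = all(d == 3 for _, d in g.degree())
    checks["contact_graph_connected"] = nx.is_connected(g)
    move1_edges = {tuple(sorted((v, int(m[1][v])))) for v in range(60)}
    checks["move1_perfect_matching"] = len(move1_edges) == 30 and len(
        {v for e in move1_edges for v in e}
    ) == 60
    rest = g.copy()
    rest.remove_edges_from(move1_edges)
    comps = list(nx.connected_components(rest))
    checks["pentagons_after_removing_move1"] = len(comps) == 12 and all(
        len(c) == 5 and rest.subgraph(c).number_of_edges() == 5 for c in comps
    )
    return ValidationReport(checks=checks)
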