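"""Gillespie simulation of packaging-signal-mediated capsid co-assembly.

An ensemble of RNAs, each carrying 30 packaging signals (PSs) with binding
free energies dG_ps, co-assembles with a shared coat-protein (CP) pool.
Reactions:

* CP binds a free PS at a pseudo-first-order rate proportional to the free
  CP pool; it unbinds at ``k_bind * exp(dG_ps / rt)`` (detailed balance).
* Nucleation: two CPs bound to sequence-adjacent PSs join the shell at a
  pair of lattice positions related by a contact move (1, 3 or 4).
* Elongation: the CP-bound PS immediately 5' or 3' of the in-shell interval
  attaches at a position reachable by a move in the move set, provided the
  target and its exclusion partner are unoccupied.  The RNA tether holds
  the complex in place; CP-CP contact support enters energetically, not as
  an eligibility constraint.
* Reverse steps: a terminal in-shell CP:PS detaches at
  ``k_attach * exp(E_contact / rt)`` where E_contact sums the CP-CP
  contact energies broken (an unsupported placement, E_contact = 0,
  detaches at the full rate and persists only once buttressed by later
  neighbours); a 2-CP nucleus dissolves as a single event.

Nucleation is where protein-protein binding is obligatory: the two CPs
must sit at positions related by a contact move, so move sets lacking
moves 1, 3 and 4 can never nucleate and assemble exactly zero capsids.

An RNA is packaged when all 30 PSs are in-shell, which by the exclusion
rule covers all 30 mutually exclusive position pairs.  Completed capsids
are treated as stable end states.
"""

from __future__ import annotations

from dataclasses import dataclass, field
from typing import Sequence

import numpy as np

from . import _kernels
from .lattice import CapsidLattice, MoveSet, build_lattice
from .paths import RNAPath, is_pseudo_hamiltonian

DG_BOUNDS = (-12.0, -4.0)

_STOP_REASONS = {0: "quiescent", 1: "t_max", 2: "max_events", 3: "no_events"}


@dataclass(frozen=True)
class RNAVariant:
    """30 packaging-signal binding free energies, 5'-most first (kcal/mol)."""

    dg_ps: np.ndarray
    bounds: tuple[float, float] = DG_BOUNDS

    def __post_init__(self):
        dg = np.asarray(self.dg_ps, dtype=float)
        if dg.shape != (30,):
            raise ValueError("an RNA variant has exactly 30 PS affinities")
        lo, hi = self.bounds
        if (dg < lo - 1e-9).any() or (dg > hi + 1e-9).any():
            raise ValueError(f"dG_ps values must lie within {self.bounds} kcal/mol")
        object.__setattr__(self, "dg_ps", dg)

    @classmethod
    def uniform(cls, dg: float, bounds: tuple[float, float] = DG_BOUNDS) -> "RNAVariant":
        return cls(np.full(30, float(dg)), bounds=bounds)

    def with_dg(self, indices, value: float) -> "RNAVariant":
        dg = self.dg_ps.copy()
        dg[list(indices)] = value
        return RNAVariant(dg, bounds=self.bounds)


@dataclass(frozen=True)
class KineticParams:
    """Kinetic and pool parameters of the assembly simulation.

    Energies are kcal/mol.  ``dg_cs`` is the CP-CP contact energy of the
    pentamer (five-fold, move-3/4 edge) interface; ``dg_cs_two`` that of
    the dimer interface across the two-fold axis (move-1 edge), taken
    weaker because the packaging-signal hairpin occupies the two-fold
    region.  ``cp_activity``
    is the dimensionless activity of the full CP pool (concentration over
    the 1 M standard state); the CP->PS on-rate per free PS is
    ``k_bind * cp_activity * free_cp / cp_total`` so that on/off rates obey
    detailed balance with the PS binding free energy.  The default 1e-5
    corresponds to a ~10 uM pool, the regime in which the -12..-4 kcal/mol
    affinity band spread translates into distinct PS occupancies.
    ``cp_per_rna`` sets the pool to 60 CPs per RNA (a full shell each),
    although only the 30 path CPs are consumed in-model.
    """

    dg_cs: float = -4.0
    dg_cs_two: float = -2.0
    rt: float = 0.593
    phi: float = 1.0
    k_bind: float = 100.0
    k_attach: float = 0.1
    k_nucleate: float = 0.001
    cp_activity: float = 1.0e-5
    cp_per_rna: int = 60
    cp_total: int | None = None
    t_max: float = 4.0e6
    quiesce_window: float = 5.0e5
    max_events: int = 400_000_000

    # phi is the Bronsted barrier-asymmetry factor: an attachment quantum
    # is split over eligible targets with weight exp(-phi*E_contact/rt),
    # E_contact the CP-CP contact energy the placement would form, so
    # contact-rich sites capture the incoming CP:PS preferentially.

    def __post_init__(self):
        if min(self.k_bind, self.k_attach, self.k_nucleate, self.rt) <= 0:
            raise ValueError("rates and rt must be positive")
        if self.dg_cs >= 0 or self.dg_cs_two >= 0:
            raise ValueError("contact energies must be negative")
        if not 0.0 <= self.phi <= 1.0:
            raise ValueError("phi must lie in [0, 1]")

    def pool_size(self, n_rna: int) -> int:
        return self.cp_total if self.cp_total is not None else self.cp_per_rna * n_rna


@dataclass
class SimState:
    """Snapshot of the simulation state (used by the event enumerator).

    ps_state: 0 = free PS, 1 = CP-bound, 2 = in-shell.  ps_pos holds the
    lattice position of in-shell PSs (-1 otherwise).  The in-shell PSs of
    each RNA form the contiguous interval [lo, hi].
    """

    ps_state: np.ndarray  # (n_rna, 30) int8
    ps_pos: np.ndarray  # (n_rna, 30) int8
    free_cp: int

    @property
    def n_rna(self) -> int:
        return self.ps_state.shape[0]

    def interval(self, r: int) -> tuple[int, int] | None:
        idx = np.flatnonzero(self.ps_state[r] == 2)
        if idx.size == 0:
            return None
        if not (np.diff(idx) == 1).all():
            raise ValueError("in-shell PSs of one RNA must be contiguous")
        return int(idx[0]), int(idx[-1])

    def occupied_mask(self, r: int) -> int:
        mask = 0
        for p in self.ps_pos[r][self.ps_state[r] == 2]:
            mask |= 1 << int(p)
        return mask

    def cp_accounted(self) -> int:
        return int(self.free_cp + (self.ps_state >= 1).sum())


@dataclass(frozen=True)
class Event:
    """One eligible reaction with its propensity."""

    kind: str  # bind | unbind | nucleate | elongate | dissolve | detach
    rna: int
    ps_index: int  # 5'-most PS involved
    propensity: float
    targets: tuple[int, ...] = ()  # candidate lattice positions (attachments)
    target_weights: tuple[float, ...] = ()  # relative capture weights


def eligible_events(
    state: SimState,
    lattice: CapsidLattice,
    move_set: MoveSet,
    params: KineticParams,
    dg_ps: np.ndarray,
    cp_total: int | None = None,
) -> list[Event]:
    """Enumerate every eligible reaction with its propensity.

    Pure-Python reference used as the oracle for the compiled Gillespie
    kernel; attachment propensities are one quantum of ``k_attach`` per
    attachable unit, split uniformly over the listed target positions.
    """
    events: list[Event] = []
    dg_ps = np.atleast_2d(dg_ps)
    cp_total = cp_total if cp_total is not None else params.pool_size(state.n_rna)
    kon = 0.0
    if cp_total > 0:
        kon = params.k_bind * params.cp_activity * state.free_cp / cp_total
    excl = lattice.exclusion_partner
    contact_moves = sorted(move_set.contact_moves)
    cmask5, cmask2 = lattice.contact_masks_by_type()

    def contact_energy(q: int, occ_mask: int) -> float:
        c5 = bin(int(cmask5[q]) & occ_mask).count("1")
        c2 = bin(int(cmask2[q]) & occ_mask).count("1")
        return params.dg_cs * c5 + params.dg_cs_two * c2
    for r in range(state.n_rna):
        ivl = state.interval(r)
        if ivl is not None and ivl[1] - ivl[0] == 29:
            continue  # completed capsid: stable end state
        occ = state.occupied_mask(r)
        blk = occ
        for p in state.ps_pos[r][state.ps_state[r] == 2]:
            blk |= 1 << int(excl[int(p)])
        if occ & blk != occ or any(
            (occ >> int(excl[int(p)])) & 1
            for p in state.ps_pos[r][state.ps_state[r] == 2]
        ):
            raise ValueError(f"RNA {r}: exclusion-pair conflict already present")
        for i in range(30):
            s = state.ps_state[r, i]
            if s == 0 and kon > 0:
                events.append(Event("bind", r, i, kon))
            elif s == 1:
                koff = params.k_bind * np.exp(dg_ps[r % dg_ps.shape[0], i] / params.rt)
                events.append(Event("unbind", r, i, koff))
        if ivl is None:
            if contact_moves:
                p0 = 0  # canonical nucleation position, WLOG by symmetry
                targets = tuple(lattice.apply_move(m, p0) for m in contact_moves)
                for i in range(29):
                    if state.ps_state[r, i] == 1 and state.ps_state[r, i + 1] == 1:
                        events.append(
                            Event("nucleate", r, i, params.k_nucleate, targets)
                        )
            continue
        lo, hi = ivl
        for side, (i_new, p_end) in (
            ("5p", (lo - 1, int(state.ps_pos[r, lo]))),
            ("3p", (hi + 1, int(state.ps_pos[r, hi]))),
        ):
            if not (0 <= i_new <= 29) or state.ps_state[r, i_new] != 1:
                continue
            targets = []
            weights = []
            for m in move_set:
                q = lattice.apply_move(m, p_end)
                if (blk >> q) & 1:
                    continue
                targets.append(q)
                weights.append(
                    float(np.exp(-params.phi * contact_energy(q, occ) / params.rt))
                )
            if targets:
                events.append(
                    Event(
                        "elongate", r, i_new, params.k_attach,
                        tuple(targets), tuple(weights),
                    )
                )
        n_in = hi - lo + 1
        if n_in == 2:
            pl = int(state.ps_pos[r, lo])
            rate = params.k_attach * np.exp(
                contact_energy(pl, occ & ~(1 << pl)) / params.rt
            )
            events.append(Event("dissolve", r, lo, rate))
        else:
            for i_end in (lo, hi):
                p = int(state.ps_pos[r, i_end])
                rate = params.k_attach * np.exp(
                    contact_energy(p, occ & ~(1 << p)) / params.rt
                )
                events.append(Event("detach", r, i_end, rate))
    return events


@dataclass
class AssemblyResult:
    """Outcome of one stochastic assembly run."""

    move_set: MoveSet
    n_rna: int
    n_cap: int
    seed: int
    paths: list[RNAPath]
    completed: np.ndarray
    completion_times: np.ndarray
    event_counts: dict[str, int]
    t_end: float
    free_cp: int
    stop_reason: str
    final_state: SimState = field(repr=False)

    @property
    def yield_pct(self) -> float:
        return 100.0 * self.n_cap / self.n_rna if self.n_rna else 0.0

    @property
    def equilibrated(self) -> bool:
        """Whether the run reached quiescence rather than a hard cap."""
        return self.stop_reason in ("quiescent", "no_events") or self.n_cap == self.n_rna


def _as_dg_matrix(variants, n_rna: int | None) -> np.ndarray:
    if isinstance(variants, RNAVariant):
        if n_rna is None:
            raise ValueError("pass n_rna when giving a single variant")
        return np.broadcast_to(variants.dg_ps, (n_rna, 30)).copy()
    if isinstance(variants, np.ndarray):
        mat = np.atleast_2d(np.asarray(variants, dtype=float))
    else:
        mat = np.array([v.dg_ps for v in variants], dtype=float)
    if mat.shape[1] != 30:
        raise ValueError("each RNA needs 30 PS affinities")
    if n_rna is not None and mat.shape[0] != n_rna:
        raise ValueError("n_rna disagrees with the number of variants")
    return mat


def run_assembly(
    variants: RNAVariant | Sequence[RNAVariant] | np.ndarray,
    params: KineticParams,
    move_set: MoveSet,
    seed: int,
    n_rna: int | None = None,
    lattice: CapsidLattice | None = None,
    validate_paths: bool = True,
) -> AssemblyResult:
    """Run the Gillespie co-assembly simulation to quiescence.

    `variants` is a single variant (replicated `n_rna` times: the standard
    homogeneous-ensemble protocol) or one variant per RNA.  Two runs with
    the same inputs and seed are bit-identical.
    """
    lattice = lattice if lattice is not None else build_lattice()
    dg_ps = _as_dg_matrix(variants, n_rna)
    n = dg_ps.shape[0]
    cp_total = params.pool_size(n)
    moves = np.array(move_set.sorted(), dtype=np.int64)
    n_contact = len(move_set.contact_moves)
    cmask5, cmask2 = lattice.contact_masks_by_type()
    (
        n_cap, t_end, free_cp, ev, ps_state, ps_pos, completed,
        completion_time, stop_code,
    ) = _kernels.gillespie_assembly(
        np.ascontiguousarray(lattice.move_maps.astype(np.int64)),
        np.ascontiguousarray(lattice.exclusion_partner.astype(np.int64)),
        cmask5,
        cmask2,
        moves,
        n_contact,
        0,  # canonical nucleation position
        np.ascontiguousarray(dg_ps),
        params.dg_cs,
        params.dg_cs_two,
        params.rt,
        params.phi,
        params.k_bind,
        params.k_attach,
        params.k_nucleate,
        params.cp_activity,
        cp_total,
        params.t_max,
        params.quiesce_window,
        params.max_events,
        np.uint64(seed),
    )
    state = SimState(ps_state=ps_state, ps_pos=ps_pos, free_cp=int(free_cp))
    if state.cp_accounted() != cp_total:
        raise RuntimeError("CP conservation violated")  # engine fault
    paths = []
    for r in np.flatnonzero(completed):
        paths.append(extract_path(ps_pos[r], lattice, move_set))
    if validate_paths:
        for p in paths:
            if not is_pseudo_hamiltonian(lattice, p, move_set):
                raise RuntimeError("completed capsid path fails validity oracle")
    names = ["bind", "unbind", "nucleate", "elongate", "dissolve", "detach"]
    return AssemblyResult(
        move_set=move_set,
        n_rna=n,
        n_cap=int(n_cap),
        seed=int(seed),
        paths=paths,
        completed=completed,
        completion_times=completion_time,
        event_counts={k: int(v) for k, v in zip(names, ev)},
        t_end=float(t_end),
        free_cp=int(free_cp),
        stop_reason=_STOP_REASONS[int(stop_code)],
        final_state=state,
    )


def extract_path(
    capsid_positions: np.ndarray | Sequence[int],
    lattice: CapsidLattice,
    move_set: MoveSet,
) -> RNAPath:
    """RNA path of a completed capsid, ordered 5'->3' by PS index.

    The position sequence follows the PS indices (sequence order), not the
    order in which CPs were placed; move labels are inferred from the
    lattice.  Rejects incomplete capsids.
    """
    pos = np.asarray(capsid_positions)
    if pos.shape != (30,) or (pos < 0).any():
        raise ValueError("capsid is incomplete; cannot extract a path")
    return RNAPath.from_positions(lattice, pos, move_set)
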