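"""Numba kernels: path enumeration DFS and the Gillespie assembly loop.

Positions fit in one machine word: the 60-vertex lattice is tracked with
uint64 bitmasks (occupied sites, exclusion-blocked sites, contact-graph
neighbourhoods), which keeps the depth-first search and the per-event
propensity updates branch-light.
"""

import numpy as np
from numba import njit

ONE = np.uint64(1)

# ---------------------------------------------------------------------- DFS


@njit(cache=True)
def dfs_count(move_maps, excl, moves, start, node_limit):
    """Count complete directed pseudo-Hamiltonian move sequences from `start`.

    A step to a position that is occupied, or whose exclusion partner is
    occupied, is pruned.  A complete path has 30 positions.  Returns
    (count, nodes_expanded, completed) where completed is False if
    `node_limit` (>0) was hit first.
    """
    nm = moves.shape[0]
    pos_stack = np.empty(30, np.int64)
    try_stack = np.empty(30, np.int64)
    blocked = np.uint64(0)
    pos_stack[0] = start
    try_stack[0] = 0
    blocked |= ONE << np.uint64(start)
    blocked |= ONE << np.uint64(excl[start])
    depth = 0
    count = np.int64(0)
    nodes = np.int64(0)
    while depth >= 0:
        v = pos_stack[depth]
        if depth == 29:
            count += 1
            blocked &= ~(ONE << np.uint64(v))
            blocked &= ~(ONE << np.uint64(excl[v]))
            depth -= 1
            continue
        ti = try_stack[depth]
        advanced = False
        while ti < nm:
            q = move_maps[moves[ti] - 1, v]
            ti += 1
            if (blocked >> np.uint64(q)) & ONE == ONE:
                continue
            nodes += 1
            if node_limit > 0 and nodes > node_limit:
                return count, nodes, False
            try_stack[depth] = ti
            depth += 1
            pos_stack[depth] = q
            try_stack[depth] = 0
            blocked |= ONE << np.uint64(q)
            blocked |= ONE << np.uint64(excl[q])
            advanced = True
            break
        if not advanced:
            blocked &= ~(ONE << np.uint64(v))
            blocked &= ~(ONE << np.uint64(excl[v]))
            depth -= 1
    return count, nodes, True


@njit(cache=True)
def dfs_enumerate(move_maps, excl, moves, start, max_paths):
    """Enumerate complete paths from `start` in DFS (ascending-move) order.

    Returns (positions, move_labels, count, complete) where positions is
    (n, 30) and move_labels (n, 29); enumeration stops after `max_paths`
    stored paths (complete=False if more exist).
    """
    nm = moves.shape[0]
    out_pos = np.empty((max_paths, 30), np.int8)
    out_mov = np.empty((max_paths, 29), np.int8)
    pos_stack = np.empty(30, np.int64)
    mov_stack = np.empty(29, np.int64)
    try_stack = np.empty(30, np.int64)
    blocked = np.uint64(0)
    pos_stack[0] = start
    try_stack[0] = 0
    blocked |= ONE << np.uint64(start)
    blocked |= ONE << np.uint64(excl[start])
    depth = 0
    count = np.int64(0)
    while depth >= 0:
        v = pos_stack[depth]
        if depth == 29:
            if count < max_paths:
                for i in range(30):
                    out_pos[count, i] = pos_stack[i]
                for i in range(29):
                    out_mov[count, i] = mov_stack[i]
                count += 1
            else:
                return out_pos, out_mov, count, False
            blocked &= ~(ONE << np.uint64(v))
            blocked &= ~(ONE << np.uint64(excl[v]))
            depth -= 1
            continue
        ti = try_stack[depth]
        advanced = False
        while ti < nm:
            m = moves[ti]
            q = move_maps[m - 1, v]
            ti += 1
            if (blocked >> np.uint64(q)) & ONE == ONE:
                continue
            try_stack[depth] = ti
            mov_stack[depth] = m
            depth += 1
            pos_stack[depth] = q
            try_stack[depth] = 0
            blocked |= ONE << np.uint64(q)
            blocked |= ONE << np.uint64(excl[q])
            advanced = True
            break
        if not advanced:
            blocked &= ~(ONE << np.uint64(v))
            blocked &= ~(ONE << np.uint64(excl[v]))
            depth -= 1
    return out_pos, out_mov, count, True


# ----------------------------------------------------------------- Gillespie

# event class indices in the returned counter array
EV_BIND = 0
EV_UNBIND = 1
EV_NUCLEATE = 2
EV_ELONGATE = 3
EV_DISSOLVE = 4  # reverse of nucleation: 2-CP nucleus dissolves
EV_DETACH = 5  # terminal CP:PS leaves the shell


@njit(cache=True, inline="always")
def _next_u64(state):
    """splitmix64 step; `state` is a 1-element uint64 array mutated in place."""
    state[0] = state[0] + np.uint64(0x9E3779B97F4A7C15)
    z = state[0]
    z = (z ^ (z >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)
    z = (z ^ (z >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)
    return z ^ (z >> np.uint64(31))


@njit(cache=True, inline="always")
def _uniform(state):
    u = np.float64(_next_u64(state) >> np.uint64(11)) * (1.0 / 9007199254740992.0)
    if u <= 0.0:
        u = 1.0e-16
    return u


@njit(cache=True, inline="always")
def _tree_set(tree, size, leaf, value):
    i = size + leaf
    tree[i] = value
    i >>= 1
    while i >= 1:
        tree[i] = tree[2 * i] + tree[2 * i + 1]
        i >>= 1


@njit(cache=True, inline="always")
def _tree_sample(tree, size, target):
    i = 1
    while i < size:
        left = tree[2 * i]
        if target < left:
            i = 2 * i
        else:
            target -= left
            i = 2 * i + 1
    return i - size


@njit(cache=True, inline="always")
def _popcount(x):
    c = 0
    while x != np.uint64(0):
        x &= x - ONE
        c += 1
    return c


@njit(cache=True, inline="always")
def _has_elong_target(p, blk, move_maps, moves):
    """True if any move from shell-end position p lands on an eligible site.

    Eligible: the target and its exclusion partner are unoccupied.  Contact
    support is not required for placement (the RNA tether holds the CP);
    an unsupported CP detaches at the full k_attach rate instead.
    """
    for t in range(moves.shape[0]):
        q = move_maps[moves[t] - 1, p]
        if (blk >> np.uint64(q)) & ONE == ONE:
            continue
        return True
    return False


@njit(cache=True, inline="always")
def _contact_class(q, occ, cmask5, cmask2):
    """Contact class of a CP at q vs the occupied set: index c5 * 2 + c2
    (a position has at most two five-fold and one two-fold neighbour)."""
    c5 = _popcount(cmask5[q] & occ)
    c2 = _popcount(cmask2[q] & occ)
    return c5 * 2 + c2


@njit(cache=True)
def _shell_propensity(
    r, ps_state, ps_pos, lo, hi, n_in, occ, blk,
    move_maps, moves, cmask5, cmask2, k_attach, detach_rate, capture_w,
):
    """Elongation + detachment propensity of RNA r (zero without a nucleus)."""
    if n_in[r] == 0:
        return 0.0
    a = 0.0
    o = occ[r]
    b = blk[r]
    l = lo[r]
    h = hi[r]
    if l > 0 and ps_state[r, l - 1] == 1:
        if _has_elong_target(ps_pos[r, l], b, move_maps, moves):
            a += k_attach
    if h < 29 and ps_state[r, h + 1] == 1:
        if _has_elong_target(ps_pos[r, h], b, move_maps, moves):
            a += k_attach
    if n_in[r] == 2:
        pl = ps_pos[r, l]
        cc = _contact_class(pl, o & ~(ONE << np.uint64(pl)), cmask5, cmask2)
        a += detach_rate[cc]
    elif n_in[r] >= 3:
        for p_end in (ps_pos[r, l], ps_pos[r, h]):
            cc = _contact_class(p_end, o & ~(ONE << np.uint64(p_end)), cmask5, cmask2)
            a += detach_rate[cc]
    return a


@njit(cache=True)
def _count_pairs(r, ps_state):
    n = 0
    for i in range(29):
        if ps_state[r, i] == 1 and ps_state[r, i + 1] == 1:
            n += 1
    return n


@njit(cache=True)
def _rna_propensity(
    r, ps_state, ps_pos, lo, hi, n_in, occ, blk, koff,
    move_maps, moves, cmask5, cmask2, n_contact_moves,
    k_attach, k_nuc, detach_rate, capture_w,
):
    """Total non-binding propensity of RNA r.

    Terms, in the order also used for event selection: PS:CP unbinding,
    nucleation (one attachment quantum per adjacent CP-bound pair),
    5' elongation, 3' elongation, nucleus dissolution / terminal detachment.
    """
    a = 0.0
    for i in range(30):
        if ps_state[r, i] == 1:
            a += koff[r, i]
    if n_in[r] == 0:
        if n_contact_moves > 0:
            for i in range(29):
                if ps_state[r, i] == 1 and ps_state[r, i + 1] == 1:
                    a += k_nuc
    else:
        o = occ[r]
        b = blk[r]
        l = lo[r]
        h = hi[r]
        if l > 0 and ps_state[r, l - 1] == 1:
            if _has_elong_target(ps_pos[r, l], b, move_maps, moves):
                a += k_attach
        if h < 29 and ps_state[r, h + 1] == 1:
            if _has_elong_target(ps_pos[r, h], b, move_maps, moves):
                a += k_attach
        if n_in[r] == 2:
            pl = ps_pos[r, l]
            cc = _contact_class(pl, o & ~(ONE << np.uint64(pl)), cmask5, cmask2)
            a += detach_rate[cc]
        elif n_in[r] >= 3:
            for p_end in (ps_pos[r, l], ps_pos[r, h]):
                cc = _contact_class(p_end, o & ~(ONE << np.uint64(p_end)), cmask5, cmask2)
                a += detach_rate[cc]
    return a


@njit(cache=True)
def gillespie_assembly(
    move_maps, excl, cmask5, cmask2, moves, n_contact_moves, nucleation_site,
    dg_ps, dg_cs5, dg_cs2, rt, phi, k_bind, k_attach, k_nuc, cp_activity,
    cp_total, t_max, quiesce_window, max_events, seed,
):
    """Stochastic co-assembly of an RNA ensemble with a shared CP pool.

    dg_ps is (n_rna, 30).  Returns
    (n_cap, t_end, free_cp, event_counts, ps_state, ps_pos, completed,
     completion_time, stop_reason) with stop_reason 0=quiescent, 1=t_max,
    2=max_events, 3=no possible events.
    """
    n_rna = dg_ps.shape[0]
    koff = k_bind * np.exp(dg_ps / rt)
    # lookup tables over contact classes (c5 in 0..2, c2 in 0..1)
    detach_rate = np.empty(6, np.float64)
    capture_w = np.empty(6, np.float64)
    for c5 in range(3):
        for c2 in range(2):
            e = dg_cs5 * c5 + dg_cs2 * c2
            detach_rate[c5 * 2 + c2] = k_attach * np.exp(e / rt)
            capture_w[c5 * 2 + c2] = np.exp(-phi * e / rt)

    ps_state = np.zeros((n_rna, 30), np.int8)
    ps_pos = np.full((n_rna, 30), -1, np.int8)
    lo = np.full(n_rna, -1, np.int64)
    hi = np.full(n_rna, -1, np.int64)
    n_in = np.zeros(n_rna, np.int64)
    occ = np.zeros(n_rna, np.uint64)
    blk = np.zeros(n_rna, np.uint64)
    completed = np.zeros(n_rna, np.bool_)
    completion_time = np.full(n_rna, np.nan, np.float64)
    event_counts = np.zeros(6, np.int64)

    size = 1
    while size < n_rna:
        size *= 2
    tree_free = np.zeros(2 * size, np.float64)
    tree_oth = np.zeros(2 * size, np.float64)
    for r in range(n_rna):
        _tree_set(tree_free, size, r, 30.0)

    # incrementally maintained per-RNA propensity components
    usum = np.zeros(n_rna, np.float64)  # sum of koff over CP-bound PSs
    nfree = np.full(n_rna, 30, np.int64)  # free PS count
    npairs = np.zeros(n_rna, np.int64)  # adjacent CP-bound pairs (no nucleus)
    shellp = np.zeros(n_rna, np.float64)  # elongation + detachment terms

    rng = np.empty(1, np.uint64)
    rng[0] = np.uint64(seed) ^ np.uint64(0xD1B54A32D192ED03)
    _next_u64(rng)

    free_cp = cp_total
    t = 0.0
    n_cap = 0
    last_progress_t = 0.0
    stop_reason = 2
    n_events = np.int64(0)

    while n_events < max_events:
        kon = 0.0
        if cp_total > 0:
            kon = k_bind * cp_activity * free_cp / cp_total
        a_bind = kon * tree_free[1]
        a_oth = tree_oth[1]
        a_tot = a_bind + a_oth
        if a_tot <= 0.0:
            stop_reason = 3
            break
        t += -np.log(_uniform(rng)) / a_tot
        if t >= t_max:
            t = t_max
            stop_reason = 1
            break
        if t - last_progress_t > quiesce_window:
            stop_reason = 0
            break
        n_events += 1
        shell_event = False
        u = _uniform(rng) * a_tot
        if u < a_bind:
            # ---- CP binds a free PS
            r = _tree_sample(tree_free, size, u / kon)
            if r >= n_rna or completed[r] or nfree[r] <= 0:
                continue  # numerical edge; resample next iteration
            k = int(_uniform(rng) * nfree[r])
            i_hit = -1
            for i in range(30):
                if ps_state[r, i] == 0:
                    if k == 0:
                        ps_state[r, i] = 1
                        i_hit = i
                        break
                    k -= 1
            free_cp -= 1
            event_counts[EV_BIND] += 1
            nfree[r] -= 1
            usum[r] += koff[r, i_hit]
            if n_in[r] == 0:
                if i_hit > 0 and ps_state[r, i_hit - 1] == 1:
                    npairs[r] += 1
                if i_hit < 29 and ps_state[r, i_hit + 1] == 1:
                    npairs[r] += 1
            elif i_hit == lo[r] - 1 or i_hit == hi[r] + 1:
                shellp[r] = _shell_propensity(
                    r, ps_state, ps_pos, lo, hi, n_in, occ, blk,
                    move_maps, moves, cmask5, cmask2, k_attach,
                    detach_rate, capture_w,
                )
        else:
            # descend the sum tree, keeping the residual target within leaf r
            resid = u - a_bind
            node = 1
            while node < size:
                left = tree_oth[2 * node]
                if resid < left:
                    node = 2 * node
                else:
                    resid -= left
                    node = 2 * node + 1
            r = node - size
            if r >= n_rna or completed[r]:
                continue
            acc = 0.0
            done = False
            # (a) unbinding
            for i in range(30):
                if ps_state[r, i] == 1:
                    acc += koff[r, i]
                    if resid < acc:
                        ps_state[r, i] = 0
                        free_cp += 1
                        event_counts[EV_UNBIND] += 1
                        nfree[r] += 1
                        usum[r] -= koff[r, i]
                        if n_in[r] == 0:
                            if i > 0 and ps_state[r, i - 1] == 1:
                                npairs[r] -= 1
                            if i < 29 and ps_state[r, i + 1] == 1:
                                npairs[r] -= 1
                        elif i == lo[r] - 1 or i == hi[r] + 1:
                            shellp[r] = _shell_propensity(
                                r, ps_state, ps_pos, lo, hi, n_in, occ, blk,
                                move_maps, moves, cmask5, cmask2, k_attach,
                                detach_rate, capture_w,
                            )
                        done = True
                        break
            if not done and n_in[r] == 0 and n_contact_moves > 0:
                # (b) nucleation: pick the adjacent bound pair, then a contact move
                for i in range(29):
                    if ps_state[r, i] == 1 and ps_state[r, i + 1] == 1:
                        acc += k_nuc
                        if resid < acc:
                            mi = int(_uniform(rng) * n_contact_moves)
                            cnt = 0
                            mv = 0
                            for tmi in range(moves.shape[0]):
                                if (moves[tmi] == 1) or (moves[tmi] == 3) or (moves[tmi] == 4):
                                    if cnt == mi:
                                        mv = moves[tmi]
                                        break
                                    cnt += 1
                            p0 = nucleation_site
                            p1 = move_maps[mv - 1, p0]
                            ps_state[r, i] = 2
                            ps_state[r, i + 1] = 2
                            ps_pos[r, i] = p0
                            ps_pos[r, i + 1] = p1
                            lo[r] = i
                            hi[r] = i + 1
                            n_in[r] = 2
                            occ[r] = (ONE << np.uint64(p0)) | (ONE << np.uint64(p1))
                            blk[r] = occ[r] | (ONE << np.uint64(excl[p0])) | (ONE << np.uint64(excl[p1]))
                            usum[r] -= koff[r, i] + koff[r, i + 1]
                            event_counts[EV_NUCLEATE] += 1
                            last_progress_t = t
                            done = True
                            shell_event = True
                            break
            elif not done and n_in[r] > 0:
                o = occ[r]
                b = blk[r]
                # (c) elongation at 5' then 3'
                for side in range(2):
                    if done:
                        break
                    if side == 0:
                        ok = lo[r] > 0 and ps_state[r, lo[r] - 1] == 1
                        p_end = ps_pos[r, lo[r]]
                        i_new = lo[r] - 1
                    else:
                        ok = hi[r] < 29 and ps_state[r, hi[r] + 1] == 1
                        p_end = ps_pos[r, hi[r]]
                        i_new = hi[r] + 1
                    if not ok:
                        continue
                    # targets weighted by contact support: w = exp(-phi*E_contact/rt)
                    wsum = 0.0
                    for tmi in range(moves.shape[0]):
                        q = move_maps[moves[tmi] - 1, p_end]
                        if (b >> np.uint64(q)) & ONE == ONE:
                            continue
                        wsum += capture_w[_contact_class(q, o, cmask5, cmask2)]
                    if wsum <= 0.0:
                        continue
                    acc += k_attach
                    if resid < acc:
                        pick = _uniform(rng) * wsum
                        q_new = -1
                        wacc = 0.0
                        for tmi in range(moves.shape[0]):
                            q = move_maps[moves[tmi] - 1, p_end]
                            if (b >> np.uint64(q)) & ONE == ONE:
                                continue
                            wacc += capture_w[_contact_class(q, o, cmask5, cmask2)]
                            q_new = q
                            if pick < wacc:
                                break
                        ps_state[r, i_new] = 2
                        ps_pos[r, i_new] = q_new
                        if side == 0:
                            lo[r] = i_new
                        else:
                            hi[r] = i_new
                        n_in[r] += 1
                        occ[r] |= ONE << np.uint64(q_new)
                        blk[r] |= (ONE << np.uint64(q_new)) | (ONE << np.uint64(excl[q_new]))
                        usum[r] -= koff[r, i_new]
                        event_counts[EV_ELONGATE] += 1
                        last_progress_t = t
                        done = True
                        shell_event = True
                # (d) dissolution / terminal detachment
                if not done and n_in[r] == 2:
                    pl = ps_pos[r, lo[r]]
                    acc += detach_rate[_contact_class(pl, o & ~(ONE << np.uint64(pl)), cmask5, cmask2)]
                    if resid < acc:
                        for i in (lo[r], hi[r]):
                            p = ps_pos[r, i]
                            ps_state[r, i] = 1
                            ps_pos[r, i] = -1
                            occ[r] &= ~(ONE << np.uint64(p))
                            blk[r] &= ~((ONE << np.uint64(p)) | (ONE << np.uint64(excl[p])))
                        usum[r] += koff[r, lo[r]] + koff[r, hi[r]]
                        lo[r] = -1
                        hi[r] = -1
                        n_in[r] = 0
                        npairs[r] = _count_pairs(r, ps_state)
                        event_counts[EV_DISSOLVE] += 1
                        last_progress_t = t
                        done = True
                        shell_event = True
                elif not done and n_in[r] >= 3:
                    for side in range(2):
                        if done:
                            break
                        if side == 0:
                            i_end = lo[r]
                        else:
                            i_end = hi[r]
                        p = ps_pos[r, i_end]
                        acc += detach_rate[_contact_class(p, o & ~(ONE << np.uint64(p)), cmask5, cmask2)]
                        if resid < acc:
                            ps_state[r, i_end] = 1
                            ps_pos[r, i_end] = -1
                            occ[r] &= ~(ONE << np.uint64(p))
                            blk[r] &= ~((ONE << np.uint64(p)) | (ONE << np.uint64(excl[p])))
                            if side == 0:
                                lo[r] = i_end + 1
                            else:
                                hi[r] = i_end - 1
                            n_in[r] -= 1
                            usum[r] += koff[r, i_end]
                            event_counts[EV_DETACH] += 1
                            last_progress_t = t
                            done = True
                            shell_event = True
            # (rounding residue: treat as no-op)
            if n_in[r] == 30 and not completed[r]:
                completed[r] = True
                completion_time[r] = t
                n_cap += 1
                last_progress_t = t
                _tree_set(tree_free, size, r, 0.0)
                _tree_set(tree_oth, size, r, 0.0)
                continue
        if not completed[r]:
            if shell_event:
                shellp[r] = _shell_propensity(
                    r, ps_state, ps_pos, lo, hi, n_in, occ, blk,
                    move_maps, moves, cmask5, cmask2, k_attach,
                    detach_rate, capture_w,
                )
            nuc_term = 0.0
            if n_in[r] == 0 and n_contact_moves > 0:
                nuc_term = k_nuc * npairs[r]
            _tree_set(tree_oth, size, r, usum[r] + nuc_term + shellp[r])
            _tree_set(tree_free, size, r, float(nfree[r]))

    return (
        n_cap, t, free_cp, event_counts, ps_state, ps_pos, completed,
        completion_time, stop_reason,
    )
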