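"""Monte Carlo kinetics: trial moves, sweeps, end-to-end annealing, run control.

One *sweep* attempts exactly one trial move per bead (in a fresh random
permutation); a sweep corresponds to roughly 1 ns of real time.  After every
sweep an annealing pass joins filament ends that have diffused to within the
maximum bond length of each other, provided the new bond and both junction
angles satisfy the same geometric constraints as the bulk of the chain.
Merged filaments are never split again (no back reactions).

The hot loops are compiled with numba and use an inline xorshift128+
generator seeded from a single integer, so every run is reproducible from
its seed.  Neighbour search for reactive ends uses a periodic cell list
(cell size >= the reaction distance) and falls back to an all-pairs scan
when the box is too small to hold a 3x3x3 cell grid.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, field
from typing import List, Optional, Tuple

import numpy as np
from numba import njit

from .polymer import (
    UNIFORM_ANGLE,
    PeriodicBox,
    SimulationParams,
    SystemState,
)

__all__ = [
    "Trajectory",
    "ReactionEvent",
    "StalePairError",
    "seed_rng_state",
    "trial_move",
    "sweep",
    "detect_reactive_pairs",
    "anneal",
    "run",
    "mean_ulf_length",
    "sweeps_to_seconds",
]

_F = np.float64
_MASK = np.uint64(0xFFFFFFFFFFFFFFFF)


class StalePairError(RuntimeError):
    """A candidate pair refers to an end consumed by an earlier merge."""


# --------------------------------------------------------------------------
# random numbers: xorshift128+ with splitmix64 seeding
# --------------------------------------------------------------------------

def seed_rng_state(seed: int) -> np.ndarray:
    """Expand an integer seed into an xorshift128+ state (splitmix64)."""
    state = np.empty(2, dtype=np.uint64)
    with np.errstate(over="ignore"):
        z = (np.uint64(seed) + np.uint64(0x9E3779B97F4A7C15)) & _MASK
        for k in range(2):
            x = z
            x = ((x ^ (x >> np.uint64(30))) * np.uint64(0xBF58476D1CE4E5B9)) & _MASK
            x = ((x ^ (x >> np.uint64(27))) * np.uint64(0x94D049BB133111EB)) & _MASK
            x = x ^ (x >> np.uint64(31))
            state[k] = x
            z = (z + np.uint64(0x9E3779B97F4A7C15)) & _MASK
    if state[0] == 0 and state[1] == 0:  # pragma: no cover - splitmix never yields 0,0
        state[0] = np.uint64(1)
    return state


@njit(inline="always")
def _rand(state):
    s1 = state[0]
    s0 = state[1]
    state[0] = s0
    s1 ^= (s1 << np.uint64(23)) & np.uint64(0xFFFFFFFFFFFFFFFF)
    s1 ^= s1 >> np.uint64(17)
    s1 ^= s0 ^ (s0 >> np.uint64(26))
    state[1] = s1
    return np.float64((s0 + s1) >> np.uint64(11)) * (1.0 / 9007199254740992.0)


@njit(inline="always")
def _rand_dir(state):
    """Uniform unit vector (Marsaglia 1972)."""
    while True:
        x1 = 2.0 * _rand(state) - 1.0
        x2 = 2.0 * _rand(state) - 1.0
        ss = x1 * x1 + x2 * x2
        if ss < 1.0:
            break
    rt = 2.0 * np.sqrt(1.0 - ss)
    return x1 * rt, x2 * rt, 1.0 - 2.0 * ss


@njit(cache=True, fastmath=True)
def _shuffle(arr, n, state):
    for i in range(n - 1, 0, -1):
        j = int(_rand(state) * (i + 1))
        tmp = arr[i]
        arr[i] = arr[j]
        arr[j] = tmp


# --------------------------------------------------------------------------
# geometry helpers (work on squared quantities; no trig in the hot path)
# --------------------------------------------------------------------------

@njit(inline="always")
def _angle_ok_c2(ux, uy, uz, cx, cy, cz, wx, wy, wz, ca2):
    """Check angle(u->c, c->w) <= alpha; return (ok, cos^2 of the angle).

    Valid for alpha < 90 deg: requires a positive dot product.
    """
    ax = cx - ux
    ay = cy - uy
    az = cz - uz
    bx = wx - cx
    by = wy - cy
    bz = wz - cz
    n2a = ax * ax + ay * ay + az * az
    n2b = bx * bx + by * by + bz * bz
    dot = ax * bx + ay * by + az * bz
    if dot <= 0.0:
        return False, 0.0
    c2 = dot * dot / (n2a * n2b)
    if dot * dot < ca2 * n2a * n2b:
        return False, c2
    return True, c2


@njit(inline="always")
def _other_nb(nb, a, i):
    if nb[a, 0] == i:
        return nb[a, 1]
    return nb[a, 0]


@njit(cache=True, fastmath=True)
def _attempt_move(pos, nb, i, geo, mode, state):
    """One trial move of bead ``i``; mutates ``pos`` on acceptance."""
    bmin2 = geo[0]
    bmax2 = geo[1]
    ca2 = geo[2]
    sin2min = geo[3]
    maxdisp = geo[4]

    dx, dy, dz = _rand_dir(state)
    mag = maxdisp * _rand(state)
    nx = pos[i, 0] + dx * mag
    ny = pos[i, 1] + dy * mag
    nz = pos[i, 2] + dz * mag

    a = nb[i, 0]
    b = nb[i, 1]
    # bond lengths touching i
    if a >= 0:
        ex = nx - pos[a, 0]
        ey = ny - pos[a, 1]
        ez = nz - pos[a, 2]
        d2 = ex * ex + ey * ey + ez * ez
        if d2 < bmin2 or d2 > bmax2:
            return False
    if b >= 0:
        ex = nx - pos[b, 0]
        ey = ny - pos[b, 1]
        ez = nz - pos[b, 2]
        d2 = ex * ex + ey * ey + ez * ez
        if d2 < bmin2 or d2 > bmax2:
            return False

    r2 = 1.0
    # angle centred at i
    if a >= 0 and b >= 0:
        ok, c2n = _angle_ok_c2(
            pos[a, 0], pos[a, 1], pos[a, 2], nx, ny, nz,
            pos[b, 0], pos[b, 1], pos[b, 2], ca2,
        )
        if not ok:
            return False
        if mode == 1:
            _, c2o = _angle_ok_c2(
                pos[a, 0], pos[a, 1], pos[a, 2],
                pos[i, 0], pos[i, 1], pos[i, 2],
                pos[b, 0], pos[b, 1], pos[b, 2], 2.0,
            )
            s2o = 1.0 - c2o
            s2n = 1.0 - c2n
            if s2o < sin2min:
                s2o = sin2min
            if s2n < sin2min:
                s2n = sin2min
            r2 *= s2o / s2n
    # angles centred at each neighbour
    for t in range(2):
        c = a if t == 0 else b
        if c < 0:
            continue
        u = _other_nb(nb, c, i)
        if u < 0:
            continue
        ok, c2n = _angle_ok_c2(
            pos[u, 0], pos[u, 1], pos[u, 2],
            pos[c, 0], pos[c, 1], pos[c, 2],
            nx, ny, nz, ca2,
        )
        if not ok:
            return False
        if mode == 1:
            _, c2o = _angle_ok_c2(
                pos[u, 0], pos[u, 1], pos[u, 2],
                pos[c, 0], pos[c, 1], pos[c, 2],
                pos[i, 0], pos[i, 1], pos[i, 2], 2.0,
            )
            s2o = 1.0 - c2o
            s2n = 1.0 - c2n
            if s2o < sin2min:
                s2o = sin2min
            if s2n < sin2min:
                s2n = sin2min
            r2 *= s2o / s2n
    if mode == 1 and r2 < 1.0:
        u01 = _rand(state)
        if u01 * u01 > r2:
            return False
    pos[i, 0] = nx
    pos[i, 1] = ny
    pos[i, 2] = nz
    return True


@njit(cache=True, fastmath=True)
def _sweep_kernel(pos, nb, perm, geo, mode, state):
    n = pos.shape[0]
    _shuffle(perm, n, state)
    acc = 0
    for t in range(n):
        if _attempt_move(pos, nb, perm[t], geo, mode, state):
            acc += 1
    return acc


# --------------------------------------------------------------------------
# reactive-pair detection (periodic cell list with all-pairs fallback)
# --------------------------------------------------------------------------

@njit(inline="always")
def _min_image_1d(x, edge):
    x -= edge * np.floor(x / edge + 0.5)
    return x


@njit(cache=True, fastmath=True)
def _collect_pairs(pos, fil_id, ends, n_ends, edge, rd2,
                   cell_head, cell_next, cell_of, ncell, pairs):
    """Fill ``pairs`` with bead-id pairs of ends closer than the reaction
    distance (minimum image), on different filaments.  Returns the number of
    pairs, or -1 on buffer overflow.  ``cell_head`` must be all -1 on entry
    and is restored to -1 on exit."""
    cap = pairs.shape[0]
    np_ = 0
    if ncell >= 3:
        csize = edge / ncell
        for k in range(n_ends):
            e = ends[k]
            x = pos[e, 0] % edge
            y = pos[e, 1] % edge
            z = pos[e, 2] % edge
            cx = int(x / csize)
            cy = int(y / csize)
            cz = int(z / csize)
            if cx >= ncell:
                cx = ncell - 1
            if cy >= ncell:
                cy = ncell - 1
            if cz >= ncell:
                cz = ncell - 1
            cid = (cx * ncell + cy) * ncell + cz
            cell_of[k] = cid
            cell_next[k] = cell_head[cid]
            cell_head[cid] = k
        for k in range(n_ends):
            e = ends[k]
            cid = cell_of[k]
            cz0 = cid % ncell
            cy0 = (cid // ncell) % ncell
            cx0 = cid // (ncell * ncell)
            for ox in range(-1, 2):
                cx = (cx0 + ox) % ncell
                for oy in range(-1, 2):
                    cy = (cy0 + oy) % ncell
                    for oz in range(-1, 2):
                        cz = (cz0 + oz) % ncell
                        j = cell_head[(cx * ncell + cy) * ncell + cz]
                        while j >= 0:
                            if j < k:
                                e2 = ends[j]
                                if fil_id[e2] != fil_id[e]:
                                    dx = _min_image_1d(pos[e2, 0] - pos[e, 0], edge)
                                    dy = _min_image_1d(pos[e2, 1] - pos[e, 1], edge)
                                    dz = _min_image_1d(pos[e2, 2] - pos[e, 2], edge)
                                    if dx * dx + dy * dy + dz * dz < rd2:
                                        if np_ >= cap:
                                            return -1
                                        pairs[np_, 0] = e
                                        pairs[np_, 1] = e2
                                        np_ += 1
                            j = cell_next[j]
        for k in range(n_ends):
            cell_head[cell_of[k]] = -1
    else:
        for k in range(n_ends):
            e = ends[k]
            for j in range(k):
                e2 = ends[j]
                if fil_id[e2] == fil_id[e]:
                    continue
                dx = _min_image_1d(pos[e2, 0] - pos[e, 0], edge)
                dy = _min_image_1d(pos[e2, 1] - pos[e, 1], edge)
                dz = _min_image_1d(pos[e2, 2] - pos[e, 2], edge)
                if dx * dx + dy * dy + dz * dz < rd2:
                    if np_ >= cap:
                        return -1
                    pairs[np_, 0] = e
                    pairs[np_, 1] = e2
                    np_ += 1
    return np_


@njit(cache=True, fastmath=True)
def _walk_apply(pos, nb, fil_id, start, sx, sy, sz, new_fid, do_shift, do_relabel):
    prev = -1
    cur = start
    while cur >= 0:
        if do_shift:
            pos[cur, 0] += sx
            pos[cur, 1] += sy
            pos[cur, 2] += sz
        if do_relabel:
            fil_id[cur] = new_fid
        a = nb[cur, 0]
        b = nb[cur, 1]
        nxt = a if a != prev else b
        prev = cur
        cur = nxt


@njit(cache=True, fastmath=True)
def _try_merge(pos, nb, fil_id, fil_nbeads, ends, n_ends, ea, eb, edge, geo):
    """Attempt an end-to-end merge of the pair (ea, eb).

    Returns (status, n_ends): status 1 = merged, 0 = geometry rejected,
    -1 = stale pair.  On success the filament of the losing id is shifted by
    the periodic image offset so the new bond is contiguous in unwrapped
    coordinates, and its beads are relabelled.
    """
    bmin2 = geo[0]
    bmax2 = geo[1]
    car2 = geo[6]
    if nb[ea, 1] >= 0 or nb[eb, 1] >= 0:
        return -1, n_ends
    fa = fil_id[ea]
    fb = fil_id[eb]
    if fa == fb:
        return -1, n_ends
    # gap vector via minimum image
    vx = _min_image_1d(pos[eb, 0] - pos[ea, 0], edge)
    vy = _min_image_1d(pos[eb, 1] - pos[ea, 1], edge)
    vz = _min_image_1d(pos[eb, 2] - pos[ea, 2], edge)
    d2 = vx * vx + vy * vy + vz * vz
    if d2 < bmin2 or d2 > bmax2:
        return 0, n_ends
    na = nb[ea, 0]
    nbb = nb[eb, 0]
    # junction angle at ea: between (ea - na) and v
    if na >= 0:
        ok, _ = _angle_ok_c2(
            pos[na, 0], pos[na, 1], pos[na, 2],
            pos[ea, 0], pos[ea, 1], pos[ea, 2],
            pos[ea, 0] + vx, pos[ea, 1] + vy, pos[ea, 2] + vz, car2,
        )
        if not ok:
            return 0, n_ends
    # junction angle at eb: between v and (nbb - eb)
    if nbb >= 0:
        ok, _ = _angle_ok_c2(
            pos[eb, 0] - vx, pos[eb, 1] - vy, pos[eb, 2] - vz,
            pos[eb, 0], pos[eb, 1], pos[eb, 2],
            pos[nbb, 0], pos[nbb, 1], pos[nbb, 2], car2,
        )
        if not ok:
            return 0, n_ends
    # merge: keep the larger filament's label and frame
    sx = pos[ea, 0] + vx - pos[eb, 0]
    sy = pos[ea, 1] + vy - pos[eb, 1]
    sz = pos[ea, 2] + vz - pos[eb, 2]
    do_shift = sx != 0.0 or sy != 0.0 or sz != 0.0
    if fil_nbeads[fa] >= fil_nbeads[fb]:
        _walk_apply(pos, nb, fil_id, eb, sx, sy, sz, fa, do_shift, True)
        fil_nbeads[fa] += fil_nbeads[fb]
        fil_nbeads[fb] = 0
    else:
        if do_shift:
            _walk_apply(pos, nb, fil_id, eb, sx, sy, sz, 0, True, False)
        _walk_apply(pos, nb, fil_id, ea, 0.0, 0.0, 0.0, fb, False, True)
        fil_nbeads[fb] += fil_nbeads[fa]
        fil_nbeads[fa] = 0
    nb[ea, 1] = eb
    nb[eb, 1] = ea
    # drop both beads from the ends list (swap-pop)
    for _ in range(2):
        for k in range(n_ends):
            if ends[k] == ea or ends[k] == eb:
                ends[k] = ends[n_ends - 1]
                n_ends -= 1
                break
    return 1, n_ends


@njit(cache=True, fastmath=True)
def _merge_candidates(pos, nb, fil_id, fil_nbeads, ends, n_ends, n_fil, edge,
                      geo, state, cand, n_cand, used, events, n_ev, sweep_no):
    """Attempt the candidate merges in random order; each end reacts at
    most once per pass."""
    for i in range(n_cand - 1, 0, -1):
        j = int(_rand(state) * (i + 1))
        t0 = cand[i, 0]
        t1 = cand[i, 1]
        cand[i, 0] = cand[j, 0]
        cand[i, 1] = cand[j, 1]
        cand[j, 0] = t0
        cand[j, 1] = t1
    n_merged = 0
    for p in range(n_cand):
        ea = cand[p, 0]
        eb = cand[p, 1]
        if used[ea] == 1 or used[eb] == 1:
            continue
        fa = fil_id[ea]
        fb = fil_id[eb]
        status, n_ends = _try_merge(pos, nb, fil_id, fil_nbeads, ends, n_ends,
                                    ea, eb, edge, geo)
        if status == 1:
            used[ea] = 1
            used[eb] = 1
            n_fil -= 1
            n_merged += 1
            if n_ev < events.shape[0]:
                events[n_ev, 0] = sweep_no
                events[n_ev, 1] = fa
                events[n_ev, 2] = fb
                events[n_ev, 3] = ea
                events[n_ev, 4] = eb
                n_ev += 1
    for p in range(n_cand):
        used[cand[p, 0]] = 0
        used[cand[p, 1]] = 0
    return n_merged, n_ends, n_fil, n_ev


@njit(cache=True, fastmath=True)
def _run_kernel(pos, nb, fil_id, fil_nbeads, ends, n_ends, n_fil, edge, geo,
                mode, state, sweep0, max_sweeps, target_nfil, record_every,
                anneal_every, rebuild_every, perm, cell_head, cell_next,
                cell_of, ncell_verlet, verlet, cand, used, events, rec_sweep,
                rec_nfil, rec_acc, capture_nfil, capture_buf):
    """Main loop: sweeps + annealing passes with early stop and recording.

    Reactive-end detection uses a Verlet pair list: every ``rebuild_every``
    sweeps all end pairs within the reaction distance plus a skin of
    ``2 * rebuild_every * max_displacement`` are cached (via a cell list);
    between rebuilds only the cached pairs are distance-checked.  Beads move
    at most ``max_displacement`` per sweep and merges never change wrapped
    coordinates, so no contact can form undetected between rebuilds.

    Returns (sweeps_done, n_ends, n_fil, n_rec, n_ev, capture_sweep,
    n_captured).  ``capture_nfil`` >= 0 requests a one-shot snapshot of the
    per-filament bead counts the first time n_fil drops to that value or
    below (used to read off the length distribution at a target mean length).
    """
    rd2 = geo[5]
    maxdisp = geo[4]
    skin = 2.0 * rebuild_every * maxdisp
    rv = np.sqrt(rd2) + skin
    rv2 = rv * rv
    n_rec = 0
    n_ev = 0
    acc_acc = 0
    att_acc = 0
    n_beads = pos.shape[0]
    capture_sweep = np.int64(-1)
    n_captured = 0
    n_verlet = -1  # force initial build
    since_rebuild = 0
    s = 0
    while s < max_sweeps:
        s += 1
        acc_acc += _sweep_kernel(pos, nb, perm, geo, mode, state)
        att_acc += n_beads
        since_rebuild += 1
        if anneal_every > 0 and s % anneal_every == 0 and n_fil > 1:
            if n_verlet < 0 or since_rebuild >= rebuild_every:
                n_verlet = _collect_pairs(pos, fil_id, ends, n_ends, edge, rv2,
                                          cell_head, cell_next, cell_of,
                                          ncell_verlet, verlet)
                if n_verlet < 0:
                    return -1, n_ends, n_fil, n_rec, n_ev, capture_sweep, n_captured
                since_rebuild = 0
            n_cand = 0
            for q in range(n_verlet):
                ea = verlet[q, 0]
                eb = verlet[q, 1]
                if nb[ea, 1] >= 0 or nb[eb, 1] >= 0:
                    continue
                dx = _min_image_1d(pos[eb, 0] - pos[ea, 0], edge)
                dy = _min_image_1d(pos[eb, 1] - pos[ea, 1], edge)
                dz = _min_image_1d(pos[eb, 2] - pos[ea, 2], edge)
                if dx * dx + dy * dy + dz * dz < rd2:
                    cand[n_cand, 0] = ea
                    cand[n_cand, 1] = eb
                    n_cand += 1
            if n_cand > 0:
                _, n_ends, n_fil, n_ev = _merge_candidates(
                    pos, nb, fil_id, fil_nbeads, ends, n_ends, n_fil, edge,
                    geo, state, cand, n_cand, used, events, n_ev, sweep0 + s)
        if capture_nfil >= 0 and capture_sweep < 0 and n_fil <= capture_nfil:
            capture_sweep = sweep0 + s
            for f in range(fil_nbeads.shape[0]):
                if fil_nbeads[f] > 0:
                    capture_buf[n_captured] = fil_nbeads[f]
                    n_captured += 1
        done = n_fil <= target_nfil or s == max_sweeps
        if s % record_every == 0 or done:
            if n_rec < rec_sweep.shape[0]:
                rec_sweep[n_rec] = sweep0 + s
                rec_nfil[n_rec] = n_fil
                rec_acc[n_rec] = acc_acc / att_acc if att_acc > 0 else 0.0
                n_rec += 1
                acc_acc = 0
                att_acc = 0
        if n_fil <= target_nfil:
            break
    return s, n_ends, n_fil, n_rec, n_ev, capture_sweep, n_captured


# --------------------------------------------------------------------------
# python-level API
# --------------------------------------------------------------------------

def _geo_array(params: SimulationParams) -> Tuple[np.ndarray, int]:
    alpha = params.max_bond_angle
    if alpha >= 90.0 or params.effective_reaction_angle >= 90.0:
        raise ValueError("engine kernels require bond/reaction angles < 90 deg")
    ca2 = math.cos(math.radians(alpha)) ** 2
    car2 = math.cos(math.radians(params.effective_reaction_angle)) ** 2
    sin2min = math.sin(math.radians(params.min_reg_angle)) ** 2
    geo = np.array(
        [
            params.bond_min ** 2,
            params.bond_max ** 2,
            ca2,
            sin2min,
            params.max_displacement,
            params.reaction_distance ** 2,
            car2,
            0.0,
        ],
        dtype=_F,
    )
    mode = 1 if params.angle_measure == UNIFORM_ANGLE else 0
    return geo, mode


class _Buffers:
    """Reusable kernel buffers bound to one SystemState."""

    REBUILD_EVERY = 5  # sweeps between Verlet-list rebuilds

    def __init__(self, state: SystemState):
        n = state.n_beads
        n_ends_cap = max(4, 2 * state.n0)
        edge = state.box.edge
        rd = state.params.reaction_distance
        ncell = int(edge // rd)
        if ncell < 3:
            ncell = 0  # all-pairs fallback
        self.ncell = ncell
        rv = rd + 2.0 * self.REBUILD_EVERY * state.params.max_displacement
        ncell_v = int(edge // rv)
        if ncell_v < 3:
            ncell_v = 0
        self.ncell_verlet = ncell_v
        self.cell_head = np.full(max(1, ncell**3, ncell_v**3), -1, dtype=np.int64)
        self.cell_next = np.full(n_ends_cap, -1, dtype=np.int64)
        self.cell_of = np.zeros(n_ends_cap, dtype=np.int64)
        self.pairs = np.zeros((max(64, 8 * n_ends_cap), 2), dtype=np.int64)
        self.verlet = np.zeros((max(256, 64 * n_ends_cap), 2), dtype=np.int64)
        self.cand = np.zeros_like(self.verlet)
        self.used = np.zeros(n, dtype=np.int8)
        self.perm = np.arange(n, dtype=np.int64)
        self.events = np.zeros((state.n0, 5), dtype=np.int64)


def _buffers(state: SystemState) -> _Buffers:
    buf = getattr(state, "_buffers", None)
    if buf is None or buf.perm.shape[0] != state.n_beads:
        buf = _Buffers(state)
        state.__dict__["_buffers"] = buf
    return buf


@dataclass
class ReactionEvent:
    """One end-to-end annealing event: the two merged filaments and the
    terminal beads that formed the new bond."""

    sweep_count: int
    filament_a: int
    filament_b: int
    end_a: int = -1
    end_b: int = -1


@dataclass
class Trajectory:
    """Recorded (sweep, filament count, mean length) time series of a run."""

    sweeps: np.ndarray          # int64
    n_filaments: np.ndarray     # int64
    acceptance: np.ndarray      # float64, mean since previous record
    n0: int
    params: SimulationParams
    seed: int
    events: List[ReactionEvent] = field(default_factory=list)
    capture_mean_ulf: Optional[float] = None
    capture_sweep: Optional[int] = None
    capture_ulf_counts: Optional[np.ndarray] = None

    def __post_init__(self) -> None:
        s = np.asarray(self.sweeps)
        if s.size and np.any(np.diff(s) <= 0):
            raise ValueError("sweep counts must be strictly increasing")
        nf = np.asarray(self.n_filaments)
        if nf.size and np.any(np.diff(nf) > 0):
            raise ValueError("filament count must be non-increasing")

    @property
    def mean_ulf(self) -> np.ndarray:
        return self.n0 / self.n_filaments.astype(float)

    def sweeps_to_mean_ulf(self, target: float) -> Optional[int]:
        """First recorded sweep count at which <l_n> >= target."""
        hit = np.nonzero(self.mean_ulf >= target)[0]
        if hit.size == 0:
            return None
        return int(self.sweeps[hit[0]])

    def to_dataframe(self):
        import pandas as pd

        return pd.DataFrame(
            {
                "sweep": self.sweeps,
                "n_filaments": self.n_filaments,
                "mean_ulf": self.mean_ulf,
                "acceptance": self.acceptance,
            }
        )


def mean_ulf_length(state: SystemState) -> float:
    """Mean filament length <l_n> in ULF units: n0 / (filament count)."""
    if state.n_filaments < 1:
        raise ValueError("empty system")
    return state.n0 / state.n_filaments


def sweeps_to_seconds(sweeps: float, params: SimulationParams) -> float:
    """Convert a sweep count to seconds (one sweep ~ 1 ns)."""
    if sweeps < 0:
        raise ValueError("sweeps must be >= 0")
    return sweeps * params.sweep_time_s


def trial_move(state: SystemState, filament_id: int, bead_index: int, rng=None) -> bool:
    """Attempt one displacement of the given bead; True if accepted.

    The bead is addressed by its filament and position along the chain
    (0-based from one end).  Uses and advances the state's own generator.
    """
    fils_beads = _chain_bead_ids(state, filament_id)
    if bead_index < 0 or bead_index >= len(fils_beads):
        raise IndexError("bead index out of range")
    i = fils_beads[bead_index]
    geo, mode = _geo_array(state.params)
    return bool(_attempt_move(state.pos, state.nb, i, geo, mode, state.rng_state))


def _chain_bead_ids(state: SystemState, filament_id: int) -> List[int]:
    if state.fil_nbeads[filament_id] <= 0:
        raise KeyError(f"filament {filament_id} does not exist")
    members = np.nonzero(state.fil_id == filament_id)[0]
    end = -1
    for m in members:
        if state.nb[m, 1] == -1:
            end = int(m)
            break
    chain = [end]
    prev, cur = -1, end
    while True:
        a, b = int(state.nb[cur, 0]), int(state.nb[cur, 1])
        nxt = a if a != prev else b
        if nxt < 0:
            break
        chain.append(nxt)
        prev, cur = cur, nxt
    return chain


def sweep(state: SystemState, rng=None) -> float:
    """One MC time step: one trial move per bead; returns the acceptance
    fraction.  Does not attempt annealing."""
    geo, mode = _geo_array(state.params)
    buf = _buffers(state)
    acc = _sweep_kernel(state.pos, state.nb, buf.perm, geo, mode, state.rng_state)
    state.sweep_count += 1
    return acc / state.n_beads


def detect_reactive_pairs(state: SystemState) -> np.ndarray:
    """All unordered end pairs on different filaments within the reaction
    distance (minimum image).  Returns an (n, 2) array of bead indices."""
    geo, _ = _geo_array(state.params)
    buf = _buffers(state)
    n_ends = len(state.ends)
    while True:
        n = _collect_pairs(
            state.pos, state.fil_id, state.ends, n_ends, state.box.edge,
            geo[5], buf.cell_head, buf.cell_next, buf.cell_of, buf.ncell,
            buf.pairs,
        )
        if n >= 0:
            break
        buf.pairs = np.zeros((buf.pairs.shape[0] * 2, 2), dtype=np.int64)
    return buf.pairs[:n].copy()


def anneal(state: SystemState, pair) -> bool:
    """Attempt to merge the two filaments whose ends form ``pair``.

    ``pair`` is a (bead_a, bead_b) index pair as returned by
    :func:`detect_reactive_pairs`.  Raises :class:`StalePairError` if either
    end has already been consumed by a previous merge.
    """
    ea, eb = int(pair[0]), int(pair[1])
    geo, _ = _geo_array(state.params)
    ends = np.asarray(state.ends, dtype=np.int64).copy()
    status, n_ends = _try_merge(
        state.pos, state.nb, state.fil_id, state.fil_nbeads, ends,
        len(ends), ea, eb, state.box.edge, geo,
    )
    if status == -1:
        raise StalePairError(f"pair ({ea}, {eb}) no longer joins two distinct ends")
    if status == 1:
        state.ends = ends[:n_ends]
        state.n_filaments -= 1
        return True
    return False


def run(
    state: SystemState,
    target_mean_ulf: Optional[float] = None,
    max_sweeps: Optional[int] = None,
    record_every: int = 1000,
    anneal_every: int = 1,
    capture_mean_ulf: Optional[float] = None,
) -> Trajectory:
    """Alternate sweeps and annealing passes until a stop criterion is met.

    Stops when <l_n> reaches ``target_mean_ulf`` or after ``max_sweeps``
    sweeps (at least one must be given).  Records (sweep, n_filaments,
    acceptance) every ``record_every`` sweeps and at the stop point.  If
    ``capture_mean_ulf`` is set, the per-filament ULF counts are snapshotted
    the first time <l_n> crosses that value and attached to the trajectory.
    The state is advanced in place.
    """
    if target_mean_ulf is None and max_sweeps is None:
        raise ValueError("need a stop criterion: target_mean_ulf or max_sweeps")
    if target_mean_ulf is not None:
        if target_mean_ulf > state.n0:
            raise ValueError(
                f"target <l_n>={target_mean_ulf} unreachable with n0={state.n0}"
            )
        target_nfil = int(state.n0 // target_mean_ulf)
    else:
        target_nfil = 0
    if max_sweeps is None:
        max_sweeps = np.iinfo(np.int64).max // 2
    if record_every < 1:
        raise ValueError("record_every must be >= 1")

    geo, mode = _geo_array(state.params)
    buf = _buffers(state)
    k = state.params.beads_per_ulf
    capture_nfil = -1
    capture_buf = np.zeros(1, dtype=np.int64)
    if capture_mean_ulf is not None:
        capture_nfil = int(state.n0 // capture_mean_ulf)
        capture_buf = np.zeros(state.n0, dtype=np.int64)

    max_records = min(int(max_sweeps) // record_every + 4, 4_000_000)
    rec_sweep = np.zeros(max_records, dtype=np.int64)
    rec_nfil = np.zeros(max_records, dtype=np.int64)
    rec_acc = np.zeros(max_records, dtype=_F)

    ends = np.zeros(buf.cell_next.shape[0], dtype=np.int64)
    ends[: len(state.ends)] = state.ends
    n_ends = len(state.ends)

    out = _run_kernel(
        state.pos, state.nb, state.fil_id, state.fil_nbeads, ends, n_ends,
        state.n_filaments, state.box.edge, geo, mode, state.rng_state,
        state.sweep_count, int(max_sweeps), target_nfil, record_every,
        anneal_every, buf.REBUILD_EVERY, buf.perm, buf.cell_head,
        buf.cell_next, buf.cell_of, buf.ncell_verlet, buf.verlet, buf.cand,
        buf.used, buf.events, rec_sweep, rec_nfil, rec_acc, capture_nfil,
        capture_buf,
    )
    sweeps_done, n_ends, n_fil, n_rec, n_ev, capture_sweep, n_captured = out
    if sweeps_done < 0:
        raise RuntimeError("reactive-pair buffer overflow; system too dense")

    state.sweep_count += int(sweeps_done)
    state.n_filaments = int(n_fil)
    state.ends = ends[:n_ends].copy()

    events = [
        ReactionEvent(*(int(x) for x in buf.events[i, :5])) for i in range(n_ev)
    ]
    traj = Trajectory(
        sweeps=rec_sweep[:n_rec].copy(),
        n_filaments=rec_nfil[:n_rec].copy(),
        acceptance=rec_acc[:n_rec].copy(),
        n0=state.n0,
        params=state.params,
        seed=state.seed,
        events=events,
        capture_mean_ulf=capture_mean_ulf,
        capture_sweep=int(capture_sweep) if capture_sweep >= 0 else None,
        capture_ulf_counts=(capture_buf[:n_captured] // k).copy()
        if capture_nfil >= 0 and n_captured > 0
        else None,
    )
    return traj
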