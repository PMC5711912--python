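"""Compiled numerical core.

Everything performance-critical lives here as numba-jitted functions
operating on flat arrays: categorical row sampling, the multiplicative
feedback update with clamping and row renormalization, maze generation
with breadth-first distance labeling, and the full per-mapping episode
loop. The object layer (gates, brains, environment) calls into these
same functions so there is exactly one implementation of the numerics.

Array encoding of a brain (one row per gate):
  kind        0 = deterministic, 1 = probabilistic, 2 = feedback
  n_in, n_out number of input/output wires (1..4)
  in_nodes    int[G, 4] node indices read (wire k -> bit k of the pattern)
  out_nodes   int[G, 4] node indices written
  det_table   int[G, 16] output pattern per input pattern
  P, P_birth  float[G, 16, 16] probability tables (padded)
  pos_node, neg_node, depth, dpos, dneg   feedback wiring / schedules
  hist_i, hist_o, hist_len                decision buffer, most recent first

Maze encoding: 64x64 arrays; ``dist`` is the shortest-path distance to
the goal over 4-neighbor moves (-1 for walls/unreachable), ``arrows``
holds the absolute direction (0=up 1=right 2=down 3=left) of a neighbor
one step closer to the goal.
"""

from __future__ import annotations

import numpy as np
from numba import njit

MAZE_SIZE = 64
WALL_FRACTION = 1.0 / 7.0
SPAWN_DISTANCE = 32

# direction deltas indexed by 0=up 1=right 2=down 3=left
_DR = np.array([-1, 0, 1, 0], dtype=np.int64)
_DC = np.array([0, 1, 0, -1], dtype=np.int64)

P_FLOOR = 0.01
P_CEIL = 0.99


@njit(cache=True)
def sample_row(row, n, r):
    """Sample a column index from ``row[:n]`` using uniform draw ``r``."""
    acc = 0.0
    for j in range(n):
        acc += row[j]
        if r < acc:
            return j
    return n - 1


@njit(cache=True)
def feedback_update_row(row, n, o, u, positive):
    """Shift ``row[o]`` by ``u`` and renormalize ``row[:n]`` in place.

    The changed entry is clamped to [0.01, min(0.99, 1 - 0.01*(n-1))];
    the remaining entries are rescaled proportionally, with any entry
    that would fall below the 0.01 floor pinned there and the rest
    rescaled again until the row is feasible. Row sums stay at 1.
    """
    cap = 1.0 - P_FLOOR * (n - 1)
    if cap > P_CEIL:
        cap = P_CEIL
    if positive:
        v = row[o] + u
    else:
        v = row[o] - u
    if v > cap:
        v = cap
    if v < P_FLOOR:
        v = P_FLOOR
    row[o] = v

    remaining = 1.0 - v
    free_sum = 0.0
    for j in range(n):
        if j != o:
            free_sum += row[j]
    if free_sum <= 0.0:
        for j in range(n):
            if j != o:
                row[j] = remaining / (n - 1)
        return

    # 0 = free, 1 = target, 2 = pinned at the floor
    status = np.zeros(n, dtype=np.uint8)
    status[o] = 1
    changed = True
    while changed:
        changed = False
        if free_sum <= 0.0:
            # every non-target entry pinned at the floor (target at cap)
            break
        scale = remaining / free_sum
        for j in range(n):
            if status[j] == 0 and row[j] * scale < P_FLOOR:
                status[j] = 2
                remaining -= P_FLOOR
                free_sum -= row[j]
                changed = True
    if free_sum > 0.0:
        scale = remaining / free_sum
    else:
        scale = 0.0
    for j in range(n):
        if status[j] == 2:
            row[j] = P_FLOOR
        elif status[j] == 0:
            row[j] = row[j] * scale


@njit(cache=True)
def generate_maze_arrays(rng):
    """Generate one 64x64 maze; returns (ok, walls, dist, arrows, goal).

    Interior tiles become walls independently with probability 1/7; the
    border is solid. The goal is a uniform random empty tile; ``dist``
    is filled by breadth-first search from the goal; every reachable
    tile gets an arrow toward a uniformly chosen neighbor one step
    closer. The maze is rebuilt from scratch until at least one tile
    sits exactly 32 steps from the goal; ``ok`` reports whether that
    succeeded within the retry cap.
    """
    n = MAZE_SIZE
    walls = np.ones((n, n), dtype=np.bool_)
    dist = np.full((n, n), -1, dtype=np.int16)
    arrows = np.full((n, n), -1, dtype=np.int8)
    queue = np.empty(n * n, dtype=np.int32)
    goal = np.zeros(2, dtype=np.int64)

    for _attempt in range(10_000):
        fill = rng.random((n - 2) * (n - 2))
        n_empty = 0
        for r in range(1, n - 1):
            for c in range(1, n - 1):
                walls[r, c] = fill[(r - 1) * (n - 2) + (c - 1)] < WALL_FRACTION
                if not walls[r, c]:
                    n_empty += 1
        if n_empty == 0:
            continue
        k = rng.integers(0, n_empty)
        gr = -1
        gc = -1
        seen = 0
        for r in range(n):
            if gr >= 0:
                break
            for c in range(n):
                if not walls[r, c]:
                    if seen == k:
                        gr = r
                        gc = c
                        break
                    seen += 1

        dist[:, :] = -1
        dist[gr, gc] = 0
        queue[0] = gr * n + gc
        head = 0
        tail = 1
        has_spawn = False
        while head < tail:
            v = queue[head]
            head += 1
            r = v // n
            c = v % n
            d = dist[r, c]
            for a in range(4):
                rr = r + _DR[a]
                cc = c + _DC[a]
                if not walls[rr, cc] and dist[rr, cc] < 0:
                    dist[rr, cc] = d + 1
                    if d + 1 == SPAWN_DISTANCE:
                        has_spawn = True
                    queue[tail] = rr * n + cc
                    tail += 1
        if not has_spawn:
            continue

        arrows[:, :] = -1
        tie = rng.random((n - 2) * (n - 2))
        for r in range(1, n - 1):
            for c in range(1, n - 1):
                d = dist[r, c]
                if d <= 0:
                    continue
                cnt = 0
                for a in range(4):
                    if dist[r + _DR[a], c + _DC[a]] == d - 1:
                        cnt += 1
                pick = int(tie[(r - 1) * (n - 2) + (c - 1)] * cnt)
                seen2 = 0
                for a in range(4):
                    if dist[r + _DR[a], c + _DC[a]] == d - 1:
                        if seen2 == pick:
                            arrows[r, c] = a
                            break
                        seen2 += 1
        goal[0] = gr
        goal[1] = gc
        return True, walls, dist, arrows, goal
    return False, walls, dist, arrows, goal


@njit(cache=True)
def spawn_tiles(dist):
    """Coordinates of all tiles at the spawn distance from the goal."""
    n = dist.shape[0]
    cnt = 0
    for r in range(n):
        for c in range(n):
            if dist[r, c] == SPAWN_DISTANCE:
                cnt += 1
    out = np.empty((cnt, 2), dtype=np.int64)
    k = 0
    for r in range(n):
        for c in range(n):
            if dist[r, c] == SPAWN_DISTANCE:
                out[k, 0] = r
                out[k, 1] = c
                k += 1
    return out


@njit(cache=True)
def _push_history(hist_i, hist_o, hist_len, g, depth, i, o):
    m = hist_len[g]
    if m < depth:
        m += 1
        hist_len[g] = m
    for k in range(m - 1, 0, -1):
        hist_i[g, k] = hist_i[g, k - 1]
        hist_o[g, k] = hist_o[g, k - 1]
    hist_i[g, 0] = i
    hist_o[g, 0] = o


@njit(cache=True)
def brain_step_arrays(
    kind, n_in, n_out, in_nodes, out_nodes, det_table, P,
    pos_node, neg_node, depth, dpos, dneg, hist_i, hist_o, hist_len,
    state, sensor_bits, feedback_enabled, rng, nxt,
):
    """One synchronous brain update; mutates ``state`` (and, for
    feedback gates, the probability tables and decision buffers).

    Sensors are overwritten first; feedback lines are read from the
    pre-update state and applied before any gate samples; all gates
    then read the pre-update state and OR their outputs into a fresh
    zero next-state, which replaces the hidden and output nodes.
    Returns the 2-bit option (node4 | node5 << 1).
    """
    n_gates = kind.shape[0]
    for b in range(4):
        state[b] = sensor_bits[b]

    # feedback phase: positive first, then negative, in gate order
    for g in range(n_gates):
        if kind[g] == 2:
            if feedback_enabled:
                if state[pos_node[g]] == 1:
                    for k in range(hist_len[g]):
                        u = rng.random() * dpos[g, k]
                        feedback_update_row(
                            P[g, hist_i[g, k]], 1 << n_out[g], hist_o[g, k], u, True
                        )
                if state[neg_node[g]] == 1:
                    for k in range(hist_len[g]):
                        u = rng.random() * dneg[g, k]
                        feedback_update_row(
                            P[g, hist_i[g, k]], 1 << n_out[g], hist_o[g, k], u, False
                        )

    for j in range(16):
        nxt[j] = 0
    for g in range(n_gates):
        i = 0
        for k in range(n_in[g]):
            if state[in_nodes[g, k]] == 1:
                i |= 1 << k
        if kind[g] == 0:
            o = det_table[g, i]
        else:
            r = rng.random()
            o = sample_row(P[g, i], 1 << n_out[g], r)
            if kind[g] == 2:
                _push_history(hist_i, hist_o, hist_len, g, depth[g], i, o)
        for k in range(n_out[g]):
            if (o >> k) & 1:
                nxt[out_nodes[g, k]] = 1
    for j in range(4, 16):
        state[j] = nxt[j]
    return state[4] | (state[5] << 1)


@njit(cache=True)
def run_episode(
    kind, n_in, n_out, in_nodes, out_nodes, det_table, P,
    pos_node, neg_node, depth, dpos, dneg, hist_i, hist_o, hist_len,
    state, feedback_enabled,
    walls, dist, arrows, spawns, action_map, T, rng, trace,
):
    """Run one lifetime of ``T`` world updates on a fixed maze.

    The agent spawns on a random spawn-distance tile with random
    heading; each update it senses the tile arrow relative to its
    heading, steps the brain, translates the 2-bit option through
    ``action_map``, moves (forward moves into walls are no-ops), and
    accrues 1/(1+d) at its resulting tile. Reaching the goal counts a
    goal and respawns the agent. Returns (dwell_sum, goal_count);
    ``trace`` (T x 7 int32) receives t, row, col, heading, option,
    action, d per update.
    """
    n_spawn = spawns.shape[0]
    j = rng.integers(0, n_spawn)
    ar = spawns[j, 0]
    ac = spawns[j, 1]
    heading = rng.integers(0, 4)
    sensor = np.zeros(4, dtype=np.uint8)
    nxt = np.zeros(16, dtype=np.uint8)
    inner = 0.0
    goals = 0
    for t in range(T):
        rel = (arrows[ar, ac] - heading) % 4
        for b in range(4):
            sensor[b] = 1 if b == rel else 0
        option = brain_step_arrays(
            kind, n_in, n_out, in_nodes, out_nodes, det_table, P,
            pos_node, neg_node, depth, dpos, dneg, hist_i, hist_o, hist_len,
            state, sensor, feedback_enabled, rng, nxt,
        )
        action = action_map[option]
        if action == 0:  # forward
            rr = ar + _DR[heading]
            cc = ac + _DC[heading]
            if not walls[rr, cc]:
                ar = rr
                ac = cc
        elif action == 2:  # turn left
            heading = (heading + 3) % 4
        elif action == 3:  # turn right
            heading = (heading + 1) % 4
        d = dist[ar, ac]
        inner += 1.0 / (1.0 + d)
        trace[t, 0] = t
        trace[t, 1] = ar
        trace[t, 2] = ac
        trace[t, 3] = heading
        trace[t, 4] = option
        trace[t, 5] = action
        trace[t, 6] = d
        if d == 0:
            goals += 1
            j = rng.integers(0, n_spawn)
            ar = spawns[j, 0]
            ac = spawns[j, 1]
            heading = rng.integers(0, 4)
    return inner, goals


@njit(cache=True)
def evaluate_all_mappings(
    kind, n_in, n_out, in_nodes, out_nodes, det_table, P, P_birth,
    pos_node, neg_node, depth, dpos, dneg, hist_i, hist_o, hist_len,
    state, feedback_enabled,
    action_maps, T, b, rng, record_tables, table_out, trace_out,
):
    """Evaluate a brain on every option-to-action mapping.

    For each mapping the brain is reset to its birth state, a fresh
    maze is generated, and one episode is run. Returns per-mapping
    scores (dwell sum + goals * b), goal counts, and pooled action
    counts; per-mapping trajectories go to ``trace_out``. When
    ``record_tables`` is set, the end-of-lifetime probability tables
    are copied into ``table_out`` per mapping.
    """
    n_maps = action_maps.shape[0]
    n_gates = kind.shape[0]
    scores = np.zeros(n_maps, dtype=np.float64)
    goals = np.zeros(n_maps, dtype=np.int64)
    action_counts = np.zeros((n_maps, 4), dtype=np.int64)
    for m in range(n_maps):
        # reset to birth state
        state[:] = 0
        for g in range(n_gates):
            if kind[g] == 2:
                P[g] = P_birth[g]
                hist_len[g] = 0
        ok, walls, dist, arrows, goal = generate_maze_arrays(rng)
        if not ok:
            scores[m] = np.nan
            continue
        spawns = spawn_tiles(dist)
        inner, g_cnt = run_episode(
            kind, n_in, n_out, in_nodes, out_nodes, det_table, P,
            pos_node, neg_node, depth, dpos, dneg, hist_i, hist_o, hist_len,
            state, feedback_enabled,
            walls, dist, arrows, spawns, action_maps[m], T, rng, trace_out[m],
        )
        scores[m] = inner + g_cnt * b
        goals[m] = g_cnt
        for t in range(T):
            action_counts[m, trace_out[m, t, 5]] += 1
        if record_tables:
            for g in range(n_gates):
                table_out[m, g] = P[g]
    return scores, goals, action_counts
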