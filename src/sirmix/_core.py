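"""Numba cores for the stochastic SIR simulators.

All rates here are per second; times are seconds.  The temporal-network core
implements a temporal Gillespie scheme: a unit-exponential deviate is consumed
against the piecewise-constant total event rate (``beta * #SI-contacts +
mu * I``), which changes at 20 s contact-window boundaries and at epidemic
events.  The contact sequence is extended periodically (window index modulo
the number of windows) until the epidemic dies out.
"""

from __future__ import annotations

import numpy as np
from numba import njit

# state codes
S, I, R = 0, 1, 2

# safety cap on simulated time per realization (seconds); with mu > 0 the
# epidemic ends long before this in any realistic configuration.
MAX_TIME = 2000.0 * 86400.0


@njit(cache=True)
def _run_sir_net(
    window_ptr,
    e_src,
    e_dst,
    n_windows,
    res,
    n_nodes,
    beta,
    mu,
    seed_node,
    seed_time,
    stop_at_seed_recovery,
    rseed,
):
    """One temporal-Gillespie SIR realization on a periodic contact sequence.

    Returns (ev_time, ev_node, ev_is_recovery, n_events, infector) where event
    times are absolute seconds (seeding at ``seed_time``) and ``infector[v]``
    is the node that infected v (-1 if never infected; seed's infector is
    itself).
    """
    np.random.seed(rseed)
    state = np.zeros(n_nodes, dtype=np.uint8)
    infector = -np.ones(n_nodes, dtype=np.int32)
    state[seed_node] = I
    infector[seed_node] = seed_node
    n_inf = 1

    max_ev = 2 * n_nodes
    ev_time = np.empty(max_ev, dtype=np.float64)
    ev_node = np.empty(max_ev, dtype=np.int32)
    ev_rec = np.empty(max_ev, dtype=np.uint8)
    n_ev = 0

    t = seed_time
    u = -np.log(np.random.random())
    while n_inf > 0 and t < MAX_TIME:
        wabs = np.int64(t // res)
        w = wabs % n_windows
        t_end = (wabs + 1) * res
        # count susceptible-infectious contacts in this window
        m = 0
        for k in range(window_ptr[w], window_ptr[w + 1]):
            a, b = e_src[k], e_dst[k]
            if (state[a] == I and state[b] == S) or (state[a] == S and state[b] == I):
                m += 1
        rate = beta * m + mu * n_inf
        span = t_end - t
        if rate * span < u:
            u -= rate * span
            t = t_end
            continue
        t += u / rate
        if np.random.random() * rate < beta * m:
            # infection: pick the r-th SI contact of the window
            r = np.int64(np.random.random() * m)
            c = 0
            for k in range(window_ptr[w], window_ptr[w + 1]):
                a, b = e_src[k], e_dst[k]
                if (state[a] == I and state[b] == S) or (state[a] == S and state[b] == I):
                    if c == r:
                        if state[a] == S:
                            v, src = a, b
                        else:
                            v, src = b, a
                        state[v] = I
                        infector[v] = src
                        n_inf += 1
                        ev_time[n_ev] = t
                        ev_node[n_ev] = v
                        ev_rec[n_ev] = 0
                        n_ev += 1
                        break
                    c += 1
        else:
            # recovery: pick the r-th infectious node
            r = np.int64(np.random.random() * n_inf)
            c = 0
            for v in range(n_nodes):
                if state[v] == I:
                    if c == r:
                        state[v] = R
                        n_inf -= 1
                        ev_time[n_ev] = t
                        ev_node[n_ev] = v
                        ev_rec[n_ev] = 1
                        n_ev += 1
                        if stop_at_seed_recovery and v == seed_node:
                            return ev_time, ev_node, ev_rec, n_ev, infector
                        break
                    c += 1
        u = -np.log(np.random.random())
    return ev_time, ev_node, ev_rec, n_ev, infector


@njit(cache=True)
def _accumulate_curve(prev_sum, ev_time, ev_rec, n_ev, seed_time, grid_dt, n_nodes):
    """Add one realization's I(t)/N, sampled at grid points, onto prev_sum."""
    n_inf = 1
    k = 0
    for g in range(len(prev_sum)):
        tg = seed_time + g * grid_dt
        while k < n_ev and ev_time[k] <= tg:
            if ev_rec[k] == 1:
                n_inf -= 1
            else:
                n_inf += 1
            k += 1
        if n_inf == 0 and k >= n_ev:
            break
        prev_sum[g] += n_inf / n_nodes


@njit(cache=True)
def _ensemble_net(
    window_ptr,
    e_src,
    e_dst,
    n_windows,
    res,
    n_nodes,
    beta,
    mu,
    seed_nodes,
    seed_times,
    rseeds,
    grid_dt,
    n_grid,
):
    """Ensemble of network SIR runs: mean prevalence curve and final sizes."""
    prev_sum = np.zeros(n_grid, dtype=np.float64)
    final_sizes = np.empty(len(rseeds), dtype=np.float64)
    for r in range(len(rseeds)):
        ev_time, ev_node, ev_rec, n_ev, infector = _run_sir_net(
            window_ptr, e_src, e_dst, n_windows, res, n_nodes, beta, mu,
            seed_nodes[r], seed_times[r], False, rseeds[r],
        )
        _accumulate_curve(prev_sum, ev_time, ev_rec, n_ev, seed_times[r], grid_dt, n_nodes)
        n_recovered = 0
        for k in range(n_ev):
            if ev_rec[k] == 1:
                n_recovered += 1
        final_sizes[r] = n_recovered / n_nodes
    return prev_sum / len(rseeds), final_sizes


@njit(cache=True)
def _seed_infection_counts(
    window_ptr, e_src, e_dst, n_windows, res, n_nodes, beta, mu,
    seed_nodes, seed_times, rseeds,
):
    """Secondary infections of the seed in a fully susceptible population.

    Only the seed transmits: infected contacts are removed from the seed's
    future targets but generate no tertiary cases.  Each run ends at the
    seed's recovery, when the count is fixed.
    """
    counts = np.empty(len(rseeds), dtype=np.float64)
    removed = np.zeros(n_nodes, dtype=np.uint8)
    for r in range(len(rseeds)):
        np.random.seed(rseeds[r])
        seed = seed_nodes[r]
        removed[:] = 0
        removed[seed] = 1
        c = 0
        t = seed_times[r]
        u = -np.log(np.random.random())
        while t < MAX_TIME:
            wabs = np.int64(t // res)
            w = wabs % n_windows
            t_end = (wabs + 1) * res
            # susceptible contacts of the seed in this window
            m = 0
            for k in range(window_ptr[w], window_ptr[w + 1]):
                a, b = e_src[k], e_dst[k]
                if (a == seed and removed[b] == 0) or (b == seed and removed[a] == 0):
                    m += 1
            rate = beta * m + mu
            span = t_end - t
            if rate * span < u:
                u -= rate * span
                t = t_end
                continue
            t += u / rate
            if np.random.random() * rate < beta * m:
                pick = np.int64(np.random.random() * m)
                cnt = 0
                for k in range(window_ptr[w], window_ptr[w + 1]):
                    a, b = e_src[k], e_dst[k]
                    if (a == seed and removed[b] == 0) or (b == seed and removed[a] == 0):
                        if cnt == pick:
                            removed[b if a == seed else a] = 1
                            c += 1
                            break
                        cnt += 1
            else:
                break  # seed recovers
            u = -np.log(np.random.random())
        counts[r] = c
    return counts


@njit(cache=True)
def _run_sir_homo(n_nodes, beta, mu, rseed):
    """One classic-Gillespie realization of frequency-dependent SIR.

    Transitions: S -> I at total rate ``beta * S * I / N``; I -> R at total
    rate ``mu * I``.  Starts from (N-1, 1, 0); returns event times (seconds
    from seeding) and types (0 infection, 1 recovery).
    """
    np.random.seed(rseed)
    n_s = n_nodes - 1
    n_i = 1
    max_ev = 2 * n_nodes
    ev_time = np.empty(max_ev, dtype=np.float64)
    ev_rec = np.empty(max_ev, dtype=np.uint8)
    n_ev = 0
    t = 0.0
    while n_i > 0:
        rate_inf = beta * n_s * n_i / n_nodes
        rate = rate_inf + mu * n_i
        t += -np.log(np.random.random()) / rate
        if np.random.random() * rate < rate_inf:
            n_s -= 1
            n_i += 1
            ev_rec[n_ev] = 0
        else:
            n_i -= 1
            ev_rec[n_ev] = 1
        ev_time[n_ev] = t
        n_ev += 1
    return ev_time, ev_rec, n_ev


@njit(cache=True)
def _ensemble_homo(n_nodes, beta, mu, rseeds, grid_dt, n_grid):
    """Ensemble of homogeneous-mixing runs: mean prevalence and final sizes."""
    prev_sum = np.zeros(n_grid, dtype=np.float64)
    final_sizes = np.empty(len(rseeds), dtype=np.float64)
    for r in range(len(rseeds)):
        ev_time, ev_rec, n_ev = _run_sir_homo(n_nodes, beta, mu, rseeds[r])
        _accumulate_curve(prev_sum, ev_time, ev_rec, n_ev, 0.0, grid_dt, n_nodes)
        n_recovered = 0
        for k in range(n_ev):
            if ev_rec[k] == 1:
                n_recovered += 1
        final_sizes[r] = n_recovered / n_nodes
    return prev_sum / len(rseeds), final_sizes


@njit(cache=True)
def _generate_contacts(
    n_nodes,
    group_idx,
    a_in,
    a_out,
    b,
    z,
    dt,
    duration,
    resolution,
    rseed,
):
    """Memory-driven contact generator core.

    Discrete clock of step ``dt`` seconds; per step, each active link (i,j)
    dies with probability ``dt*z/(1+tau_ij)`` and each agent initiates with
    probability ``dt*b/(1+tau_i)``, choosing the partner among its non-contacts
    with weight ``a[p,q]/(1+tau_j)/(1+tau_ij)`` (tau in seconds).  Emits one
    event per link per ``resolution`` window in which the link was active.
    Returns (times, src, dst) arrays.
    """
    np.random.seed(rseed)
    active = np.zeros((n_nodes, n_nodes), dtype=np.uint8)
    t_node = np.zeros(n_nodes, dtype=np.float64)
    t_link = np.zeros((n_nodes, n_nodes), dtype=np.float64)
    last_emit = -np.ones((n_nodes, n_nodes), dtype=np.int64)
    # active edge list with positions for O(1) removal
    max_edges = n_nodes * (n_nodes - 1) // 2
    edge_i = np.empty(max_edges, dtype=np.int32)
    edge_j = np.empty(max_edges, dtype=np.int32)
    edge_pos = -np.ones((n_nodes, n_nodes), dtype=np.int64)
    n_active = 0

    cap = 1 << 16
    ev_t = np.empty(cap, dtype=np.int64)
    ev_i = np.empty(cap, dtype=np.int32)
    ev_j = np.empty(cap, dtype=np.int32)
    n_ev = 0

    weights = np.empty(n_nodes, dtype=np.float64)
    n_steps = np.int64(duration / dt)
    for s in range(n_steps):
        t = s * dt
        # rule (i): terminate active links
        k = 0
        while k < n_active:
            i, j = edge_i[k], edge_j[k]
            tau = t - t_link[i, j]
            if np.random.random() < dt * z / (1.0 + tau):
                active[i, j] = active[j, i] = 0
                t_link[i, j] = t_link[j, i] = t
                t_node[i] = t_node[j] = t
                # swap-remove
                n_active -= 1
                edge_pos[i, j] = edge_pos[j, i] = -1
                if k != n_active:
                    li, lj = edge_i[n_active], edge_j[n_active]
                    edge_i[k], edge_j[k] = li, lj
                    edge_pos[li, lj] = edge_pos[lj, li] = k
            else:
                k += 1
        # rule (ii): initiate contacts
        for i in range(n_nodes):
            if np.random.random() >= dt * b / (1.0 + (t - t_node[i])):
                continue
            tot = 0.0
            for j in range(n_nodes):
                if j == i or active[i, j] == 1:
                    weights[j] = 0.0
                else:
                    a = a_in if group_idx[i] == group_idx[j] else a_out
                    weights[j] = a / (1.0 + (t - t_node[j])) / (1.0 + (t - t_link[i, j]))
                tot += weights[j]
            if tot <= 0.0:
                continue
            u = np.random.random() * tot
            acc = 0.0
            j = n_nodes - 1
            for jj in range(n_nodes):
                acc += weights[jj]
                if u < acc:
                    j = jj
                    break
            if active[i, j] == 0:
                active[i, j] = active[j, i] = 1
                t_link[i, j] = t_link[j, i] = t
                t_node[i] = t_node[j] = t
                edge_i[n_active], edge_j[n_active] = min(i, j), max(i, j)
                edge_pos[i, j] = edge_pos[j, i] = n_active
                n_active += 1
        # emit events: one per link per resolution window it is active in
        w = np.int64(t // resolution)
        for k in range(n_active):
            i, j = edge_i[k], edge_j[k]
            if last_emit[i, j] < w:
                last_emit[i, j] = w
                if n_ev == cap:
                    cap *= 2
                    new_t = np.empty(cap, dtype=np.int64)
                    new_i = np.empty(cap, dtype=np.int32)
                    new_j = np.empty(cap, dtype=np.int32)
                    new_t[:n_ev] = ev_t[:n_ev]
                    new_i[:n_ev] = ev_i[:n_ev]
                    new_j[:n_ev] = ev_j[:n_ev]
                    ev_t, ev_i, ev_j = new_t, new_i, new_j
                ev_t[n_ev] = w * resolution
                ev_i[n_ev] = i
                ev_j[n_ev] = j
                n_ev += 1
    return ev_t[:n_ev], ev_i[:n_ev], ev_j[:n_ev]
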