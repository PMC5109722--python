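"""Independent brute-force oracles shared by the test modules.

These deliberately avoid the package's temporal-Gillespie machinery: epidemics
are advanced with small-step Bernoulli updates so that the exact event-driven
simulators can be validated against them.
"""

import math

import numpy as np


def discretized_network_final_sizes(
    net, beta_per_day, mu_per_day, n_reps, seed, substeps=100, max_periods=40
):
    """Final-size sample from a per-window small-step discretized SIR.

    Time advances in steps of resolution/substeps; within each step every
    susceptible-infectious contact transmits independently and every
    infectious node recovers independently, looping the window sequence
    periodically until extinction.  Seeded at node 0, time 0.
    """
    beta = beta_per_day / 86400.0
    mu = mu_per_day / 86400.0
    ptr, src, dst = net.window_csr()
    n_windows = len(ptr) - 1
    n = net.n_nodes
    sub = net.resolution / substeps

    rng = np.random.default_rng(seed)
    states = np.zeros((n_reps, n), dtype=np.uint8)
    states[:, 0] = 1
    p_rec = 1.0 - math.exp(-mu * sub)
    alive = np.ones(n_reps, dtype=bool)
    step_idx = 0
    max_steps = substeps * n_windows * max_periods
    while alive.any() and step_idx < max_steps:
        w = (step_idx // substeps) % n_windows
        pressure = np.zeros((n_reps, n))
        for k in range(ptr[w], ptr[w + 1]):
            a, b = src[k], dst[k]
            pressure[:, b] += states[:, a] == 1
            pressure[:, a] += states[:, b] == 1
        p_inf = 1.0 - np.exp(-beta * sub * pressure)
        new_inf = (states == 0) & (rng.random((n_reps, n)) < p_inf)
        recov = (states == 1) & (rng.random((n_reps, n)) < p_rec)
        states[new_inf] = 1
        states[recov] = 2
        alive = (states == 1).any(axis=1)
        step_idx += 1
    if alive.any():
        raise RuntimeError("discretized oracle did not reach extinction")
    return (states == 2).sum(axis=1)


def gillespie_network_final_sizes(net, beta_per_day, mu_per_day, n_reps, seed):
    """Final sizes from the package's temporal-Gillespie core (node 0, t=0)."""
    from sirmix._core import _ensemble_net

    ptr, src, dst = net.window_csr()
    seeds = np.zeros(n_reps, dtype=np.int64)
    times = np.zeros(n_reps, dtype=np.float64)
    rseeds = np.random.default_rng(seed).integers(0, 2**31 - 1, n_reps).astype(np.int64)
    _, final = _ensemble_net(
        ptr, src, dst, np.int64(len(ptr) - 1), np.float64(net.resolution),
        net.n_nodes, beta_per_day / 86400.0, mu_per_day / 86400.0,
        seeds, times, rseeds, 600.0, np.int64(2),
    )
    return np.round(final * net.n_nodes).astype(int)


def tv_distance(sizes_a, sizes_b, n_nodes):
    """Total-variation distance between two final-size samples."""
    return 0.5 * sum(
        abs(np.mean(sizes_a == k) - np.mean(sizes_b == k))
        for k in range(1, n_nodes + 1)
    )
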