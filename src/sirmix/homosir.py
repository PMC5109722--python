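"""Frequency-dependent homogeneous-mixing SIR (classic Gillespie).

The population mixes uniformly: each susceptible becomes infectious at rate
``beta * I(t) / N`` and each infectious individual recovers at rate ``mu``;
the reproductive number is ``r0 = beta / mu``.  Rates are per day in the
public API and times are seconds, matching the network simulator so that
prevalence curves from the two frameworks live on the same axes.
"""

from __future__ import annotations

import numpy as np

from ._core import _ensemble_homo, _run_sir_homo
from .netsir import DAY, DEFAULT_GRID_DT, PrevalenceCurve, SirTrajectory, _as_rng

__all__ = ["run_sir_homogeneous", "average_prevalence_h"]


def run_sir_homogeneous(n_nodes: int, beta: float, mu: float, rng) -> SirTrajectory:
    """One exact realization started from (S, I, R) = (N-1, 1, 0)."""
    if n_nodes < 2:
        raise ValueError("population must have at least 2 individuals")
    if beta < 0 or mu <= 0:
        raise ValueError("need beta >= 0 and mu > 0")
    rng = _as_rng(rng)
    rseed = int(rng.integers(0, 2**31 - 1))
    ev_time, ev_rec, n_ev = _run_sir_homo(n_nodes, beta / DAY, mu / DAY, rseed)
    times = np.empty(n_ev + 1)
    ns = np.empty(n_ev + 1, dtype=np.int64)
    ni = np.empty(n_ev + 1, dtype=np.int64)
    nr = np.empty(n_ev + 1, dtype=np.int64)
    times[0], ns[0], ni[0], nr[0] = 0.0, n_nodes - 1, 1, 0
    for k in range(n_ev):
        times[k + 1] = ev_time[k]
        if ev_rec[k] == 1:
            ns[k + 1], ni[k + 1], nr[k + 1] = ns[k], ni[k] - 1, nr[k] + 1
        else:
            ns[k + 1], ni[k + 1], nr[k + 1] = ns[k] - 1, ni[k] + 1, nr[k]
    return SirTrajectory(times=times, n_s=ns, n_i=ni, n_r=nr, seed_node=0, seed_time=0.0)


def average_prevalence_h(
    n_nodes: int,
    r0: float,
    mu: float,
    n_real: int,
    rng,
    grid_dt: float = DEFAULT_GRID_DT,
    t_max: float | None = None,
    grid: np.ndarray | None = None,
) -> PrevalenceCurve:
    """Mean I(t)/N over ``n_real`` homogeneous-mixing realizations.

    ``beta = r0 * mu``.  If ``grid`` (a uniform grid starting at 0, seconds)
    is given, the curve is evaluated exactly on it; otherwise a default
    10-minute grid spanning forty mean infectious periods is used and
    trailing zeros are trimmed.  Extinct runs are included in the average.
    """
    if n_real < 1:
        raise ValueError("n_real must be >= 1")
    if r0 < 0 or mu <= 0:
        raise ValueError("need r0 >= 0 and mu > 0")
    rng = _as_rng(rng)
    beta = r0 * mu
    if grid is not None:
        grid = np.asarray(grid, dtype=np.float64)
        if len(grid) < 2 or grid[0] != 0:
            raise ValueError("grid must start at 0 and have >= 2 points")
        steps = np.diff(grid)
        if not np.allclose(steps, steps[0]):
            raise ValueError("grid must be uniform")
        gdt, n_grid, trim = float(steps[0]), len(grid), False
    else:
        if t_max is None:
            t_max = 40.0 / mu * DAY
        gdt, n_grid, trim = float(grid_dt), max(2, int(np.ceil(t_max / grid_dt)) + 1), True
    rseeds = rng.integers(0, 2**31 - 1, size=n_real).astype(np.int64)
    prev, final_sizes = _ensemble_homo(
        n_nodes, beta / DAY, mu / DAY, rseeds, np.float64(gdt), np.int64(n_grid)
    )
    if trim:
        last = int(np.max(np.nonzero(prev)[0])) + 1 if np.any(prev) else 1
        n_keep = min(n_grid, last + 1)
    else:
        n_keep = n_grid
    return PrevalenceCurve(
        t=np.arange(n_keep) * gdt,
        prevalence=prev[:n_keep],
        n_realizations=n_real,
        final_sizes=final_sizes,
    )
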