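"""Group-structured synthetic temporal contact networks.

The generator is a memory-driven agent-based model of face-to-face contacts in
a population of N agents partitioned into Q non-overlapping social groups.
Agents and links carry memory clocks: ``tau_i`` is the time since agent *i*
last gained or lost a contact, ``tau_(i,j)`` the time since link *(i,j)* last
changed state.  At every update step of length ``dt``:

(i)  each active link *(i,j)* is inactivated with probability
     ``dt * z / (1 + tau_(i,j))``;
(ii) each agent *i* initiates a contact with probability
     ``dt * b / (1 + tau_i)``, choosing the partner *j* among agents not in
     contact with *i* with probability proportional to
     ``a[p,q] / (1 + tau_j) / (1 + tau_(i,j))``,
     where *p*, *q* are the groups of *i*, *j*.

The aging kernels make creation/termination hazards decay with elapsed time,
which produces heavy-tailed (power-law-like) contact and inter-contact
durations and heterogeneous pair contact frequencies, as observed in wearable
sensor data.  The affinity matrix has two values — ``a0`` within a group and
``a1`` across groups — and is calibrated so that agents have a target ratio
(about 50, comparable to a high-school setting) of within-group to cross-group
contacts per available pair.

Elapsed times tau are in seconds and the update step defaults to ``dt = 1`` s,
finer than the 20 s output resolution at which events are emitted; ``dt*z`` and
``dt*b`` must lie in (0, 1] for the step probabilities to be valid at tau = 0.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace

import numpy as np

from .network import GroupStructure, TemporalContactNetwork

__all__ = [
    "ContactModelParams",
    "GeneratorState",
    "step",
    "generate",
    "count_contacts",
    "contact_ratio",
    "calibrate_affinities",
]

DAY = 86400  # seconds


@dataclass(frozen=True)
class ContactModelParams:
    """Parameters of the contact generator.

    Attributes
    ----------
    b : float
        Contact-creation rate, per second: ``dt*b`` is the probability that a
        fully rested agent (tau=0) initiates a contact in one step.
    z : float
        Contact-termination rate, per second: ``dt*z`` is the probability that
        a fresh (tau=0) contact ends in one step.  The survival function of
        a contact decays like ``(1+tau)**-z``; the default z = 1.2 gives
        heavy-tailed durations (infinite-variance regime) with a mean near one
        minute at the 20 s output resolution.
    affinity_in, affinity_out : float
        Within-group (``a0``) and cross-group (``a1``) affinities; only their
        ratio matters for partner choice.
    dt : float
        Update step in seconds (may be fractional), finer than the output
        resolution.
    duration : int
        Total generated (active) time in seconds.
    """

    b: float = 0.3
    z: float = 1.2
    affinity_in: float = 1.0
    affinity_out: float = 1.0 / 50.0
    dt: float = 0.5
    duration: int = 10 * DAY

    def __post_init__(self) -> None:
        if min(self.b, self.z, self.affinity_in, self.affinity_out) <= 0:
            raise ValueError("b, z and affinities must be strictly positive")
        if self.dt <= 0 or self.duration < 0:
            raise ValueError("dt must be positive and duration non-negative")
        if self.dt * self.z > 1 or self.dt * self.b > 1:
            raise ValueError("dt*z and dt*b must not exceed 1 (probability at tau=0)")

    def affinity(self, p: int, q: int) -> float:
        return self.affinity_in if p == q else self.affinity_out


@dataclass
class GeneratorState:
    """Mutable simulation state: active links and memory clocks.

    ``t_node[i]`` / ``t_link[i, j]`` record the last state-change time of the
    agent / link (seconds); elapsed times are ``t - t_node``.  At
    initialization all links are inactive and all clocks are 0.
    """

    active: np.ndarray  # (N, N) bool, symmetric
    t_node: np.ndarray  # (N,) float64
    t_link: np.ndarray  # (N, N) float64
    t: float = 0.0

    @classmethod
    def initial(cls, n: int) -> "GeneratorState":
        return cls(
            active=np.zeros((n, n), dtype=bool),
            t_node=np.zeros(n),
            t_link=np.zeros((n, n)),
        )


def _kernel(tau: np.ndarray) -> np.ndarray:
    return 1.0 / (1.0 + tau)


def step(
    state: GeneratorState,
    params: ContactModelParams,
    groups: GroupStructure,
    rng: np.random.Generator,
    group_idx: np.ndarray | None = None,
) -> GeneratorState:
    """Advance the generator by one step of length ``dt`` (in place).

    Link inactivations (rule i) are applied before contact initiations
    (rule ii); partner weights use the post-inactivation clocks, and mutual
    simultaneous selections collapse to a single activation.
    """
    n = len(state.t_node)
    dt, t = params.dt, state.t
    if group_idx is None:
        group_idx = np.zeros(n, dtype=np.int32)

    # rule (i): terminate active links
    ai, aj = np.nonzero(np.triu(state.active, k=1))
    if len(ai):
        p_off = dt * params.z * _kernel(t - state.t_link[ai, aj])
        off = rng.random(len(ai)) < p_off
        for a, b in zip(ai[off], aj[off]):
            state.active[a, b] = state.active[b, a] = False
            state.t_link[a, b] = state.t_link[b, a] = t
            state.t_node[a] = state.t_node[b] = t

    # rule (ii): initiate contacts (post-inactivation clock snapshot)
    tau_node = t - state.t_node
    p_on = dt * params.b * _kernel(tau_node)
    initiators = np.flatnonzero(rng.random(n) < p_on)
    if len(initiators):
        node_kern = _kernel(tau_node)
        aff = np.where(
            group_idx[:, None] == group_idx[None, :], params.affinity_in, params.affinity_out
        )
        for i in initiators:
            w = aff[i] * node_kern * _kernel(t - state.t_link[i])
            w[i] = 0.0
            w[state.active[i]] = 0.0  # partners drawn among non-contacts of i
            total = w.sum()
            if total <= 0:
                continue
            j = rng.choice(n, p=w / total)
            if not state.active[i, j]:  # mutual selection is idempotent
                state.active[i, j] = state.active[j, i] = True
                state.t_link[i, j] = state.t_link[j, i] = t
                state.t_node[i] = state.t_node[j] = t

    state.t = t + dt
    return state


def generate(
    params: ContactModelParams,
    groups: GroupStructure,
    seed: int,
    resolution: int = 20,
) -> TemporalContactNetwork:
    """Generate a temporal contact network; deterministic given ``seed``.

    The generator clock advances in steps of ``params.dt`` seconds; events are
    emitted at the coarser output ``resolution``: a pair produces one event for
    every resolution window during which its link was active at some step.
    """
    if 0 < params.duration < resolution:
        raise ValueError("duration shorter than one resolution window")
    if abs(resolution / params.dt - round(resolution / params.dt)) > 1e-9:
        raise ValueError("resolution must be a multiple of the generator step dt")
    from ._core import _generate_contacts

    n = groups.n_nodes
    node_ids = sorted(groups.membership, key=lambda k: (groups.membership[k], k))
    group_idx = np.array([groups.membership[k] for k in node_ids], dtype=np.int64)
    rseed = int(np.random.default_rng(seed).integers(0, 2**31 - 1))
    times, src, dst = _generate_contacts(
        n, group_idx, params.affinity_in, params.affinity_out,
        params.b, params.z, np.float64(params.dt), np.float64(params.duration),
        np.float64(resolution), rseed,
    )
    return TemporalContactNetwork(
        node_ids=node_ids,
        times=times,
        src=src,
        dst=dst,
        resolution=resolution,
        groups=groups,
        active_periods=[(0, max(params.duration, resolution))],
    )


def count_contacts(net: TemporalContactNetwork) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
    """Contact episodes: maximal runs of consecutive windows per node pair.

    Returns ``(src, dst, counts)``: the number of distinct contacts for every
    pair with at least one event.
    """
    if net.n_events == 0:
        return (np.zeros(0, np.int32), np.zeros(0, np.int32), np.zeros(0, np.int64))
    order = np.lexsort((net.times, net.dst, net.src))
    t, s, d = net.times[order], net.src[order], net.dst[order]
    new_pair = np.empty(len(t), dtype=bool)
    new_pair[0] = True
    new_pair[1:] = (s[1:] != s[:-1]) | (d[1:] != d[:-1])
    starts = new_pair | np.concatenate(([True], np.diff(t) > net.resolution))
    pair_first = np.flatnonzero(new_pair)
    counts = np.add.reduceat(starts.astype(np.int64), pair_first)
    return s[pair_first], d[pair_first], counts


def contact_ratio(net: TemporalContactNetwork, groups: GroupStructure | None = None) -> float:
    """Within/cross-group contacts per available pair.

    Returns ``(W / S) / (C / X)`` where W (C) is the number of within-group
    (cross-group) contact episodes and S (X) the number of same-group
    (cross-group) unordered node pairs.  A contact episode is a maximal run of
    consecutive event windows of a pair — one created contact, however long it
    lasts.  ``math.inf`` signals a network with within-group contacts but no
    cross-group ones.
    """
    groups = groups or net.groups
    if groups is None:
        raise ValueError("network has no group labels")
    if net.n_events == 0:
        raise ValueError("contact ratio undefined on an empty network")
    gi = np.array([groups.membership[n] for n in net.node_ids], dtype=np.int32)
    ps, pd_, counts = count_contacts(net)
    within_mask = gi[ps] == gi[pd_]
    w_events = int(counts[within_mask].sum())
    c_events = int(counts[~within_mask].sum())
    sizes = np.asarray(groups.group_sizes)
    s_pairs = int((sizes * (sizes - 1) // 2).sum())
    n_total = sizes.sum()
    x_pairs = int(n_total * (n_total - 1) // 2 - s_pairs)
    if x_pairs == 0:
        raise ValueError("single-group network has no cross-group pairs")
    if c_events == 0:
        return math.inf
    return (w_events / s_pairs) / (c_events / x_pairs)


def calibrate_affinities(
    params: ContactModelParams,
    groups: GroupStructure,
    target_ratio: float,
    seed: int,
    rel_tol: float = 0.15,
    max_iter: int = 12,
    pilot_duration: int | None = None,
    n_pilots: int = 3,
) -> tuple[float, float]:
    """Find ``(a0, a1)`` giving a target within/cross contact ratio.

    The search is on ``a0/a1`` at fixed ``a0 = 1``.  Each evaluation averages
    the measured ratio over ``n_pilots`` generations of ``pilot_duration``
    seconds (default: the duration in ``params``, so the calibrated quantity
    is measured under production conditions), pooling episode counts across
    pilots and reusing the same pilot seeds at every evaluation (common random
    numbers) so the ratio is a deterministic, near-monotone function of
    ``a0/a1``.  A multiplicative secant update with
    a log-space bisection fallback converges in a handful of pilots; once a
    bracket has collapsed below evaluation resolution the crossing point (its
    log-midpoint) is returned, since the residual mismatch there is pilot
    noise.  Raises ``RuntimeError`` if the target is never bracketed within
    the iteration budget.
    """
    if target_ratio < 1:
        raise ValueError("target_ratio must be >= 1")
    if pilot_duration is None:
        pilot_duration = params.duration

    gi_by_node = groups.membership
    sizes = np.asarray(groups.group_sizes)
    s_pairs = int((sizes * (sizes - 1) // 2).sum())
    x_pairs = int(sizes.sum() * (sizes.sum() - 1) // 2 - s_pairs)

    def measure(a1: float) -> float:
        # pool episode counts over pilots: cross-group episodes are rare and a
        # per-pilot ratio would be dominated by their sampling noise
        p = replace(params, affinity_in=1.0, affinity_out=a1, duration=pilot_duration)
        w_tot = c_tot = 0
        for k in range(n_pilots):
            net = generate(p, groups, seed=seed + k)
            if net.n_events == 0:
                continue
            gi = np.array([gi_by_node[n] for n in net.node_ids], dtype=np.int32)
            ps, pd_, counts = count_contacts(net)
            within = gi[ps] == gi[pd_]
            w_tot += int(counts[within].sum())
            c_tot += int(counts[~within].sum())
        if c_tot == 0:
            return math.inf
        return (w_tot / s_pairs) / (c_tot / x_pairs)

    a1 = 1.0 / target_ratio
    lo_a1 = hi_a1 = None  # lo_a1: ratio too high; hi_a1: ratio too low
    for k in range(max_iter):
        r = measure(a1)
        if math.isfinite(r) and abs(math.log(r / target_ratio)) <= math.log1p(rel_tol):
            return 1.0, a1
        if not math.isfinite(r) or r > target_ratio:
            lo_a1 = a1
        else:
            hi_a1 = a1
        if lo_a1 is not None and hi_a1 is not None:
            if hi_a1 / lo_a1 < 1.05:  # bracket exhausted; target crossed inside
                return 1.0, math.sqrt(lo_a1 * hi_a1)
            a1 = math.sqrt(lo_a1 * hi_a1)  # bisect in log space
        elif math.isfinite(r):
            a1 = a1 * r / target_ratio
        else:
            a1 = a1 * 10.0
    if lo_a1 is not None and hi_a1 is not None:
        return 1.0, math.sqrt(lo_a1 * hi_a1)
    raise RuntimeError(
        f"affinity calibration failed to bracket ratio {target_ratio} within "
        f"{max_iter} pilots (last a1={a1:.4g}, bracket=({lo_a1}, {hi_a1}))"
    )
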