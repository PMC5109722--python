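"""Temporal contact networks: data model, SocioPatterns-style I/O, preprocessing.

A temporal contact network records face-to-face proximity events at a fixed
temporal resolution (20 s by convention for wearable-sensor data): an event
``(t, i, j)`` means nodes *i* and *j* were in contact during the half-open
window ``[t, t + resolution)``.  Networks may carry a group structure (classes,
departments) and a set of *active periods* — the intervals during which the
sensors were actually deployed; nights and weekends fall outside them.
"""

from __future__ import annotations

import warnings
from dataclasses import dataclass, field
from typing import Iterator, Sequence

import numpy as np

__all__ = [
    "GroupStructure",
    "TemporalContactNetwork",
    "read_events",
    "write_events",
    "subset_groups",
    "subset_random_fraction",
    "compress_active_time",
    "extend_periodically",
]


@dataclass(frozen=True)
class GroupStructure:
    """Partition of the population into non-overlapping groups.

    Parameters
    ----------
    group_sizes
        Number of agents in each group ``n_q``; ``sum(n_q) = N``.
    membership
        Mapping node-id -> group index in ``range(len(group_sizes))``.
    """

    group_sizes: tuple[int, ...]
    membership: dict[str, int] = field(compare=False)

    def __post_init__(self) -> None:
        if any(n <= 0 for n in self.group_sizes):
            raise ValueError("group sizes must be positive")
        if len(self.membership) != sum(self.group_sizes):
            raise ValueError("membership size does not match sum of group sizes")
        counts = np.bincount(
            [self.membership[n] for n in self.membership], minlength=len(self.group_sizes)
        )
        if tuple(counts) != tuple(self.group_sizes):
            raise ValueError("membership counts disagree with group_sizes")

    @property
    def n_groups(self) -> int:
        return len(self.group_sizes)

    @property
    def n_nodes(self) -> int:
        return sum(self.group_sizes)

    @classmethod
    def equal_groups(cls, n_groups: int, group_size: int, prefix: str = "n") -> "GroupStructure":
        """Build Q equal groups of a given size with generated node ids."""
        membership = {
            f"{prefix}{q * group_size + k}": q
            for q in range(n_groups)
            for k in range(group_size)
        }
        return cls(group_sizes=(group_size,) * n_groups, membership=membership)


@dataclass
class TemporalContactNetwork:
    """Time-ordered undirected contact events at a fixed resolution.

    ``times[k]`` is the window start (integer seconds, multiple of
    ``resolution``) of the k-th event between ``node_ids[src[k]]`` and
    ``node_ids[dst[k]]``.  Events are stored sorted by time; pairs are stored
    with ``src < dst`` (unordered pair convention).
    """

    node_ids: list[str]
    times: np.ndarray
    src: np.ndarray
    dst: np.ndarray
    resolution: int = 20
    groups: GroupStructure | None = None
    active_periods: list[tuple[int, int]] | None = None

    def __post_init__(self) -> None:
        self.times = np.asarray(self.times, dtype=np.int64)
        self.src = np.asarray(self.src, dtype=np.int32)
        self.dst = np.asarray(self.dst, dtype=np.int32)
        if not (len(self.times) == len(self.src) == len(self.dst)):
            raise ValueError("event arrays must have equal length")
        if np.any(self.src == self.dst):
            raise ValueError("self-contacts are not allowed")
        # canonical order: unordered pair, time-sorted
        lo = np.minimum(self.src, self.dst)
        hi = np.maximum(self.src, self.dst)
        order = np.lexsort((hi, lo, self.times))
        self.times, self.src, self.dst = self.times[order], lo[order], hi[order]
        if self.active_periods is None:
            end = int(self.times.max()) + self.resolution if len(self.times) else self.resolution
            self.active_periods = [(0, end)]
        if len(self.times) and self.times.min() < 0:
            raise ValueError("negative event timestamps")

    # -- basic properties -------------------------------------------------
    @property
    def n_nodes(self) -> int:
        return len(self.node_ids)

    @property
    def n_events(self) -> int:
        return len(self.times)

    @property
    def duration(self) -> int:
        """Total active time in seconds (sum of active-period lengths)."""
        return sum(e - s for s, e in self.active_periods)

    @property
    def is_compressed(self) -> bool:
        """True if the timeline is a single active period starting at 0."""
        return len(self.active_periods) == 1 and self.active_periods[0][0] == 0

    def group_index(self) -> np.ndarray | None:
        """Group index per node position, or None if ungrouped."""
        if self.groups is None:
            return None
        return np.array([self.groups.membership[n] for n in self.node_ids], dtype=np.int32)

    def window_csr(self) -> tuple[np.ndarray, np.ndarray, np.ndarray]:
        """CSR layout of events by window index for the simulators.

        Returns ``(window_ptr, src, dst)`` where events of window ``w`` are
        ``slice(window_ptr[w], window_ptr[w+1])``.  Requires a compressed
        timeline.
        """
        if not self.is_compressed:
            raise ValueError("network must be compressed (single active period from 0)")
        n_windows = max(1, self.duration // self.resolution)
        w = self.times // self.resolution
        if len(w) and w.max() >= n_windows:
            raise ValueError("event outside the declared active period")
        ptr = np.zeros(n_windows + 1, dtype=np.int64)
        np.add.at(ptr, w + 1, 1)
        np.cumsum(ptr, out=ptr)
        return ptr, self.src, self.dst


# ---------------------------------------------------------------------------
# I/O: SocioPatterns "t i j" dialect
# ---------------------------------------------------------------------------

def read_events(
    path,
    resolution: int = 20,
    metadata_path=None,
    active_periods: Sequence[tuple[int, int]] | None = None,
) -> TemporalContactNetwork:
    """Read a whitespace/TAB-separated ``t i j`` event file.

    Duplicate ``(t, i, j)`` rows are collapsed; rows with ``i == j`` are
    rejected with a warning.  An optional metadata file of ``id group`` rows
    supplies group labels; its node ids are unioned into the node set.
    """
    rows: set[tuple[int, str, str]] = set()
    n_self = 0
    with open(path) as fh:
        for lineno, line in enumerate(fh, start=1):
            parts = line.split()
            if not parts or parts[0].startswith("#"):
                continue
            if len(parts) < 3:
                raise ValueError(f"{path}:{lineno}: expected 't i j', got {line!r}")
            try:
                t = int(parts[0])
            except ValueError as exc:
                raise ValueError(f"{path}:{lineno}: bad timestamp {parts[0]!r}") from exc
            i, j = parts[1], parts[2]
            if i == j:
                n_self += 1
                continue
            rows.add((t, *sorted((i, j))))
    if n_self:
        warnings.warn(f"rejected {n_self} self-contact rows", stacklevel=2)

    groups = None
    meta_nodes: list[str] = []
    if metadata_path is not None:
        labels: dict[str, str] = {}
        with open(metadata_path) as fh:
            for line in fh:
                parts = line.split()
                if not parts or parts[0].startswith("#"):
                    continue
                labels[parts[0]] = parts[1]
        meta_nodes = list(labels)
        uniq = sorted(set(labels.values()))
        membership = {n: uniq.index(g) for n, g in labels.items()}
        sizes = tuple(
            int(np.sum([membership[n] == q for n in membership])) for q in range(len(uniq))
        )
        groups = GroupStructure(group_sizes=sizes, membership=membership)

    node_set = sorted({i for _, i, _ in rows} | {j for _, _, j in rows} | set(meta_nodes))
    index = {n: k for k, n in enumerate(node_set)}
    rows_sorted = sorted(rows)
    times = np.array([r[0] for r in rows_sorted], dtype=np.int64)
    src = np.array([index[r[1]] for r in rows_sorted], dtype=np.int32)
    dst = np.array([index[r[2]] for r in rows_sorted], dtype=np.int32)
    return TemporalContactNetwork(
        node_ids=node_set,
        times=times,
        src=src,
        dst=dst,
        resolution=resolution,
        groups=groups,
        active_periods=list(active_periods) if active_periods else None,
    )


def write_events(net: TemporalContactNetwork, path, metadata_path=None) -> None:
    """Write a network back to the ``t i j`` dialect (and ``id group`` metadata)."""
    with open(path, "w") as fh:
        for t, a, b in zip(net.times, net.src, net.dst):
            fh.write(f"{t}\t{net.node_ids[a]}\t{net.node_ids[b]}\n")
    if metadata_path is not None and net.groups is not None:
        with open(metadata_path, "w") as fh:
            for n in net.node_ids:
                fh.write(f"{n}\t{net.groups.membership[n]}\n")


# ---------------------------------------------------------------------------
# Preprocessing: subsetting, timeline compression, periodic extension
# ---------------------------------------------------------------------------

def _induced(net: TemporalContactNetwork, keep_positions: np.ndarray) -> TemporalContactNetwork:
    """Restrict to a node subset; keep events with both endpoints inside."""
    keep_positions = np.asarray(sorted(keep_positions), dtype=np.int64)
    remap = -np.ones(net.n_nodes, dtype=np.int64)
    remap[keep_positions] = np.arange(len(keep_positions))
    mask = (remap[net.src] >= 0) & (remap[net.dst] >= 0)
    node_ids = [net.node_ids[k] for k in keep_positions]
    groups = None
    if net.groups is not None:
        membership = {n: net.groups.membership[n] for n in node_ids}
        present = sorted(set(membership.values()))
        reindex = {g: k for k, g in enumerate(present)}
        membership = {n: reindex[g] for n, g in membership.items()}
        sizes = tuple(
            int(sum(1 for g in membership.values() if g == q)) for q in range(len(present))
        )
        groups = GroupStructure(group_sizes=sizes, membership=membership)
    return TemporalContactNetwork(
        node_ids=node_ids,
        times=net.times[mask],
        src=remap[net.src[mask]].astype(np.int32),
        dst=remap[net.dst[mask]].astype(np.int32),
        resolution=net.resolution,
        groups=groups,
        active_periods=list(net.active_periods),
    )


def subset_groups(net: TemporalContactNetwork, keep_groups: Sequence[int]) -> TemporalContactNetwork:
    """Keep only nodes of the given groups and the contacts among them."""
    if net.groups is None:
        raise ValueError("network has no group labels")
    keep = set(keep_groups)
    unknown = keep - set(range(net.groups.n_groups))
    if unknown:
        raise ValueError(f"unknown group labels: {sorted(unknown)}")
    gi = net.group_index()
    return _induced(net, np.flatnonzero(np.isin(gi, list(keep))))


def subset_random_fraction(
    net: TemporalContactNetwork, fraction: float, seed: int
) -> TemporalContactNetwork:
    """Keep ``round(fraction * N)`` uniformly chosen nodes (without replacement)."""
    if not 0 < fraction <= 1:
        raise ValueError("fraction must be in (0, 1]")
    rng = np.random.default_rng(seed)
    n_keep = int(round(fraction * net.n_nodes))
    keep = rng.choice(net.n_nodes, size=n_keep, replace=False)
    return _induced(net, keep)


def compress_active_time(net: TemporalContactNetwork) -> TemporalContactNetwork:
    """Concatenate active periods so inactive time (nights, weekends) vanishes.

    Each active period is shifted left so periods abut, starting at 0; event
    timestamps are re-timed accordingly.  The result has a single active
    period ``[0, total_active_duration)``.
    """
    periods = sorted(net.active_periods)
    for (s0, e0), (s1, e1) in zip(periods, periods[1:]):
        if s1 < e0:
            raise ValueError("overlapping active periods")
    new_times = np.array(net.times, dtype=np.int64)
    offset = 0
    for s, e in periods:
        inside = (net.times >= s) & (net.times < e)
        new_times[inside] = net.times[inside] - s + offset
        offset += e - s
    outside = np.ones(len(net.times), dtype=bool)
    for s, e in periods:
        outside &= ~((net.times >= s) & (net.times < e))
    if outside.any():
        raise ValueError(f"{int(outside.sum())} events outside declared active periods")
    return TemporalContactNetwork(
        node_ids=list(net.node_ids),
        times=new_times,
        src=net.src.copy(),
        dst=net.dst.copy(),
        resolution=net.resolution,
        groups=net.groups,
        active_periods=[(0, offset)],
    )


def extend_periodically(
    net: TemporalContactNetwork, t_end: int
) -> Iterator[tuple[int, int, int]]:
    """Yield ``(t, src, dst)`` with the dataset repeated until ``t_end``.

    The network must be compressed; copy *k* of an event at *t* appears at
    ``t + k * duration`` for all ``k`` with the shifted time below ``t_end``.
    """
    if not net.is_compressed:
        raise ValueError("extend_periodically requires a compressed network")
    period = net.duration
    if period <= 0:
        raise ValueError("zero-duration network cannot be extended")
    k = 0
    while k * period < t_end:
        base = k * period
        for t, a, b in zip(net.times, net.src, net.dst):
            shifted = int(t) + base
            if shifted >= t_end:
                return
            yield shifted, int(a), int(b)
        k += 1
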