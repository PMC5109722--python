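import numpy as np
import pytest

from sirmix.network import GroupStructure, TemporalContactNetwork

DAY = 86400


@pytest.fixture
def toy_event_file(tmp_path):
    """3 events, 4 nodes, one duplicated row and one self-contact row."""
    p = tmp_path / "events.tsv"
    p.write_text("0 a b\n20 b c\n40 c d\n20 b c\n60 d d\n")
    return p


@pytest.fixture
def two_group_toy():
    """Hand-built 4-node, 2-group network: 2 within-group and 1 cross event."""
    groups = GroupStructure(
        group_sizes=(2, 2), membership={"a": 0, "b": 0, "c": 1, "d": 1}
    )
    return TemporalContactNetwork(
        node_ids=["a", "b", "c", "d"],
        times=np.array([0, 100, 200]),
        src=np.array([0, 2, 0]),
        dst=np.array([1, 3, 2]),
        groups=groups,
    )


def permanent_pair_net(n_nodes: int, pairs, n_windows: int = 4320, resolution: int = 20):
    """Network where the given pairs are in contact during every window."""
    times, src, dst = [], [], []
    for w in range(n_windows):
        for a, b in pairs:
            times.append(w * resolution)
            src.append(a)
            dst.append(b)
    return TemporalContactNetwork(
        node_ids=[f"n{k}" for k in range(n_nodes)],
        times=np.array(times),
        src=np.array(src),
        dst=np.array(dst),
        resolution=resolution,
        active_periods=[(0, n_windows * resolution)],
    )


@pytest.fixture
def two_node_always(scope="session"):
    """Two nodes permanently in contact for one day."""
    return permanent_pair_net(2, [(0, 1)])


@pytest.fixture
def toy_window_net():
    """5-node, 50-window network with a deterministic pseudo-random edge set."""
    rng = np.random.default_rng(2024)
    times, src, dst = [], [], []
    for w in range(50):
        for a in range(5):
            for b in range(a + 1, 5):
                if rng.random() < 0.25:
                    times.append(w * 20)
                    src.append(a)
                    dst.append(b)
    return TemporalContactNetwork(
        node_ids=[f"n{k}" for k in range(5)],
        times=np.array(times),
        src=np.array(src),
        dst=np.array(dst),
        active_periods=[(0, 1000)],
    )
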