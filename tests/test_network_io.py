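"""Event-file I/O, subsetting, timeline compression, periodic extension."""

import numpy as np
import pytest

from sirmix.network import (
    GroupStructure,
    TemporalContactNetwork,
    compress_active_time,
    extend_periodically,
    read_events,
    subset_groups,
    subset_random_fraction,
    write_events,
)


class TestReadEvents:
    def test_toy_file_parsed_with_duplicates_collapsed(self, toy_event_file):
        with pytest.warns(UserWarning, match="self-contact"):
            net = read_events(toy_event_file)
        assert net.n_events == 3  # duplicate (20, b, c) collapses; (60, d, d) dropped
        assert net.node_ids == ["a", "b", "c", "d"]

    def test_malformed_row_reports_line_number(self, tmp_path):
        p = tmp_path / "bad.tsv"
        p.write_text("0 a b\nxx a c\n")
        with pytest.raises(ValueError, match=":2:"):
            read_events(p)

    def test_metadata_extends_node_set_and_sets_groups(self, tmp_path):
        ev = tmp_path / "e.tsv"
        ev.write_text("0 a b\n")
        meta = tmp_path / "m.tsv"
        meta.write_text("a g1\nb g1\nz g2\n")
        net = read_events(ev, metadata_path=meta)
        assert net.node_ids == ["a", "b", "z"]
        assert net.groups.group_sizes == (2, 1)

    def test_roundtrip_identity(self, two_group_toy, tmp_path):
        ev, meta = tmp_path / "e.tsv", tmp_path / "m.tsv"
        write_events(two_group_toy, ev, metadata_path=meta)
        back = read_events(ev, metadata_path=meta)
        assert back.node_ids == two_group_toy.node_ids
        assert np.array_equal(back.times, two_group_toy.times)
        assert np.array_equal(back.src, two_group_toy.src)
        assert np.array_equal(back.dst, two_group_toy.dst)
        assert back.groups.membership == two_group_toy.groups.membership


class TestSubsetting:
    def test_keep_all_groups_is_identity(self, two_group_toy):
        sub = subset_groups(two_group_toy, [0, 1])
        assert sub.node_ids == two_group_toy.node_ids
        assert np.array_equal(sub.times, two_group_toy.times)

    def test_keep_one_group_keeps_only_internal_events(self, two_group_toy):
        sub = subset_groups(two_group_toy, [0])
        assert sub.node_ids == ["a", "b"]
        assert sub.n_events == 1  # only the (0, a, b) event survives
        assert sub.times[0] == 0

    def test_unknown_group_raises(self, two_group_toy):
        with pytest.raises(ValueError, match="unknown group"):
            subset_groups(two_group_toy, [5])

    def test_subsetting_idempotent(self, two_group_toy):
        once = subset_groups(two_group_toy, [0])
        twice = subset_groups(once, [0])
        assert twice.node_ids == once.node_ids
        assert np.array_equal(twice.times, once.times)

    def test_random_fraction_node_count_and_determinism(self, two_group_toy):
        sub = subset_random_fraction(two_group_toy, 0.5, seed=3)
        assert sub.n_nodes == 2
        again = subset_random_fraction(two_group_toy, 0.5, seed=3)
        assert again.node_ids == sub.node_ids

    def test_fraction_one_is_identity_on_nodes(self, two_group_toy):
        assert subset_random_fraction(two_group_toy, 1.0, 0).node_ids == two_group_toy.node_ids

    def test_fraction_out_of_range(self, two_group_toy):
        with pytest.raises(ValueError):
            subset_random_fraction(two_group_toy, 1.5, 0)

    @pytest.mark.parametrize("seed", range(5))
    def test_induced_events_never_mention_excluded_nodes(self, seed):
        rng = np.random.default_rng(seed)
        n = 12
        times = np.arange(0, 40 * 20, 20)
        src = rng.integers(0, n - 1, len(times))
        dst = src + 1 + rng.integers(0, n - 1 - src)
        net = TemporalContactNetwork(
            node_ids=[f"n{k}" for k in range(n)], times=times, src=src, dst=dst
        )
        sub = subset_random_fraction(net, 0.5, seed=seed)
        kept = set(sub.node_ids)
        assert kept <= set(net.node_ids)
        for a, b in zip(sub.src, sub.dst):
            assert sub.node_ids[a] in kept and sub.node_ids[b] in kept


class TestCompressAndExtend:
    def _net_two_periods(self):
        return TemporalContactNetwork(
            node_ids=["a", "b"],
            times=np.array([100, 39620]),
            src=np.array([0, 0]),
            dst=np.array([1, 1]),
            active_periods=[(0, 3600), (39600, 43200)],
        )

    def test_single_period_identity(self, two_group_toy):
        out = compress_active_time(two_group_toy)
        assert np.array_equal(out.times, two_group_toy.times)
        assert out.duration == two_group_toy.duration

    def test_two_periods_concatenated(self):
        out = compress_active_time(self._net_two_periods())
        assert out.duration == 7200
        # second-period event shifted left by the 36000 s gap
        assert list(out.times) == [100, 3620]

    def test_event_order_preserved(self):
        out = compress_active_time(self._net_two_periods())
        assert np.all(np.diff(out.times) >= 0)

    def test_overlapping_periods_rejected(self):
        net = TemporalContactNetwork(
            node_ids=["a", "b"], times=np.array([0]), src=np.array([0]),
            dst=np.array([1]), active_periods=[(0, 100), (50, 200)],
        )
        with pytest.raises(ValueError, match="overlap"):
            compress_active_time(net)

    def test_extension_copies_at_period_multiples(self):
        net = TemporalContactNetwork(
            node_ids=["a", "b"], times=np.array([10]), src=np.array([0]),
            dst=np.array([1]), resolution=10, active_periods=[(0, 100)],
        )
        out = list(extend_periodically(net, 350))
        assert [t for t, _, _ in out] == [10, 110, 210, 310]

    def test_extension_within_one_period_is_original(self, two_group_toy):
        net = compress_active_time(two_group_toy)
        out = list(extend_periodically(net, net.duration))
        assert [t for t, _, _ in out] == list(net.times)

    def test_extension_preserves_per_period_counts(self, two_group_toy):
        net = compress_active_time(two_group_toy)
        out = list(extend_periodically(net, 2 * net.duration))
        assert len(out) == 2 * net.n_events


class TestInvariants:
    def test_self_contacts_rejected_in_constructor(self):
        with pytest.raises(ValueError, match="self-contact"):
            TemporalContactNetwork(
                node_ids=["a", "b"], times=np.array([0]),
                src=np.array([0]), dst=np.array([0]),
            )

    def test_group_structure_validates_sizes(self):
        with pytest.raises(ValueError):
            GroupStructure(group_sizes=(2, 2), membership={"a": 0, "b": 0, "c": 1})

    def test_window_csr_layout(self, two_group_toy):
        net = compress_active_time(two_group_toy)
        ptr, src, dst = net.window_csr()
        assert len(ptr) == net.duration // net.resolution + 1
        assert ptr[-1] == net.n_events
        w = net.times // net.resolution
        for k in range(net.n_events):
            assert ptr[w[k]] <= k < ptr[w[k] + 1]


class TestPropertyBased:
    """Randomised invariants over arbitrary small event sets."""

    from hypothesis import given, settings
    from hypothesis import strategies as st

    # windows constrained to the two declared active periods:
    # [0, 600) -> windows 0..29, [2000, 2600) -> windows 100..129
    events = st.lists(
        st.tuples(
            st.one_of(
                st.integers(min_value=0, max_value=29),
                st.integers(min_value=100, max_value=129),
            ),
            st.integers(min_value=0, max_value=7),    # node a
            st.integers(min_value=0, max_value=7),    # node b
        ).filter(lambda e: e[1] != e[2]),
        min_size=1, max_size=60,
    )

    @staticmethod
    def _build(raw):
        rows = sorted({(w * 20, *sorted((a, b))) for w, a, b in raw})
        groups = GroupStructure(
            group_sizes=(4, 4), membership={f"n{k}": k // 4 for k in range(8)}
        )
        return TemporalContactNetwork(
            node_ids=[f"n{k}" for k in range(8)],
            times=np.array([r[0] for r in rows]),
            src=np.array([r[1] for r in rows]),
            dst=np.array([r[2] for r in rows]),
            groups=groups,
            active_periods=[(0, 600), (2000, 2600)],
        )

    @given(events)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_roundtrip_preserves_events(self, tmp_path_factory, raw):
        net = self._build(raw)
        d = tmp_path_factory.mktemp("rt")
        write_events(net, d / "e.tsv", metadata_path=d / "m.tsv")
        back = read_events(d / "e.tsv", metadata_path=d / "m.tsv")
        assert np.array_equal(back.times, net.times)
        assert np.array_equal(back.src, net.src)
        assert np.array_equal(back.dst, net.dst)

    @given(events)
    @settings(max_examples=40, deadline=None, derandomize=True)
    def test_subset_commutes_with_compression(self, raw):
        net = self._build(raw)
        a = compress_active_time(subset_groups(net, [0]))
        b = subset_groups(compress_active_time(net), [0])
        assert a.node_ids == b.node_ids
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.src, b.src) and np.array_equal(a.dst, b.dst)
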