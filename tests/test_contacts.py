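"""Synthetic contact generator: update rules, heavy tails, group mixing."""

import collections
import math

import numpy as np
import pytest

from sirmix.contacts import (
    ContactModelParams,
    GeneratorState,
    calibrate_affinities,
    contact_ratio,
    count_contacts,
    generate,
    step,
)
from sirmix.network import GroupStructure

DAY = 86400


def episode_stats(net):
    """Contact durations and inter-contact gaps (seconds) per pair."""
    pair_t = collections.defaultdict(list)
    for t, i, j in zip(net.times, net.src, net.dst):
        pair_t[(i, j)].append(t)
    durs, gaps = [], []
    for ts in pair_t.values():
        ts = np.sort(ts)
        brk = np.nonzero(np.diff(ts) > net.resolution)[0]
        segs = np.split(ts, brk + 1)
        durs += [len(s) * net.resolution for s in segs]
        gaps += [segs[k + 1][0] - segs[k][-1] for k in range(len(segs) - 1)]
    return np.array(durs, float), np.array(gaps, float)


class TestParams:
    def test_invalid_probability_at_tau_zero_rejected(self):
        with pytest.raises(ValueError, match="exceed 1"):
            ContactModelParams(z=0.06, dt=20)

    def test_nonpositive_rates_rejected(self):
        with pytest.raises(ValueError):
            ContactModelParams(b=0.0)


class TestStepRules:
    def test_fresh_link_inactivation_probability(self):
        # tau=0, z=0.1/s, dt=1 s -> inactivation probability 0.10
        params = ContactModelParams(b=1e-9, z=0.1, dt=1, duration=10)
        groups = GroupStructure.equal_groups(1, 2)
        n_trials, deaths = 4000, 0
        rng = np.random.default_rng(0)
        for _ in range(n_trials):
            st = GeneratorState.initial(2)
            st.active[0, 1] = st.active[1, 0] = True  # link formed at t=0
            step(st, params, groups, rng)
            deaths += not st.active[0, 1]
        p_hat = deaths / n_trials
        assert abs(p_hat - 0.10) < 4 * math.sqrt(0.1 * 0.9 / n_trials)

    def test_negligible_z_means_no_inactivation(self):
        params = ContactModelParams(b=0.5, z=1e-12, dt=1, duration=100)
        groups = GroupStructure.equal_groups(1, 5)
        st = GeneratorState.initial(5)
        rng = np.random.default_rng(1)
        counts = []
        for _ in range(100):
            step(st, params, groups, rng)
            counts.append(int(st.active.sum()))
        assert all(b >= a for a, b in zip(counts, counts[1:]))

    def test_certain_death_resets_link_and_node_clocks(self):
        # dt*z = 1 and tau = 0 -> inactivation probability exactly 1
        params = ContactModelParams(b=1e-9, z=1.0, dt=1, duration=10)
        groups = GroupStructure.equal_groups(1, 2)
        st = GeneratorState.initial(2)
        st.active[0, 1] = st.active[1, 0] = True
        step(st, params, groups, np.random.default_rng(2))
        assert not st.active[0, 1]
        assert st.t_link[0, 1] == 0.0 and st.t_node[0] == 0.0  # reset at t=0
        st2 = GeneratorState.initial(2)
        st2.active[0, 1] = st2.active[1, 0] = True
        step(st2, params, groups, np.random.default_rng(3))
        # one step later the elapsed time is exactly dt
        assert st2.t - st2.t_link[0, 1] == params.dt


class TestGenerate:
    def test_zero_duration_gives_empty_network_with_all_nodes(self):
        groups = GroupStructure.equal_groups(2, 3)
        net = generate(ContactModelParams(duration=0), groups, seed=0)
        assert net.n_events == 0 and net.n_nodes == 6

    def test_determinism_and_seed_sensitivity(self):
        groups = GroupStructure.equal_groups(2, 5)
        params = ContactModelParams(duration=7200)
        a = generate(params, groups, seed=9)
        b = generate(params, groups, seed=9)
        c = generate(params, groups, seed=10)
        assert np.array_equal(a.times, b.times)
        assert np.array_equal(a.src, b.src) and np.array_equal(a.dst, b.dst)
        assert not (
            len(a.times) == len(c.times)
            and np.array_equal(a.times, c.times)
            and np.array_equal(a.src, c.src)
        )

    def test_heavy_tailed_durations_and_gaps(self):
        groups = GroupStructure.equal_groups(3, 20)
        net = generate(ContactModelParams(duration=DAY), groups, seed=3)
        durs, gaps = episode_stats(net)
        assert len(durs) > 100
        assert durs.std() / durs.mean() > 1
        assert gaps.std() / gaps.mean() > 1

    def test_two_agent_window_activity_matches_exact_chain(self):
        """Exhaustive finite-horizon chain oracle for the 2-agent system.

        With two agents the node and link clocks coincide, so the exact state
        is (active?, age).  Propagating that chain gives the expected fraction
        of windows with an active link, which the simulated generator must
        reproduce within Monte-Carlo error.
        """
        b, z, T = 0.4, 0.8, 200

        # exact forward propagation over states (s, age), age <= t
        p_act = np.zeros(T + 2)
        p_ina = np.zeros(T + 2)
        p_ina[0] = 1.0
        expected = 0.0
        reform = 1.0 - (1.0 - b) ** 2  # both agents rested after a death
        for _ in range(T):
            new_act = np.zeros_like(p_act)
            new_ina = np.zeros_like(p_ina)
            for a in range(T + 1):
                if p_act[a]:
                    p_d = z / (1.0 + a)
                    new_act[1] += p_act[a] * p_d * reform
                    new_ina[1] += p_act[a] * p_d * (1.0 - reform)
                    new_act[a + 1] += p_act[a] * (1.0 - p_d)
                if p_ina[a]:
                    q = 1.0 - (1.0 - b / (1.0 + a)) ** 2
                    new_act[1] += p_ina[a] * q
                    new_ina[a + 1] += p_ina[a] * (1.0 - q)
            p_act, p_ina = new_act, new_ina
            expected += p_act.sum()
        expected /= T

        # Monte Carlo through the compiled generator (1 s windows)
        groups = GroupStructure.equal_groups(1, 2)
        params = ContactModelParams(b=b, z=z, dt=1, duration=T)
        n_runs = 400
        fractions = [
            generate(params, groups, seed=1000 + k, resolution=1).n_events / T
            for k in range(n_runs)
        ]
        mc = float(np.mean(fractions))
        se = float(np.std(fractions)) / math.sqrt(n_runs)
        assert abs(mc - expected) < 4 * se + 1e-3

        # and through the pure-python reference step()
        rng = np.random.default_rng(7)
        fr = []
        for _ in range(150):
            st = GeneratorState.initial(2)
            active_windows = 0
            for _ in range(T):
                step(st, params, groups, rng)
                active_windows += int(st.active[0, 1])
            fr.append(active_windows / T)
        mc2 = float(np.mean(fr))
        se2 = float(np.std(fr)) / math.sqrt(len(fr))
        assert abs(mc2 - expected) < 4 * se2 + 1e-3


class TestContactRatio:
    def test_hand_built_two_group_network(self, two_group_toy):
        # 2 within-group contacts over 2 same-group pairs, 1 cross contact
        # over 4 cross pairs: ratio = (2/2) / (1/4) = 4
        assert contact_ratio(two_group_toy) == pytest.approx(4.0)

    def test_count_contacts_merges_adjacent_windows(self, two_group_toy):
        import numpy as np

        from sirmix.network import TemporalContactNetwork

        net = TemporalContactNetwork(
            node_ids=["a", "b"],
            times=np.array([0, 20, 100]),  # windows 0,1 merge; 100 is separate
            src=np.array([0, 0, 0]),
            dst=np.array([1, 1, 1]),
        )
        _, _, counts = count_contacts(net)
        assert list(counts) == [2]

    def test_only_within_group_events_signal_infinity(self, two_group_toy):
        from sirmix.network import subset_groups

        # dropping the cross event: restrict then re-attach both groups
        net = two_group_toy
        within_only = subset_groups(net, [0])
        # rebuild a 2-group labelling over the one-group network is impossible;
        # instead test directly with a crafted network
        import numpy as np

        from sirmix.network import TemporalContactNetwork

        crafted = TemporalContactNetwork(
            node_ids=["a", "b", "c", "d"],
            times=np.array([0]),
            src=np.array([0]),
            dst=np.array([1]),
            groups=net.groups,
        )
        assert contact_ratio(crafted) == math.inf
        assert within_only.n_events == 1  # sanity on the subset above

    def test_empty_network_rejected(self, two_group_toy):
        import numpy as np

        from sirmix.network import TemporalContactNetwork

        empty = TemporalContactNetwork(
            node_ids=["a", "b", "c", "d"],
            times=np.array([], dtype=int),
            src=np.array([], dtype=int),
            dst=np.array([], dtype=int),
            groups=two_group_toy.groups,
        )
        with pytest.raises(ValueError, match="empty"):
            contact_ratio(empty)


class TestCalibrateAffinities:
    def test_target_one_returns_near_symmetric_affinities(self):
        # with a symmetric target the search should stay close to a0 == a1,
        # up to the sampling noise of the pilot ratio measurements
        groups = GroupStructure.equal_groups(2, 10)
        params = ContactModelParams(duration=DAY)
        a0, a1 = calibrate_affinities(params, groups, 1.0, seed=1)
        assert 0.6 <= a1 / a0 <= 1 / 0.6

    def test_measured_ratio_increases_with_affinity_ratio(self):
        groups = GroupStructure.equal_groups(3, 20)
        ratios = []
        for a1 in (1.0, 0.05, 0.005):
            r = []
            for s in (11, 12):
                net = generate(
                    ContactModelParams(affinity_out=a1, duration=DAY), groups, seed=s
                )
                r.append(contact_ratio(net, groups))
            ratios.append(float(np.exp(np.mean(np.log(r)))))
        assert ratios[0] < ratios[1] < ratios[2]

    def test_target_fifty_reached_within_twenty_percent(self):
        # calibration pilot and production draw share the seed (the pipeline's
        # coupling), so the generated network itself carries the target ratio
        groups = GroupStructure.equal_groups(3, 20)
        params = ContactModelParams(duration=3 * DAY)
        a0, a1 = calibrate_affinities(params, groups, 50.0, seed=4, n_pilots=1)
        net = generate(
            ContactModelParams(affinity_in=a0, affinity_out=a1, duration=3 * DAY),
            groups, seed=4,
        )
        assert 40 <= contact_ratio(net) <= 60
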