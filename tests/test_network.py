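"""Association matrices and node metrics against brute-force oracles."""

import itertools

import networkx as nx
import numpy as np
import pandas as pd
import pytest

from flocknet import (AssociationMatrix, betweenness, build_gbi,
                      daily_networks, degree, eigenvector_centrality,
                      node_metric_table, parent_association, repeatability,
                      social_differentiation, sri)
from flocknet.events import GatheringEvent
from flocknet.simulate import BirdRecord


def _roster(n, room="R1"):
    return [BirdRecord(f"B{i}", f"F{i // 2 + 1:02d}", room, "chick",
                       "M", "control") for i in range(n)]


def _gbi_from_sets(event_sets, roster):
    evs = [GatheringEvent(i, "R1F1", 1, float(i), float(i) + 0.5,
                          frozenset(s), {t: 1 for t in s}, "R1")
           for i, s in enumerate(event_sets)]
    return build_gbi(evs, roster)


def _mat(w, n=None, room="R1"):
    w = np.asarray(w, dtype=float)
    n = n or w.shape[0]
    tags = [f"B{i}" for i in range(n)]
    return AssociationMatrix(w, tags, [room] * n)


class TestSRI:
    def test_always_together_is_one(self):
        roster = _roster(2)
        gbi = _gbi_from_sets([{"B0", "B1"}] * 7, roster)
        assert sri(gbi).weights[0, 1] == 1.0

    def test_never_together_is_zero(self):
        roster = _roster(2)
        gbi = _gbi_from_sets([{"B0"}] * 3 + [{"B1"}] * 4, roster)
        assert sri(gbi).weights[0, 1] == 0.0

    def test_worked_example(self):
        roster = _roster(3)
        gbi = _gbi_from_sets(
            [{"B0", "B1"}, {"B0"}, {"B1", "B2"}, {"B0", "B1", "B2"}, {"B2"}],
            roster)
        w = sri(gbi).weights
        assert w[0, 1] == pytest.approx(0.5)
        assert w[0, 2] == pytest.approx(0.2)
        assert w[1, 2] == pytest.approx(0.5)

    def test_equals_jaccard_oracle_exhaustively(self):
        """SRI == Jaccard of event-membership sets over all small GBIs."""
        rng = np.random.default_rng(0)
        roster = _roster(5)
        for _ in range(50):
            n_events = int(rng.integers(2, 9))
            sets = []
            for _ in range(n_events):
                k = int(rng.integers(1, 5))
                sets.append(set(rng.choice([b.tag for b in roster], k,
                                           replace=False)))
            a = sri(_gbi_from_sets(sets, roster))
            for i, j in itertools.combinations(range(5), 2):
                ei = {e for e, s in enumerate(sets) if f"B{i}" in s}
                ej = {e for e, s in enumerate(sets) if f"B{j}" in s}
                expect = len(ei & ej) / len(ei | ej) if ei | ej else 0.0
                assert a.weights[i, j] == pytest.approx(expect)

    def test_cross_room_edges_zero(self):
        roster = _roster(2) + _roster(2, room="R2")
        for i, b in enumerate(roster):  # retag to be unique
            roster[i] = BirdRecord(f"X{i}", b.family_id, b.room_id, b.role,
                                   b.sex, b.treatment)
        evs = [GatheringEvent(0, "R1F1", 1, 0, 1, frozenset({"X0", "X1"}),
                              {}, "R1"),
               GatheringEvent(1, "R2F1", 1, 0, 1, frozenset({"X2", "X3"}),
                              {}, "R2")]
        a = sri(build_gbi(evs, roster))
        assert a.weights[0, 2] == 0 and a.weights[1, 3] == 0

    def test_overall_not_mean_of_daily(self):
        """The study-period network is not the average of daily networks:
        counterexample with uneven sampling across days."""
        roster = _roster(2)
        evs = [GatheringEvent(0, "R1F1", 1, 0, 1, frozenset({"B0", "B1"}), {}, "R1"),
               GatheringEvent(1, "R1F1", 2, 0, 1, frozenset({"B0", "B1"}), {}, "R1"),
               GatheringEvent(2, "R1F1", 2, 2, 3, frozenset({"B0"}), {}, "R1"),
               GatheringEvent(3, "R1F1", 2, 4, 5, frozenset({"B0"}), {}, "R1")]
        overall = sri(build_gbi(evs, roster)).weights[0, 1]
        dailies = daily_networks(evs, roster)
        mean_daily = np.mean([d.weights[0, 1] for d in dailies])
        assert overall == pytest.approx(0.5)
        assert mean_daily == pytest.approx((1.0 + 1 / 3) / 2)
        assert overall != pytest.approx(mean_daily)


class TestDailyNetworks:
    def test_one_matrix_per_day_with_flagged_gaps(self):
        roster = _roster(2)
        evs = [GatheringEvent(0, "R1F1", 1, 0, 1, frozenset({"B0", "B1"}), {}, "R1"),
               GatheringEvent(1, "R1F1", 3, 0, 1, frozenset({"B0", "B1"}), {}, "R1")]
        dailies = daily_networks(evs, roster, n_days=4)
        assert len(dailies) == 4
        assert [d.empty for d in dailies] == [False, True, False, True]
        assert all(d.tags == dailies[0].tags for d in dailies)

    def test_default_simulation_yields_35_daily_networks(self, small_roster,
                                                         small_stream,
                                                         small_config):
        _, truth = small_stream
        dailies = daily_networks(truth, small_roster,
                                 n_days=small_config.n_days)
        assert len(dailies) == small_config.n_days


class TestDegreeAndBetweenness:
    def test_triangle(self):
        a = _mat([[0, .5, .5], [.5, 0, .5], [.5, .5, 0]])
        assert degree(a).tolist() == [2, 2, 2]
        assert degree(a, weighted=True).tolist() == [1.0, 1.0, 1.0]
        assert betweenness(a).tolist() == [0, 0, 0]

    def test_isolated_node(self):
        a = _mat([[0, 1, 0], [1, 0, 0], [0, 0, 0]])
        assert degree(a)[2] == 0 and degree(a, weighted=True)[2] == 0.0

    def test_path_center_betweenness(self):
        a = _mat([[0, .4, 0], [.4, 0, .4], [0, .4, 0]])
        assert betweenness(a).tolist() == [0, 1, 0]

    def test_degree_matches_row_scan_oracle(self, rng):
        for _ in range(100):
            n = 5
            w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.5), 1)
            w = w + w.T
            a = _mat(w)
            for i in range(n):
                assert degree(a)[i] == sum(w[i, j] > 0 for j in range(n))
                assert degree(a, weighted=True)[i] == pytest.approx(w[i].sum())

    def test_weighted_betweenness_matches_path_enumeration(self, rng):
        """Independent oracle: enumerate all simple paths, find geodesics
        under the 1/w length, credit interior nodes fractionally."""
        for trial in range(10):
            n = 7
            w = np.triu((rng.random((n, n)) < 0.5) * rng.random((n, n)), 1)
            w = w + w.T
            a = _mat(w)
            g = nx.from_numpy_array(w)
            expect = np.zeros(n)
            for s, t in itertools.combinations(range(n), 2):
                if not nx.has_path(g, s, t):
                    continue
                paths = list(nx.all_simple_paths(g, s, t))
                lengths = [sum(1.0 / w[u, v] for u, v in zip(p, p[1:]))
                           for p in paths]
                best = min(lengths)
                geos = [p for p, l in zip(paths, lengths)
                        if l <= best + 1e-12]
                for p in geos:
                    for v in p[1:-1]:
                        expect[v] += 1.0 / len(geos)
            np.testing.assert_allclose(betweenness(a, weighted=True), expect,
                                       atol=1e-9)


class TestEigenvector:
    def test_complete_graph_uniform(self):
        a = _mat(0.3 * (1 - np.eye(4)))
        np.testing.assert_allclose(eigenvector_centrality(a), 1.0)

    def test_star_center_dominates(self):
        w = np.zeros((5, 5))
        w[0, 1:] = w[1:, 0] = 0.5
        c = eigenvector_centrality(_mat(w))
        assert c[0] == 1.0 and np.all(c[1:] < 1.0)

    def test_matches_dense_eigendecomposition(self, rng):
        for _ in range(20):
            n = 6
            w = np.triu(rng.random((n, n)) * (rng.random((n, n)) < 0.7), 1)
            w = w + w.T
            if not np.any(w > 0):
                continue
            c = eigenvector_centrality(_mat(w))
            g = nx.from_numpy_array(w)
            for comp in nx.connected_components(g):
                idx = np.asarray(sorted(comp))
                if idx.size == 1:
                    assert c[idx[0]] == 0.0
                    continue
                vals, vecs = np.linalg.eigh(w[np.ix_(idx, idx)])
                lead = np.abs(vecs[:, -1])
                np.testing.assert_allclose(c[idx], lead / lead.max(),
                                           atol=1e-8)

    def test_all_zero_matrix_warns(self):
        with pytest.warns(UserWarning):
            c = eigenvector_centrality(_mat(np.zeros((3, 3))))
        assert np.all(c == 0)


class TestSocialDifferentiation:
    def test_equal_weights_zero_cv(self):
        a = _mat(0.4 * (1 - np.eye(4)))
        assert social_differentiation(a, "B0") == pytest.approx(0.0)

    def test_single_partner_cv(self):
        w = np.zeros((5, 5))
        w[0, 1] = w[1, 0] = 1.0
        assert social_differentiation(_mat(w), "B0") == pytest.approx(np.sqrt(3))

    def test_relabelling_other_nodes_invariant(self, rng):
        w = rng.random((5, 5))
        w = np.triu(w, 1) + np.triu(w, 1).T
        a = _mat(w)
        base = social_differentiation(a, "B0")
        perm = np.concatenate([[0], 1 + rng.permutation(4)])
        b = AssociationMatrix(w[np.ix_(perm, perm)],
                              [a.tags[i] for i in perm], ["R1"] * 5)
        assert social_differentiation(b, "B0") == pytest.approx(base)

    def test_singleton_room_undefined(self):
        a = AssociationMatrix(np.zeros((2, 2)), ["B0", "B1"], ["R1", "R2"])
        with pytest.raises(ValueError):
            social_differentiation(a, "B0")


class TestParentAssociation:
    @staticmethod
    def _family():
        return [
            BirdRecord("PM", "F01", "R1", "parent", "M", "NA", "PF"),
            BirdRecord("PF", "F01", "R1", "parent", "F", "NA", "PM"),
            BirdRecord("CK", "F01", "R1", "chick", "M", "CORT"),
        ]

    def test_mean_of_two_parent_edges(self):
        w = np.array([[0, 0, .4], [0, 0, .6], [.4, .6, 0]])
        a = AssociationMatrix(w, ["PM", "PF", "CK"], ["R1"] * 3)
        assert parent_association(a, self._family(), "CK") == pytest.approx(0.5)

    def test_unobserved_parents_give_zero(self):
        a = AssociationMatrix(np.zeros((3, 3)), ["PM", "PF", "CK"], ["R1"] * 3)
        assert parent_association(a, self._family(), "CK") == 0.0

    def test_parent_as_focal_rejected(self):
        a = AssociationMatrix(np.zeros((3, 3)), ["PM", "PF", "CK"], ["R1"] * 3)
        with pytest.raises(ValueError):
            parent_association(a, self._family(), "PM")

    def test_matches_daily_gbi_recomputation(self, small_roster, small_gbi):
        from flocknet import metrics_from_gbi

        df = metrics_from_gbi(small_gbi, small_roster,
                              metrics=("parent_association",))
        dailies = daily_networks(small_gbi.events, small_roster)
        table = node_metric_table(dailies, small_roster,
                                  metrics=("parent_association",))
        merged = df.merge(table, on=["tag", "day"], suffixes=("_fast", "_ref"))
        merged = merged.dropna()
        np.testing.assert_allclose(merged["parent_association_fast"],
                                   merged["parent_association_ref"],
                                   atol=1e-12)


class TestRepeatability:
    def test_constant_within_bird_gives_one(self):
        df = pd.DataFrame({"tag": np.repeat(list("abcd"), 5),
                           "day": np.tile(range(5), 4),
                           "m": np.repeat([1.0, 2.0, 3.0, 4.0], 5)})
        assert repeatability(df, "m")["icc"] == pytest.approx(1.0)

    def test_iid_values_near_zero(self, rng):
        df = pd.DataFrame({"tag": np.repeat([f"b{i}" for i in range(50)], 35),
                           "day": np.tile(range(35), 50),
                           "m": rng.normal(size=50 * 35)})
        assert abs(repeatability(df, "m")["icc_raw"]) < 0.1

    def test_balanced_two_group_hand_example(self):
        # two birds x three days; textbook one-way ANOVA arithmetic:
        # groups (1,2,3) and (5,6,7): MS_among = 24, MS_within = 1, k0 = 3
        # R = (24 - 1) / (24 + 2*1) = 23/26
        df = pd.DataFrame({"tag": ["a"] * 3 + ["b"] * 3,
                           "day": [1, 2, 3] * 2,
                           "m": [1.0, 2, 3, 5, 6, 7]})
        assert repeatability(df, "m")["icc"] == pytest.approx(23 / 26)

    def test_single_day_rejected(self):
        df = pd.DataFrame({"tag": ["a", "b"], "day": [1, 1], "m": [1.0, 2.0]})
        with pytest.raises(ValueError):
            repeatability(df, "m")
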