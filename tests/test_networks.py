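"""Gathering detection, simple-ratio indices, layer routing, presence."""

import numpy as np
import pandas as pd
import pytest

from tadanet import networks as nw
from tadanet.networks import DAY_S, GatheringEvent

from conftest import detection_frame


def ge(members, start=0.0, end=1.0, site="S1", day=0):
    return GatheringEvent(site, day, frozenset(members), (start, end))


class TestGatheringDetection:
    def test_two_separated_bursts(self):
        rng = np.random.default_rng(0)
        rows = []
        for centre, birds in ((9 * 3600, ["a", "b"]), (13 * 3600, ["c", "d"])):
            for b in birds:
                for _ in range(10):
                    rows.append((b, centre + rng.normal(0, 60), "S1", "network_feeder"))
        det = detection_frame(rows)
        events = nw.detect_gathering_events(det, seed=0)
        assert len(events) == 2
        assert {frozenset(e.member_ids) for e in events} == {
            frozenset({"a", "b"}),
            frozenset({"c", "d"}),
        }

    def test_degenerate_inputs(self):
        one = detection_frame([("a", 100.0, "S1", "network_feeder")])
        assert len(nw.detect_gathering_events(one)) == 1
        same = detection_frame([(b, 100.0, "S1", "network_feeder") for b in "abc"])
        events = nw.detect_gathering_events(same)
        assert len(events) == 1 and events[0].member_ids == frozenset("abc")

    def test_three_component_mixture_assignment(self):
        rng = np.random.default_rng(123)
        rows, labels = [], []
        centres = [9 * 3600, 12 * 3600, 15 * 3600]
        for k, centre in enumerate(centres):
            for i in range(40):
                rows.append((f"b{k}_{i % 8}", centre + rng.normal(0, 90), "S1",
                             "network_feeder"))
                labels.append(k)
        det = detection_frame(rows)
        events = nw.detect_gathering_events(det, seed=0)
        assert len(events) == 3
        # membership of each event should be one generating component's birds
        correct = 0
        for e in events:
            k = int(np.argmin([abs(0.5 * sum(e.time_span) - c) for c in centres]))
            correct += sum(1 for b in e.member_ids if b.startswith(f"b{k}_"))
        assert correct / 24 >= 0.95  # 3 components x 8 distinct birds

    def test_deterministic_given_seed(self):
        rng = np.random.default_rng(9)
        det = detection_frame(
            [(f"b{i%6}", float(rng.uniform(0, 3600 * 10)), "S1", "network_feeder")
             for i in range(120)]
        )
        a = nw.detect_gathering_events(det, seed=5)
        b = nw.detect_gathering_events(det, seed=5)
        assert a == b


class TestSimpleRatioIndex:
    def test_always_together_is_one(self):
        events = [ge({"A", "B", "C"}) for _ in range(5)]
        assert nw.simple_ratio_index(events, "A", "B") == 1.0

    def test_disjoint_is_zero(self):
        events = [ge({"A"}), ge({"A"}), ge({"B"}), ge({"B"})]
        assert nw.simple_ratio_index(events, "A", "B") == 0.0

    def test_hand_count(self):
        events = [ge({"A", "B"}), ge({"A", "B"}), ge({"A"}), ge({"B"})]
        assert nw.simple_ratio_index(events, "A", "B") == pytest.approx(0.5)

    def test_monotonicity(self):
        rng = np.random.default_rng(3)
        events = [
            ge(set(rng.choice(list("ABCDE"), rng.integers(1, 5), replace=False)))
            for _ in range(30)
        ]
        base = nw.simple_ratio_index(events, "A", "B")
        assert nw.simple_ratio_index(events + [ge({"A", "B"})], "A", "B") >= base
        assert nw.simple_ratio_index(events + [ge({"A"})], "A", "B") <= base
        assert nw.simple_ratio_index(events, "B", "A") == base
        assert 0.0 <= base <= 1.0


class TestLayerMasks:
    def test_definitions(self, toy_registry):
        assert nw.dyad_layer(toy_registry, "J1", "A-F") == "vertical"
        assert nw.dyad_layer(toy_registry, "J1", "J2") == "sibling"
        assert nw.dyad_layer(toy_registry, "J1", "J3") == "peer"
        assert nw.dyad_layer(toy_registry, "J1", "B-M") == "oblique"
        assert nw.dyad_layer(toy_registry, "A-F", "B-M") is None

    def test_exhaustive_against_rule_checker(self, toy_registry):
        masks = nw.layer_masks(toy_registry)
        ids = toy_registry.bird_ids
        for i, a in enumerate(ids):
            for b in ids[i + 1:]:
                a_j, b_j = toy_registry.is_juvenile(a), toy_registry.is_juvenile(b)
                if a_j and b_j:
                    want = (
                        "sibling"
                        if toy_registry.brood(a) == toy_registry.brood(b)
                        else "peer"
                    )
                elif a_j or b_j:
                    juv, ad = (a, b) if a_j else (b, a)
                    want = "vertical" if ad in toy_registry.parents(juv) else "oblique"
                else:
                    want = None
                assert masks.get(tuple(sorted((a, b)))) == want
        # layers partition admissible dyads: each dyad appears at most once
        assert len(masks) == len(set(masks))


class TestDynamicNetwork:
    def _stream(self, toy_registry, rng, co_feeding=True):
        rows = []
        for day in range(14):
            centre = day * DAY_S + 10 * 3600
            birds = toy_registry.bird_ids if co_feeding else ["J1"]
            for b in birds:
                for _ in range(3):
                    rows.append((b, centre + rng.normal(0, 60), "S1", "network_feeder"))
        return detection_frame(rows)

    def test_empty_window_gives_zero_network(self, toy_registry):
        det = detection_frame(
            [("J1", 0.0, "S1", "network_feeder")] * 12
        )
        net = nw.dynamic_network(det, toy_registry, event_time=40 * DAY_S)
        assert all(net.matrices[l].sum() == 0 for l in nw.LAYERS)

    def test_single_family_cofeeding(self, toy_registry):
        rng = np.random.default_rng(0)
        rows = []
        for day in range(14):
            centre = day * DAY_S + 10 * 3600
            for b in ["A-F", "A-M", "J1", "J2"]:
                rows.append((b, centre + rng.normal(0, 30), "S1", "network_feeder"))
        det = detection_frame(rows)
        net = nw.dynamic_network(det, toy_registry, event_time=7 * DAY_S)
        i, j = net.index_of("J1"), net.index_of("J2")
        assert net.matrices["sibling"][i, j] == 1.0
        assert net.matrices["vertical"][i, net.index_of("A-F")] == 1.0
        assert net.matrices["oblique"].sum() == 0
        assert net.matrices["peer"].sum() == 0

    def test_weights_match_independent_recomputation(self, toy_registry):
        rng = np.random.default_rng(8)
        rows = []
        for day in range(10):
            for g in range(2):
                centre = day * DAY_S + (9 + 4 * g) * 3600
                members = rng.choice(
                    toy_registry.bird_ids, rng.integers(2, 7), replace=False
                )
                for b in members:
                    for _ in range(2):
                        rows.append(
                            (b, centre + rng.normal(0, 40), "S1", "network_feeder")
                        )
        det = detection_frame(rows)
        net = nw.dynamic_network(det, toy_registry, event_time=5 * DAY_S, seed=0)
        # independent path: gatherings -> per-dyad SRI by the set-count rule
        window = (5 * DAY_S - 7 * DAY_S, 5 * DAY_S + 7 * DAY_S)
        counts = det["bird_id"].value_counts()
        included = [b for b in toy_registry.bird_ids if counts.get(b, 0) >= 10]
        gatherings = nw.gathering_events_in_window(
            det[det["bird_id"].isin(included)], window[0], window[1], seed=0
        )
        masks = nw.layer_masks(toy_registry)
        for (a, b), layer in masks.items():
            if a not in included or b not in included:
                continue
            want = nw.simple_ratio_index(gatherings, a, b)
            got = net.matrices[layer][net.index_of(a), net.index_of(b)]
            assert got == pytest.approx(want, abs=1e-12)

    def test_bit_reproducible(self, toy_registry):
        rng = np.random.default_rng(1)
        det = self._stream(toy_registry, rng)
        a = nw.dynamic_network(det, toy_registry, 7 * DAY_S, seed=3)
        b = nw.dynamic_network(det, toy_registry, 7 * DAY_S, seed=3)
        for layer in nw.LAYERS:
            assert np.array_equal(a.matrices[layer], b.matrices[layer])

    def test_positive_weights_in_exactly_one_layer(self, toy_registry):
        rng = np.random.default_rng(4)
        det = self._stream(toy_registry, rng)
        net = nw.dynamic_network(det, toy_registry, 7 * DAY_S)
        positive = sum((net.matrices[l] > 0).astype(int) for l in nw.LAYERS)
        assert positive.max() <= 1


class TestPresenceMatrix:
    def test_site_and_window_rules(self, toy_registry):
        det = detection_frame(
            [
                ("J1", 4 * DAY_S, "S1", "network_feeder"),  # 3 days before event
                ("J2", 4 * DAY_S, "S2", "network_feeder"),  # wrong site
                ("J3", 7 * DAY_S + 1.0, "S1", "network_feeder"),  # after event
            ]
        )
        puz = pd.DataFrame(
            [("J4", 6.5 * DAY_S, "S1", "visit")],
            columns=["bird_id", "timestamp", "site_id", "action"],
        )
        acq = pd.DataFrame(
            [("J5", 7 * DAY_S, "S1")], columns=["learner_id", "timestamp", "site_id"]
        )
        pres = nw.presence_matrix(det, puz, acq, toy_registry)
        assert pres.loc["J1", 0] == 1
        assert pres.loc["J2", 0] == 0
        assert pres.loc["J3", 0] == 0
        assert pres.loc["J4", 0] == 1  # puzzle visits count

    def test_matches_brute_force(self, toy_registry):
        rng = np.random.default_rng(6)
        det = detection_frame(
            [
                (
                    rng.choice(toy_registry.bird_ids),
                    float(rng.uniform(0, 30 * DAY_S)),
                    rng.choice(["S1", "S2"]),
                    "network_feeder",
                )
                for _ in range(300)
            ]
        )
        puz = pd.DataFrame(
            [
                (
                    rng.choice(toy_registry.bird_ids),
                    float(rng.uniform(0, 30 * DAY_S)),
                    rng.choice(["S1", "S2"]),
                    "visit",
                )
                for _ in range(100)
            ],
            columns=["bird_id", "timestamp", "site_id", "action"],
        )
        acq = pd.DataFrame(
            [
                ("J1", float(rng.uniform(8, 29) * DAY_S), rng.choice(["S1", "S2"]))
                for _ in range(5)
            ],
            columns=["learner_id", "timestamp", "site_id"],
        )
        pres = nw.presence_matrix(det, puz, acq, toy_registry)
        allev = pd.concat(
            [det[["bird_id", "timestamp", "site_id"]], puz[["bird_id", "timestamp", "site_id"]]]
        )
        for b in toy_registry.bird_ids:
            for e, r in acq.iterrows():
                hit = allev[
                    (allev.bird_id == b)
                    & (allev.site_id == r.site_id)
                    & (allev.timestamp > r.timestamp - 7 * DAY_S)
                    & (allev.timestamp <= r.timestamp)
                ]
                assert pres.loc[b, e] == (1 if len(hit) else 0)
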