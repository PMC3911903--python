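"""Network grouping by contained sets, signature enumeration and voting."""

from __future__ import annotations

import numpy as np
import pytest

from charnets import (
    ConflictError,
    Ensemble,
    SignedInteraction,
    contains_set,
    enumerate_valid_signatures,
    extract_characteristic_sets,
    group_ensembles,
    group_networks,
    group_score,
    signed_vote,
)
from charnets.dependencies import CharacteristicSet, CharacteristicSetSystem
from charnets.grouping import NetworkGroup
from helpers import make_collection, make_network

E = SignedInteraction


def _system(set_members: dict, competitions=(), conflicts=()):
    sets = tuple(
        CharacteristicSet(sid, frozenset(E(*m) for m in members), 0.5)
        for sid, members in sorted(set_members.items())
    )
    return CharacteristicSetSystem(
        sets=sets,
        competitions=frozenset(tuple(sorted(p)) for p in competitions),
        conflicts=frozenset(tuple(sorted(p)) for p in conflicts),
    )


THREE_SETS = _system(
    {
        "S1": [("A", "X", "+"), ("B", "X", "-")],
        "S2": [("C", "Y", "+"), ("D", "Y", "-")],
        "S3": [("E", "Y", "+"), ("F", "Y", "-")],
    },
    competitions=[("S2", "S3")],
)


class TestContainsSet:
    cset = THREE_SETS.sets[0]

    def test_containment_requires_all_members(self):
        full = make_network("n", [("A", "X", "+"), ("B", "X", "-"), ("Z", "X", "+")])
        partial = make_network("n", [("A", "X", "+")])
        empty = make_network("n", [])
        assert contains_set(full, self.cset)
        assert not contains_set(partial, self.cset)
        assert not contains_set(empty, self.cset)


class TestEnumerateSignatures:
    def test_three_sets_one_competing_pair_gives_five(self):
        sigs = enumerate_valid_signatures(THREE_SETS)
        assert [sorted(s) for s in sigs] == [
            ["S1"],
            ["S2"],
            ["S3"],
            ["S1", "S2"],
            ["S1", "S3"],
        ]

    def test_single_set(self):
        system = _system({"S1": [("A", "X", "+"), ("B", "X", "-")]})
        assert enumerate_valid_signatures(system) == [frozenset({"S1"})]

    def test_two_mutually_competing_sets(self):
        system = _system(
            {"S1": [("A", "X", "+"), ("B", "X", "-")], "S2": [("C", "Y", "+"), ("D", "Y", "-")]},
            competitions=[("S1", "S2")],
        )
        assert [sorted(s) for s in enumerate_valid_signatures(system)] == [["S1"], ["S2"]]

    def test_conflicted_system_refuses(self):
        system = _system(
            {"S1": [("A", "X", "+"), ("B", "X", "-")]}, conflicts=[("S1", "S1")]
        )
        with pytest.raises(ConflictError):
            enumerate_valid_signatures(system)


class TestGroupNetworks:
    s1 = [("A", "X", "+"), ("B", "X", "-")]
    s2 = [("C", "Y", "+"), ("D", "Y", "-")]
    s3 = [("E", "Y", "+"), ("F", "Y", "-")]

    def _collection(self):
        return make_collection(
            {
                "only_s1": self.s1,
                "s1_and_s2": self.s1 + self.s2,
                "nothing": [("Z", "X", "+")],
                "partial_s2": self.s2[:1],
                "competing": self.s2 + self.s3,
            }
        )

    def test_partition_into_groups_excluded_and_violations(self):
        grouping = group_networks(self._collection(), THREE_SETS)
        by_sig = {tuple(sorted(g.signature)): g.member_ids for g in grouping.groups}
        assert by_sig == {("S1",): ("only_s1",), ("S1", "S2"): ("s1_and_s2",)}
        assert set(grouping.excluded) == {"nothing", "partial_s2", "competing"}
        assert grouping.violations == ("competing",)

    def test_keep_violations_groups_by_all_contained_sets(self):
        grouping = group_networks(self._collection(), THREE_SETS, keep_violations=True)
        sigs = {tuple(sorted(g.signature)) for g in grouping.groups}
        assert ("S2", "S3") in sigs
        assert "competing" not in grouping.excluded

    def test_every_network_lands_in_exactly_one_bucket(self):
        coll = self._collection()
        grouping = group_networks(coll, THREE_SETS)
        grouped = [nid for g in grouping.groups for nid in g.member_ids]
        assert sorted(grouped + list(grouping.excluded)) == sorted(
            n.network_id for n in coll
        )

    def test_conflicted_system_needs_force(self):
        system = _system(
            {"S1": self.s1}, conflicts=[("S1", "S1")]
        )
        coll = make_collection({"n1": self.s1})
        with pytest.raises(ConflictError):
            group_networks(coll, system)
        grouping = group_networks(coll, system, force=True)
        assert grouping.groups[0].member_ids == ("n1",)


class TestSignedVote:
    def test_one_sided_edge_gets_its_frequency(self):
        nets = [make_network(f"n{i}", [("A", "B", "+")]) for i in range(6)]
        nets += [make_network(f"m{i}", []) for i in range(4)]
        ens = signed_vote(nets)
        assert ens.weight(E("A", "B", "+")) == pytest.approx(0.6)
        assert ens.n_networks == 10

    def test_exact_sign_tie_cancels_to_no_entry(self):
        nets = [make_network(f"p{i}", [("A", "B", "+")]) for i in range(5)]
        nets += [make_network(f"q{i}", [("A", "B", "-")]) for i in range(5)]
        ens = signed_vote(nets)
        assert len(ens) == 0

    def test_majority_sign_wins_with_net_weight(self):
        nets = [make_network(f"p{i}", [("A", "B", "+")]) for i in range(7)]
        nets += [make_network(f"q{i}", [("A", "B", "-")]) for i in range(3)]
        ens = signed_vote(nets)
        assert ens.weight(E("A", "B", "+")) == pytest.approx(0.4)
        assert ens.weight(E("A", "B", "-")) == 0.0

    def test_frequency_scheme_keeps_both_signs(self):
        nets = [make_network(f"p{i}", [("A", "B", "+")]) for i in range(7)]
        nets += [make_network(f"q{i}", [("A", "B", "-")]) for i in range(3)]
        ens = signed_vote(nets, scheme="frequency")
        assert ens.weight(E("A", "B", "+")) == pytest.approx(0.7)
        assert ens.weight(E("A", "B", "-")) == pytest.approx(0.3)

    def test_single_network_weights_are_zero_or_one(self):
        ens = signed_vote([make_network("n", [("A", "B", "+"), ("B", "C", "-")])])
        assert set(ens.weights.values()) == {1.0}

    def test_weights_always_within_unit_interval(self):
        rng = np.random.default_rng(5)
        genes = [f"g{i}" for i in range(4)]
        for _ in range(50):
            nets = []
            for i in range(int(rng.integers(1, 8))):
                edges = [
                    (e, t, "+" if rng.random() < 0.5 else "-")
                    for e in genes
                    for t in genes
                    if e != t and rng.random() < 0.4
                ]
                dedup = {}
                for e, t, s in edges:
                    dedup[(e, t)] = s
                nets.append(
                    make_network(f"n{i}", [(e, t, s) for (e, t), s in dedup.items()])
                )
            for scheme in ("signed", "frequency"):
                ens = signed_vote(nets, scheme=scheme)
                assert all(0.0 < w <= 1.0 for w in ens.weights.values())

    def test_empty_list_is_an_error(self):
        with pytest.raises(ValueError):
            signed_vote([])


class TestGroupEnsembles:
    def test_characteristic_members_have_within_group_frequency_one(
        self, two_set_collection
    ):
        result = extract_characteristic_sets(two_set_collection)
        grouping = group_networks(two_set_collection, result.system)
        ensembles = group_ensembles(grouping.groups, two_set_collection)
        for group in grouping.groups:
            ens = ensembles[group.signature]
            for sid in group.signature:
                for member in result.system.set_by_id(sid).members:
                    assert ens.weight(member) == 1.0

    def test_backbone_rides_along_in_every_group_ensemble(self, two_set_collection):
        result = extract_characteristic_sets(two_set_collection)
        grouping = group_networks(two_set_collection, result.system)
        ensembles = group_ensembles(grouping.groups, two_set_collection)
        for ens in ensembles.values():
            assert ens.weight(E("X", "Y", "+")) == 1.0

    def test_each_group_voted_over_its_own_member_count(self, two_set_collection):
        result = extract_characteristic_sets(two_set_collection)
        grouping = group_networks(two_set_collection, result.system)
        ensembles = group_ensembles(grouping.groups, two_set_collection)
        assert {e.n_networks for e in ensembles.values()} == {4}


class TestGroupScore:
    def test_mean_of_member_scores(self):
        coll = make_collection({"n1": [("A", "B", "+")], "n2": [("A", "B", "+")]})
        coll = coll.__class__(
            networks=tuple(
                n.__class__(n.network_id, n.interactions, score)
                for n, score in zip(coll.networks, (0.1, 0.2))
            ),
            gene_universe=coll.gene_universe,
        )
        group = NetworkGroup(signature=frozenset({"S1"}), member_ids=("n1", "n2"))
        assert group_score(group, coll) == pytest.approx(0.15)

    def test_missing_score_is_an_error(self):
        coll = make_collection({"n1": [("A", "B", "+")]})
        group = NetworkGroup(signature=frozenset({"S1"}), member_ids=("n1",))
        with pytest.raises(ValueError, match="no score"):
            group_score(group, coll)
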