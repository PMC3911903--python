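"""Pairwise dependency scoring and characteristic-set assembly (step 2).

Two low-confidence edges can be *co-occurring* (AND related: each is a
reliable indicator for the other) or *mutually exclusive* (EX related:
each occurs mostly without the other).  Both scores are built from
association-rule confidences — conf(a→b) = f_ab / f_a is the conditional
frequency of b among networks containing a — combined by a min
conjunction:

    AND(a, b) = min(conf(a→b), conf(b→a)) = min(f_ab/f_a, f_ab/f_b)
    EX(a, b)  = min(conf(a→¬b), conf(b→¬a))
              = min(f_a\\b / f_a, f_b\\a / f_b)

where f_a\\b is the frequency of networks containing a but not b.  Since
conf(a→b) + conf(a→¬b) = 1, the two scores sum to at most 1, so with a
score cutoff above 0.5 at most one relation can qualify for any pair.

Characteristic sets are the connected components of the graph whose edges
are the qualifying AND relations; sets linked by an EX relation are
*competing* (a valid network realizes at most one of them); an EX
relation between two members of one AND component is a conflict that
requires manual resolution.
"""

from __future__ import annotations

import enum
from collections.abc import Callable, Mapping
from dataclasses import dataclass, field

import networkx as nx

from .model import CutoffConfig, NetworkCollection, SignedInteraction, UndefinedScoreError
from .frequencies import PairKey, PairStats

#: how the two association-rule confidences are conjoined into one score;
#: "min" is the default, alternatives kept for sensitivity analyses.
CONJUNCTIONS: dict[str, Callable[[float, float], float]] = {
    "min": min,
    "product": lambda x, y: x * y,
    "bounded_product": lambda x, y: max(0.0, x + y - 1.0),
}


class Relation(str, enum.Enum):
    AND = "AND"
    EX = "EX"
    NONE = "NONE"

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


def _confidences(stats: PairStats) -> tuple[float, float]:
    if stats.f_a <= 0.0 or stats.f_b <= 0.0:
        raise UndefinedScoreError("dependency scores need positive marginal frequencies")
    return stats.f_ab / stats.f_a, stats.f_ab / stats.f_b


def and_score(stats: PairStats, conjunction: str = "min") -> float:
    """Co-occurrence score: conjunction of conf(a→b) and conf(b→a)."""
    c_ab, c_ba = _confidences(stats)
    return CONJUNCTIONS[conjunction](c_ab, c_ba)


def ex_score(stats: PairStats, conjunction: str = "min") -> float:
    """Mutual-exclusion score: conjunction of conf(a→¬b) and conf(b→¬a)."""
    c_ab, c_ba = _confidences(stats)
    return CONJUNCTIONS[conjunction](1.0 - c_ab, 1.0 - c_ba)


@dataclass(frozen=True)
class PairRelation:
    """Scored dependency between one unordered pair of LOW edges."""

    pair: PairKey
    and_score: float
    ex_score: float
    relation: Relation
    stats: PairStats


def pairwise_relations(
    pairs: Mapping[PairKey, PairStats],
    cutoffs: CutoffConfig,
    conjunction: str = "min",
) -> list[PairRelation]:
    """Decide AND / EX / NONE for every scored pair.

    A relation qualifies only if both its score and its evidence
    frequency strictly exceed the respective cutoff: the joint frequency
    f_ab for AND, and both exclusive frequencies for EX.
    """
    out: list[PairRelation] = []
    for pair in sorted(pairs):
        stats = pairs[pair]
        a_sc = and_score(stats, conjunction)
        e_sc = ex_score(stats, conjunction)
        relation = Relation.NONE
        if a_sc > cutoffs.score_cutoff and stats.f_ab > cutoffs.joint_cutoff:
            relation = Relation.AND
        elif e_sc > cutoffs.score_cutoff and (
            min(stats.f_a_not_b, stats.f_b_not_a) > cutoffs.joint_cutoff
        ):
            relation = Relation.EX
        out.append(
            PairRelation(pair=pair, and_score=a_sc, ex_score=e_sc, relation=relation, stats=stats)
        )
    return out


@dataclass(frozen=True)
class CharacteristicSet:
    """A maximal set of AND-related low-confidence interactions.

    ``support`` is the fraction of networks containing *all* members when
    computed against a collection; otherwise the smallest pairwise joint
    frequency among its AND edges (an upper bound on the true support).
    """

    set_id: str
    members: frozenset[SignedInteraction]
    support: float

    def sorted_members(self) -> list[SignedInteraction]:
        return sorted(self.members)


@dataclass(frozen=True)
class CharacteristicSetSystem:
    """Extracted sets plus the competition/conflict structure between them.

    ``competitions`` holds id pairs of sets linked by at least one EX
    relation.  ``conflicts`` holds pairs carrying both AND and EX links;
    since sets are closed under AND, the only possible form is an EX edge
    *inside* one set, recorded as the pair (set_id, set_id).  Conflicts
    are reported, never auto-resolved.
    """

    sets: tuple[CharacteristicSet, ...]
    competitions: frozenset[tuple[str, str]]
    conflicts: frozenset[tuple[str, str]]

    def set_by_id(self, set_id: str) -> CharacteristicSet:
        for s in self.sets:
            if s.set_id == set_id:
                return s
        raise KeyError(set_id)

    def set_ids(self) -> list[str]:
        return [s.set_id for s in self.sets]

    def are_competing(self, id_a: str, id_b: str) -> bool:
        return tuple(sorted((id_a, id_b))) in self.competitions

    @property
    def conflict_free(self) -> bool:
        return not self.conflicts

    def conflicted_set_ids(self) -> frozenset[str]:
        return frozenset(sid for pair in self.conflicts for sid in pair)


def build_characteristic_sets(
    relations: list[PairRelation],
    collection: NetworkCollection | None = None,
) -> CharacteristicSetSystem:
    """Merge AND-related pairs into characteristic sets.

    Each qualifying AND pair seeds a two-element set; sets sharing an AND
    relation are merged transitively, i.e. the sets are the connected
    components of the AND graph.  Set ids S1, S2, ... are assigned by the
    lexicographically smallest member so repeated runs are byte-identical.
    """
    and_graph: nx.Graph = nx.Graph()
    for rel in relations:
        if rel.relation is Relation.AND:
            and_graph.add_edge(*rel.pair, f_ab=rel.stats.f_ab)

    components = sorted(
        (sorted(c) for c in nx.connected_components(and_graph)), key=lambda c: c[0]
    )
    member_to_set: dict[SignedInteraction, str] = {}
    sets: list[CharacteristicSet] = []
    for idx, members in enumerate(components, start=1):
        set_id = f"S{idx}"
        support = _support(members, and_graph, collection)
        sets.append(
            CharacteristicSet(set_id=set_id, members=frozenset(members), support=support)
        )
        for m in members:
            member_to_set[m] = set_id

    competitions: set[tuple[str, str]] = set()
    conflicts: set[tuple[str, str]] = set()
    for rel in relations:
        if rel.relation is not Relation.EX:
            continue
        a, b = rel.pair
        sid_a, sid_b = member_to_set.get(a), member_to_set.get(b)
        if sid_a is None or sid_b is None:
            continue  # EX edges touching non-set interactions carry no set semantics
        if sid_a == sid_b:
            conflicts.add((sid_a, sid_b))
        else:
            competitions.add(tuple(sorted((sid_a, sid_b))))

    # a pair that is both competing and conflicted is kept as conflict only
    competitions -= conflicts
    return CharacteristicSetSystem(
        sets=tuple(sets),
        competitions=frozenset(competitions),
        conflicts=frozenset(conflicts),
    )


def _support(
    members: list[SignedInteraction],
    and_graph: nx.Graph,
    collection: NetworkCollection | None,
) -> float:
    if collection is not None:
        needed = set(members)
        hits = sum(1 for net in collection if needed <= net.interactions)
        return hits / len(collection)
    joints = [
        d["f_ab"]
        for u, v, d in and_graph.edges(data=True)
        if u in members and v in members
    ]
    return min(joints)
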