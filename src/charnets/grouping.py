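"""Grouping networks by contained characteristic sets and voting (step 3).

Networks are grouped by the exact combination (signature) of
characteristic sets they fully contain; networks containing none are
excluded from ensemble creation.  Voting is then applied separately per
group, so each group-ensemble carries its characteristic interactions at
within-group frequency 1 alongside the high-confidence backbone.
"""

from __future__ import annotations

import itertools
from collections import defaultdict
from collections.abc import Iterable, Mapping
from dataclasses import dataclass

from .model import (
    ACTIVATING,
    INHIBITING,
    ConflictError,
    Ensemble,
    Network,
    NetworkCollection,
    SignedInteraction,
)
from .dependencies import CharacteristicSet, CharacteristicSetSystem

GroupSignature = frozenset[str]

VOTING_SCHEMES = ("signed", "frequency")


def signature_name(signature: GroupSignature) -> str:
    """Stable human-readable label, e.g. ``S1+S3``."""
    return "+".join(sorted(signature))


@dataclass(frozen=True)
class NetworkGroup:
    """The networks sharing one signature of characteristic sets."""

    signature: GroupSignature
    member_ids: tuple[str, ...]


@dataclass(frozen=True)
class GroupingResult:
    groups: tuple[NetworkGroup, ...]
    excluded: tuple[str, ...]  # networks containing no characteristic set
    violations: tuple[str, ...]  # networks containing two competing sets

    def group_of(self, network_id: str) -> GroupSignature | None:
        for g in self.groups:
            if network_id in g.member_ids:
                return g.signature
        return None


def contains_set(network: Network, cset: CharacteristicSet) -> bool:
    """Crisp containment: every member interaction present in the network."""
    return cset.members <= network.interactions


def group_networks(
    collection: NetworkCollection,
    system: CharacteristicSetSystem,
    *,
    keep_violations: bool = False,
    force: bool = False,
) -> GroupingResult:
    """Partition the collection by contained-set signature.

    Every network ends up in exactly one group or in ``excluded``.
    Networks simultaneously containing two competing sets should not
    exist, but noise can produce them; they are flagged as violations and
    excluded unless ``keep_violations``.  A system with unresolved
    conflicts refuses automatic grouping unless ``force``.
    """
    if not system.conflict_free and not force:
        raise ConflictError(
            "characteristic-set system has intra-set conflicts; "
            "resolve manually or pass force=True"
        )
    conflicted = system.conflicted_set_ids() if not force else frozenset()

    members: dict[GroupSignature, list[str]] = defaultdict(list)
    excluded: list[str] = []
    violations: list[str] = []
    for network in collection:
        contained = frozenset(
            s.set_id
            for s in system.sets
            if s.set_id not in conflicted and contains_set(network, s)
        )
        if not contained:
            excluded.append(network.network_id)
            continue
        competing = any(
            system.are_competing(a, b)
            for a, b in itertools.combinations(sorted(contained), 2)
        )
        if competing:
            violations.append(network.network_id)
            if not keep_violations:
                excluded.append(network.network_id)
                continue
        members[contained].append(network.network_id)

    groups = tuple(
        NetworkGroup(signature=sig, member_ids=tuple(members[sig]))
        for sig in sorted(members, key=lambda s: (len(s), sorted(s)))
    )
    return GroupingResult(
        groups=groups, excluded=tuple(excluded), violations=tuple(violations)
    )


def enumerate_valid_signatures(system: CharacteristicSetSystem) -> list[GroupSignature]:
    """All non-empty set combinations containing no competing pair.

    E.g. with sets S1, S2, S3 where S2 and S3 compete there are five
    valid signatures: {S1}, {S2}, {S3}, {S1,S2}, {S1,S3}.
    """
    if not system.conflict_free:
        raise ConflictError("cannot enumerate signatures of a conflicted system")
    ids = system.set_ids()
    out: list[GroupSignature] = []
    for size in range(1, len(ids) + 1):
        for combo in itertools.combinations(ids, size):
            if any(
                system.are_competing(a, b)
                for a, b in itertools.combinations(combo, 2)
            ):
                continue
            out.append(frozenset(combo))
    return out


def signed_vote(networks: Iterable[Network], scheme: str = "signed") -> Ensemble:
    """Vote an ensemble from a list of networks.

    Under ``signed`` voting (default) activating and inhibiting
    predictions on a gene pair cancel: with n+ networks predicting the
    activating edge and n− the inhibiting one out of N, the net vote is
    v = (n+ − n−)/N and the ensemble assigns weight |v| to the edge with
    the sign of v (no entry when v = 0).  Under ``frequency`` voting each
    signed edge independently gets weight n±/N, so both signs of a pair
    may carry weight.
    """
    if scheme not in VOTING_SCHEMES:
        raise ValueError(f"unknown voting scheme {scheme!r}")
    nets = list(networks)
    if not nets:
        raise ValueError("cannot vote over an empty list of networks")
    n_total = len(nets)

    counts: dict[SignedInteraction, int] = defaultdict(int)
    for net in nets:
        for i in net.interactions:
            counts[i] += 1

    weights: dict[SignedInteraction, float] = {}
    if scheme == "frequency":
        for i, c in counts.items():
            weights[i] = c / n_total
        return Ensemble(weights=weights, n_networks=n_total)

    for pair in {i.pair for i in counts}:
        n_act = counts.get(SignedInteraction(*pair, ACTIVATING), 0)
        n_inh = counts.get(SignedInteraction(*pair, INHIBITING), 0)
        v = (n_act - n_inh) / n_total
        if v > 0:
            weights[SignedInteraction(*pair, ACTIVATING)] = v
        elif v < 0:
            weights[SignedInteraction(*pair, INHIBITING)] = -v
    return Ensemble(weights=weights, n_networks=n_total)


def group_ensembles(
    groups: Iterable[NetworkGroup],
    collection: NetworkCollection,
    scheme: str = "signed",
) -> dict[GroupSignature, Ensemble]:
    """One voted ensemble per non-empty group (empty groups are omitted)."""
    by_id = {n.network_id: n for n in collection}
    out: dict[GroupSignature, Ensemble] = {}
    for group in groups:
        if not group.member_ids:
            continue
        out[group.signature] = signed_vote(
            [by_id[i] for i in group.member_ids], scheme=scheme
        )
    return out


def group_score(group: NetworkGroup, collection: NetworkCollection) -> float:
    """Mean fit score of the group's members (e.g. mean RMSD)."""
    scores = []
    for network_id in group.member_ids:
        score = collection.get(network_id).score
        if score is None:
            raise ValueError(f"network {network_id} carries no score")
        scores.append(score)
    return sum(scores) / len(scores)
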