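"""Synthetic network-ensemble benchmarks with planted structure.

Real collections of this kind come out of non-deterministic
reverse-engineering (e.g. evolutionary optimisation of dynamical models)
where a few hundred high-scoring predictions share a confident backbone
but differ in variable sub-regions.  This module generates the
*resulting* topology distribution directly: a random signed reference, a
high-frequency backbone, planted competing sets of co-occurring edges
realised group-wise, unspecific variable edges, and random add/remove
noise.  The planted ground truth is returned alongside, so extraction
and grouping can be scored exactly.
"""

from __future__ import annotations

import math
from collections.abc import Mapping, Sequence
from dataclasses import dataclass, field

import numpy as np

from .model import (
    ACTIVATING,
    INHIBITING,
    SIGNS,
    Network,
    NetworkCollection,
    SignedInteraction,
)

GroupSignature = frozenset[str]


@dataclass(frozen=True)
class SyntheticSpec:
    """Generator configuration.

    Defaults emulate a mid-sized study: a 10-gene reference with 1–3
    effectors per gene, 500 predicted networks, one pair of competing
    planted 3-edge sets realised in equal proportions, a backbone present
    in 95% of networks, four unspecific variable edges each present
    independently with probability 0.4, and 2% presence-flip noise per
    admissible signed edge (kept below the non-interaction cutoff so
    noise alone cannot fake low-confidence structure).
    """

    n_genes: int = 10
    n_networks: int = 500
    indegree_range: tuple[int, int] = (1, 3)
    backbone_presence: float = 0.95
    planted_sets: Mapping[str, frozenset[SignedInteraction]] | None = None
    planted_competitions: tuple[tuple[str, str], ...] = ()
    set_size: int = 3
    group_proportions: Mapping[GroupSignature, float] | None = None
    n_variable_edges: int = 4
    variable_presence: float = 0.4
    noise_rate: float = 0.02
    score_range: tuple[float, float] = (0.05, 0.15)
    seed: int = 0

    def __post_init__(self) -> None:
        if self.n_networks < 1 or self.n_genes < 2:
            raise ValueError("need at least one network and two genes")
        if not 0.0 <= self.noise_rate < 1.0:
            raise ValueError("noise_rate must be in [0, 1)")
        if not 0.0 <= self.backbone_presence <= 1.0:
            raise ValueError("backbone_presence must be a probability")
        if self.group_proportions is not None:
            total = sum(self.group_proportions.values())
            if not math.isclose(total, 1.0, abs_tol=1e-9):
                raise ValueError(f"group_proportions must sum to 1, got {total}")


@dataclass(frozen=True)
class PlantedTruth:
    """Ground truth written into a synthetic collection before noise."""

    reference: Network
    true_sets: Mapping[str, frozenset[SignedInteraction]]
    true_competitions: frozenset[tuple[str, str]]
    group_assignment: Mapping[str, GroupSignature]


def _genes(n: int) -> list[str]:
    return [f"G{i:02d}" for i in range(1, n + 1)]


def random_reference(
    n_genes: int,
    indegree_range: tuple[int, int] = (1, 3),
    seed: int | None = None,
    rng: np.random.Generator | None = None,
) -> Network:
    """Random signed reference: each gene gets 1–3 distinct non-self effectors.

    The in-degree is drawn uniformly from ``indegree_range``; each edge is
    activating or inhibiting with probability 0.5.
    """
    lo, hi = indegree_range
    if lo < 1 or hi < lo:
        raise ValueError("indegree_range must satisfy 1 <= lo <= hi")
    if n_genes < hi + 1:
        raise ValueError(
            f"cannot draw up to {hi} distinct non-self effectors from {n_genes} genes"
        )
    if rng is None:
        rng = np.random.default_rng(seed)
    genes = _genes(n_genes)
    edges: set[SignedInteraction] = set()
    for target in genes:
        pool = [g for g in genes if g != target]
        k = int(rng.integers(lo, hi + 1))
        effectors = rng.choice(pool, size=k, replace=False)
        for effector in effectors:
            sign = ACTIVATING if rng.random() < 0.5 else INHIBITING
            edges.add(SignedInteraction(str(effector), target, sign))
    return Network(network_id="reference", interactions=frozenset(edges))


def _plant_competing_sets(
    reference: Network,
    set_size: int,
    genes: list[str],
    rng: np.random.Generator,
) -> tuple[dict[str, frozenset[SignedInteraction]], tuple[tuple[str, str], ...]]:
    """Derive a competing pair of planted sets from the reference.

    P1 takes ``set_size`` reference edges with distinct targets; P2 is the
    competing alternative, rewiring each of those targets to a different
    effector (so P2 edges are absent from the reference).  This mirrors
    the situation where two disjoint edge sets can each realise the
    functionality the data demands.
    """
    ref_edges = sorted(reference.interactions)
    by_target: dict[str, list[SignedInteraction]] = {}
    for e in ref_edges:
        by_target.setdefault(e.target, []).append(e)
    targets = sorted(by_target)
    chosen_targets = [str(t) for t in rng.choice(targets, size=set_size, replace=False)]

    members_a: set[SignedInteraction] = set()
    members_b: set[SignedInteraction] = set()
    ref_pairs = {e.pair for e in reference.interactions}
    for target in chosen_targets:
        candidates = by_target[target]
        edge_a = candidates[int(rng.integers(len(candidates)))]
        members_a.add(edge_a)
        pool = [
            g for g in genes if g != target and (g, target) not in ref_pairs
        ]
        effector_b = str(rng.choice(pool))
        sign_b = ACTIVATING if rng.random() < 0.5 else INHIBITING
        members_b.add(SignedInteraction(effector_b, target, sign_b))
    sets = {"P1": frozenset(members_a), "P2": frozenset(members_b)}
    return sets, (("P1", "P2"),)


def generate_collection(spec: SyntheticSpec) -> tuple[NetworkCollection, PlantedTruth]:
    """Generate a collection with planted characteristic-set structure.

    Per network: a group signature is drawn from ``group_proportions``;
    backbone edges appear with probability ``backbone_presence``; all
    members of the signature's planted sets are written in; each variable
    edge appears independently; finally the presence of every admissible
    signed edge is flipped with probability ``noise_rate`` (noise never
    introduces an edge whose opposite sign is already present, so
    networks keep one regulatory role per gene pair).  Fully reproducible
    from ``spec.seed``.
    """
    rng = np.random.default_rng(spec.seed)
    genes = _genes(spec.n_genes)
    reference = random_reference(spec.n_genes, spec.indegree_range, rng=rng)

    if spec.planted_sets is None:
        planted, competitions = _plant_competing_sets(
            reference, spec.set_size, genes, rng
        )
    else:
        planted = {k: frozenset(v) for k, v in spec.planted_sets.items()}
        competitions = spec.planted_competitions
    planted_union = frozenset().union(*planted.values()) if planted else frozenset()

    backbone = sorted(reference.interactions - planted_union)

    if spec.group_proportions is None:
        # default: one single-set signature per planted set, equal mass
        signatures = [frozenset({sid}) for sid in sorted(planted)]
        if not signatures:
            raise ValueError("no planted sets to form group signatures from")
        proportions = [1.0 / len(signatures)] * len(signatures)
    else:
        signatures = sorted(spec.group_proportions, key=lambda s: sorted(s))
        proportions = [spec.group_proportions[s] for s in signatures]

    # unspecific variable edges on gene pairs untouched by reference or sets
    taken_pairs = {e.pair for e in reference.interactions} | {
        e.pair for e in planted_union
    }
    free_pairs = sorted(
        (e, t)
        for e in genes
        for t in genes
        if e != t and (e, t) not in taken_pairs
    )
    idx = rng.choice(len(free_pairs), size=spec.n_variable_edges, replace=False)
    variable_edges = [
        SignedInteraction(*free_pairs[i], ACTIVATING if rng.random() < 0.5 else INHIBITING)
        for i in sorted(int(i) for i in idx)
    ]

    admissible = sorted(
        SignedInteraction(e, t, s)
        for e in genes
        for t in genes
        if e != t
        for s in SIGNS
    )

    networks: list[Network] = []
    assignment: dict[str, GroupSignature] = {}
    sig_idx = rng.choice(len(signatures), size=spec.n_networks, p=proportions)
    width = len(str(spec.n_networks))
    for i in range(spec.n_networks):
        signature = signatures[int(sig_idx[i])]
        edges: set[SignedInteraction] = set()
        mask = rng.random(len(backbone)) < spec.backbone_presence
        edges.update(e for e, keep in zip(backbone, mask) if keep)
        for sid in signature:
            edges.update(planted[sid])
        mask = rng.random(len(variable_edges)) < spec.variable_presence
        edges.update(e for e, keep in zip(variable_edges, mask) if keep)

        flips = rng.random(len(admissible)) < spec.noise_rate
        for e, flip in zip(admissible, flips):
            if not flip:
                continue
            if e in edges:
                edges.discard(e)
            elif e.opposite() not in edges:
                edges.add(e)  # never both signs on one pair

        score = float(rng.uniform(*spec.score_range))
        network_id = f"n{i:0{width}d}"
        networks.append(
            Network(network_id=network_id, interactions=frozenset(edges), score=score)
        )
        assignment[network_id] = signature

    collection = NetworkCollection(
        networks=tuple(networks), gene_universe=frozenset(genes)
    )
    truth = PlantedTruth(
        reference=reference,
        true_sets=planted,
        true_competitions=frozenset(tuple(sorted(p)) for p in competitions),
        group_assignment=assignment,
    )
    return collection, truth


def select_top_fraction(
    collection: NetworkCollection, fraction: float
) -> NetworkCollection:
    """Keep the ceil(fraction·N) networks with the smallest fit score.

    Mirrors the common practice of retaining e.g. the best-fitting 20% of
    predictions before extraction.  Ties at the boundary are broken by
    network_id so the result is deterministic.
    """
    if not 0.0 < fraction <= 1.0:
        raise ValueError("fraction must be in (0, 1]")
    for n in collection:
        if n.score is None:
            raise ValueError(f"network {n.network_id} carries no score")
    k = math.ceil(fraction * len(collection))
    ranked = sorted(collection, key=lambda n: (n.score, n.network_id))
    keep = {n.network_id for n in ranked[:k]}
    return collection.subset(keep)
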