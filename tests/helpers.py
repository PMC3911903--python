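"""Independent brute-force oracles used to cross-check the implementation.

These deliberately avoid the package's internal code paths: frequencies
are recounted by direct looping, AND components by repeated list
merging, and AUPRC by exhaustive threshold enumeration.
"""

from __future__ import annotations

import numpy as np

from charnets.model import (
    ACTIVATING,
    INHIBITING,
    Ensemble,
    Network,
    NetworkCollection,
    SignedInteraction,
)


def make_network(network_id, edges, score=None):
    """Build a Network from (effector, target, sign) triples."""
    return Network(
        network_id=network_id,
        interactions=frozenset(SignedInteraction(*e) for e in edges),
        score=score,
    )


def make_collection(spec: dict, extra_genes=()):
    """Build a collection from {network_id: [(effector, target, sign), ...]}."""
    return NetworkCollection.from_networks(
        [make_network(nid, edges) for nid, edges in spec.items()],
        extra_genes=extra_genes,
    )


def brute_frequency(collection: NetworkCollection, interaction) -> float:
    return sum(1 for n in collection if interaction in n.interactions) / len(collection)


def brute_pair_counts(collection: NetworkCollection, a, b):
    """(n_a, n_b, n_ab, n_a_not_b, n_b_not_a) by direct recount."""
    n_a = n_b = n_ab = n_anb = n_bna = 0
    for net in collection:
        has_a = a in net.interactions
        has_b = b in net.interactions
        n_a += has_a
        n_b += has_b
        n_ab += has_a and has_b
        n_anb += has_a and not has_b
        n_bna += has_b and not has_a
    return n_a, n_b, n_ab, n_anb, n_bna


def brute_and_components(nodes, and_pairs):
    """Partition refinement: repeatedly merge parts sharing an AND pair."""
    parts = [{n} for n in nodes]
    changed = True
    while changed:
        changed = False
        for a, b in and_pairs:
            pa = next(p for p in parts if a in p)
            pb = next(p for p in parts if b in p)
            if pa is not pb:
                parts.remove(pb)
                pa |= pb
                changed = True
    return {frozenset(p) for p in parts if len(p) >= 2}


def brute_auprc(weights: dict, reference: Network) -> float:
    """Exhaustive threshold enumeration with direct set comprehension."""
    positive = {i: w for i, w in weights.items() if w > 0}
    area = 0.0
    prev_recall = 0.0
    for t in sorted(set(positive.values()), reverse=True):
        pred = {i for i, w in positive.items() if w >= t}
        tp = len(pred & reference.interactions)
        precision = tp / len(pred)
        recall = tp / len(reference.interactions)
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return area


def random_small_collection(rng: np.random.Generator):
    """A random collection of ≤ 8 networks over ≤ 10 candidate signed edges."""
    genes = [f"g{i}" for i in range(4)]
    pool = [
        (e, t, s)
        for e in genes
        for t in genes
        if e != t
        for s in (ACTIVATING, INHIBITING)
    ]
    # cap the edge pool at 10 and avoid both signs on one pair
    rng.shuffle(pool)
    chosen, seen_pairs = [], set()
    for e, t, s in pool:
        if (e, t) not in seen_pairs:
            chosen.append((e, t, s))
            seen_pairs.add((e, t))
        if len(chosen) == 10:
            break
    n_networks = int(rng.integers(1, 9))
    spec = {}
    for i in range(n_networks):
        present = [edge for edge in chosen if rng.random() < 0.5]
        spec[f"n{i}"] = present
    return make_collection(spec, extra_genes=genes)
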