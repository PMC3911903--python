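"""Ensemble quality measures and the interaction-validation experiment.

Entropy quantifies how confident an ensemble is overall: each edge
contributes the binary entropy of its frequency, so edges at frequency
0 or 1 contribute nothing and edges near 0.5 contribute up to one bit.
AUPRC (area under the precision-recall curve of weight-ranked edges
against a signed reference network) quantifies predictive quality.
Validating a single interaction experimentally lets one reject all
networks inconsistent with the outcome and re-vote over the survivors.
"""

from __future__ import annotations

import itertools
import math
from collections.abc import Iterable
from dataclasses import dataclass

from .model import (
    SIGNS,
    DegenerateValidationError,
    Ensemble,
    Network,
    NetworkCollection,
    SignedInteraction,
)
from .dependencies import CharacteristicSet
from .grouping import signed_vote


def candidate_universe(
    genes: Iterable[str], allow_self_loops: bool = False
) -> frozenset[SignedInteraction]:
    """All admissible signed edges over a gene set (both signs per ordered pair)."""
    gene_list = sorted(set(genes))
    return frozenset(
        SignedInteraction(e, t, s)
        for e, t in itertools.product(gene_list, repeat=2)
        if (e != t or allow_self_loops)
        for s in SIGNS
    )


def _binary_entropy(f: float, base: float) -> float:
    if f <= 0.0 or f >= 1.0:
        return 0.0
    return -(f * math.log(f, base) + (1.0 - f) * math.log(1.0 - f, base))


def ensemble_entropy(
    ensemble: Ensemble,
    universe: frozenset[SignedInteraction] | None = None,
    base: float = 2.0,
) -> float:
    """Total per-edge binary entropy of the ensemble's frequencies, in bits.

    Edges of the candidate universe absent from the ensemble have
    frequency 0 and contribute nothing, so only the stored weights enter
    the sum; ``universe``, when given, is used to check the ensemble does
    not range outside it.
    """
    if universe is not None:
        stray = set(ensemble.weights) - universe
        if stray:
            raise ValueError(f"ensemble contains edges outside the universe: {sorted(stray)[:3]}")
    return sum(_binary_entropy(w, base) for w in ensemble.weights.values())


def entropy_ratio(
    group_ensembles: Iterable[Ensemble],
    full_ensemble: Ensemble,
    universe: frozenset[SignedInteraction] | None = None,
    base: float = 2.0,
) -> float:
    """Mean of H(group)/H(full) over the group ensembles.

    Values below 1 mean grouping sharpened the frequencies; the ratio is
    independent of the logarithm base.
    """
    h_full = ensemble_entropy(full_ensemble, universe, base)
    if h_full == 0.0:
        raise ValueError("full ensemble has zero entropy; ratio undefined")
    ratios = [ensemble_entropy(g, universe, base) / h_full for g in group_ensembles]
    if not ratios:
        raise ValueError("no group ensembles given")
    return sum(ratios) / len(ratios)


@dataclass(frozen=True)
class PRCurve:
    """Precision-recall points at the distinct weight thresholds, and their area."""

    points: tuple[tuple[float, float], ...]  # (recall, precision)
    auprc: float


def auprc(
    ensemble: Ensemble,
    reference: Network,
    universe: frozenset[SignedInteraction] | None = None,
) -> PRCurve:
    """Step-integrated area under the precision-recall curve.

    Edges are ranked by descending weight; at each distinct positive
    weight t the prediction set is every edge with weight ≥ t (ties share
    one threshold).  A true positive is an exact (effector, target, sign)
    match with the reference.  The area is Σ (R_k − R_{k−1})·P_k over
    successive thresholds with R_0 = 0 — rectangular integration, no
    interpolation, hence bit-reproducible.
    """
    if not reference.interactions:
        raise ValueError("reference network is empty")
    if universe is not None:
        if not reference.interactions <= universe:
            raise ValueError("reference contains edges outside the candidate universe")
        stray = set(ensemble.weights) - universe
        if stray:
            raise ValueError("ensemble contains edges outside the candidate universe")

    positive = [(w, i) for i, w in ensemble.weights.items() if w > 0.0]
    thresholds = sorted({w for w, _ in positive}, reverse=True)
    n_ref = len(reference.interactions)

    points: list[tuple[float, float]] = []
    area = 0.0
    prev_recall = 0.0
    n_pred = 0
    tp = 0
    ranked = sorted(positive, key=lambda wi: -wi[0])
    pos = 0
    for t in thresholds:
        while pos < len(ranked) and ranked[pos][0] >= t:
            n_pred += 1
            if ranked[pos][1] in reference.interactions:
                tp += 1
            pos += 1
        precision = tp / n_pred
        recall = tp / n_ref
        points.append((recall, precision))
        area += (recall - prev_recall) * precision
        prev_recall = recall
    return PRCurve(points=tuple(points), auprc=area)


def charset_precision(cset: CharacteristicSet, reference: Network) -> float:
    """Fraction of the set's member interactions found in the reference."""
    return len(cset.members & reference.interactions) / len(cset.members)


def validate_interaction(
    collection: NetworkCollection,
    reference: Network,
    tested: SignedInteraction,
    scheme: str = "signed",
) -> tuple[NetworkCollection, Ensemble]:
    """Simulate experimental validation of one interaction.

    If the tested interaction is present in the reference, every network
    lacking it is rejected; otherwise every network containing it is
    rejected.  The surviving networks are re-voted into a new ensemble.
    """
    if tested in reference.interactions:
        keep = [n for n in collection if tested in n.interactions]
    else:
        keep = [n for n in collection if tested not in n.interactions]
    if not keep:
        raise DegenerateValidationError(
            f"validating {tested} rejected every network in the collection"
        )
    retained = collection.subset(n.network_id for n in keep)
    return retained, signed_vote(list(retained), scheme=scheme)
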