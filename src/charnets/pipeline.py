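"""End-to-end wiring of the extraction steps.

Convenience layer used by the command-line interface and the test
fixtures; every step is also available individually from its module.
"""

from __future__ import annotations

from dataclasses import dataclass

from .model import CutoffConfig, Ensemble, NetworkCollection
from .frequencies import (
    FrequencyTable,
    InteractionClassification,
    PairKey,
    PairStats,
    classify_interactions,
    interaction_frequencies,
    pair_stats,
)
from .dependencies import (
    CharacteristicSetSystem,
    PairRelation,
    build_characteristic_sets,
    pairwise_relations,
)
from .grouping import (
    GroupingResult,
    GroupSignature,
    group_ensembles,
    group_networks,
    signed_vote,
)


@dataclass(frozen=True)
class ExtractionResult:
    """Everything the three extraction steps produce for one collection."""

    cutoffs: CutoffConfig
    frequencies: FrequencyTable
    classification: InteractionClassification
    pair_stats: dict[PairKey, PairStats]
    relations: list[PairRelation]
    system: CharacteristicSetSystem


def extract_characteristic_sets(
    collection: NetworkCollection,
    cutoffs: CutoffConfig | None = None,
    conjunction: str = "min",
) -> ExtractionResult:
    """Run frequency classification, dependency scoring and set assembly."""
    cutoffs = cutoffs or CutoffConfig()
    freqs = interaction_frequencies(collection)
    classification = classify_interactions(freqs, cutoffs)
    stats = pair_stats(collection, classification)
    relations = pairwise_relations(stats, cutoffs, conjunction)
    system = build_characteristic_sets(relations, collection)
    return ExtractionResult(
        cutoffs=cutoffs,
        frequencies=freqs,
        classification=classification,
        pair_stats=stats,
        relations=relations,
        system=system,
    )


def vote_groups(
    collection: NetworkCollection,
    result: ExtractionResult,
    *,
    scheme: str = "signed",
    keep_violations: bool = False,
    force: bool = False,
) -> tuple[GroupingResult, dict[GroupSignature, Ensemble], Ensemble]:
    """Group the collection and vote one ensemble per group plus the full one."""
    grouping = group_networks(
        collection, result.system, keep_violations=keep_violations, force=force
    )
    per_group = group_ensembles(grouping.groups, collection, scheme=scheme)
    full = signed_vote(list(collection), scheme=scheme)
    return grouping, per_group, full
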