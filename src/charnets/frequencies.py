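"""Interaction frequencies and confidence tiers (extraction step 1).

Every signed edge observed in a collection is classified by its relative
frequency across *all* networks: high-confidence interaction (present in
nearly all), high-confidence non-interaction (nearly none), or
low-confidence (intermediate).  Only low-confidence edges carry grouping
information, so pairwise co-occurrence statistics are computed for them
alone.
"""

from __future__ import annotations

import enum
from collections import Counter
from collections.abc import Mapping
from dataclasses import dataclass

from .model import CutoffConfig, NetworkCollection, SignedInteraction

PairKey = tuple[SignedInteraction, SignedInteraction]


class Tier(str, enum.Enum):
    HIGH = "HIGH"  # high-confidence interaction
    NON = "NON"  # high-confidence non-interaction
    LOW = "LOW"  # low-confidence: eligible for dependency analysis

    def __str__(self) -> str:  # pragma: no cover - cosmetic
        return self.value


@dataclass(frozen=True)
class FrequencyTable:
    """Relative frequency of each observed interaction in a collection."""

    counts: Mapping[SignedInteraction, int]
    n_networks: int

    def frequency(self, interaction: SignedInteraction) -> float:
        return self.counts.get(interaction, 0) / self.n_networks

    @property
    def freq(self) -> dict[SignedInteraction, float]:
        return {i: c / self.n_networks for i, c in self.counts.items()}

    def __iter__(self):
        return iter(self.counts)


@dataclass(frozen=True)
class InteractionClassification:
    """Total tier assignment over the observed interactions."""

    tier: Mapping[SignedInteraction, Tier]

    def low_interactions(self) -> list[SignedInteraction]:
        """Low-confidence interactions in deterministic (sorted) order."""
        return sorted(i for i, t in self.tier.items() if t is Tier.LOW)

    def of_tier(self, tier: Tier) -> list[SignedInteraction]:
        return sorted(i for i, t in self.tier.items() if t is tier)


@dataclass(frozen=True)
class PairStats:
    """Marginal, joint and exclusive frequencies of a low-confidence pair.

    All five frequencies are over the same collection, so
    ``f_a_not_b == f_a - f_ab`` and ``f_b_not_a == f_b - f_ab`` exactly.
    """

    f_a: float
    f_b: float
    f_ab: float
    f_a_not_b: float
    f_b_not_a: float

    @classmethod
    def from_counts(cls, n_a: int, n_b: int, n_ab: int, n_networks: int) -> "PairStats":
        if n_ab > min(n_a, n_b):
            raise ValueError("joint count exceeds a marginal count")
        n = n_networks
        return cls(
            f_a=n_a / n,
            f_b=n_b / n,
            f_ab=n_ab / n,
            f_a_not_b=(n_a - n_ab) / n,
            f_b_not_a=(n_b - n_ab) / n,
        )

    def swapped(self) -> "PairStats":
        return PairStats(self.f_b, self.f_a, self.f_ab, self.f_b_not_a, self.f_a_not_b)


def interaction_frequencies(collection: NetworkCollection) -> FrequencyTable:
    """Count, for every observed signed edge, the fraction of networks containing it.

    Edges never observed are simply absent from the table (frequency 0).
    """
    counts: Counter[SignedInteraction] = Counter()
    for network in collection:
        counts.update(network.interactions)
    return FrequencyTable(counts=dict(counts), n_networks=len(collection))


def classify_interactions(
    freqs: FrequencyTable, cutoffs: CutoffConfig
) -> InteractionClassification:
    """Assign each observed interaction its confidence tier.

    Cutoff comparisons are strict: frequencies exactly at a cutoff stay
    low-confidence, which keeps borderline edges available for set
    extraction.
    """
    tier: dict[SignedInteraction, Tier] = {}
    for interaction, count in freqs.counts.items():
        f = count / freqs.n_networks
        if f > cutoffs.hc_cutoff:
            tier[interaction] = Tier.HIGH
        elif f < cutoffs.nc_cutoff:
            tier[interaction] = Tier.NON
        else:
            tier[interaction] = Tier.LOW
    return InteractionClassification(tier=tier)


def pair_stats(
    collection: NetworkCollection, classification: InteractionClassification
) -> dict[PairKey, PairStats]:
    """Joint-occurrence statistics for every unordered pair of LOW edges.

    All pairs with positive marginals are retained, including pairs that
    never co-occur — those are exactly the candidates for mutual
    exclusion.  Keys are (a, b) with a < b in the interaction ordering.
    """
    low = classification.low_interactions()
    membership: dict[SignedInteraction, set[int]] = {i: set() for i in low}
    for idx, network in enumerate(collection):
        for i in low:
            if i in network.interactions:
                membership[i].add(idx)

    n = len(collection)
    out: dict[PairKey, PairStats] = {}
    for ai in range(len(low)):
        a = low[ai]
        nets_a = membership[a]
        if not nets_a:
            continue
        for bi in range(ai + 1, len(low)):
            b = low[bi]
            nets_b = membership[b]
            if not nets_b:
                continue
            out[(a, b)] = PairStats.from_counts(
                n_a=len(nets_a), n_b=len(nets_b), n_ab=len(nets_a & nets_b), n_networks=n
            )
    return out
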