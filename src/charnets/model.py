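"""Core domain types for ensembles of predicted gene regulatory networks.

A predicted network is a set of signed directed edges (effector gene,
target gene, regulation polarity) over a common gene universe.  A
collection holds many such predictions of the same system, typically the
high-scoring output of a non-deterministic reverse-engineering run; an
ensemble maps each signed edge to a confidence weight obtained by voting
over a collection.
"""

from __future__ import annotations

import math
from collections.abc import Iterable, Iterator, Mapping
from dataclasses import dataclass, field

ACTIVATING = "+"
INHIBITING = "-"
SIGNS = (ACTIVATING, INHIBITING)

#: accepted sign spellings on input; "+"/"-" is the canonical written form
SIGN_ALIASES: dict[str, str] = {
    "+": ACTIVATING,
    "-": INHIBITING,
    "activating": ACTIVATING,
    "inhibiting": INHIBITING,
    "1": ACTIVATING,
    "-1": INHIBITING,
}


class CharnetsError(Exception):
    """Base class for errors raised by this package."""


class ParseError(CharnetsError):
    """A malformed input file (carries the offending line number)."""


class UndefinedScoreError(CharnetsError):
    """A dependency score was requested for a pair with a zero marginal."""


class ConflictError(CharnetsError):
    """Automatic grouping refused because the set system has conflicts."""


class DegenerateValidationError(CharnetsError):
    """Interaction validation left no network to vote over."""


def parse_sign(token: str) -> str:
    """Normalise a sign token, accepting the read aliases."""
    try:
        return SIGN_ALIASES[token.strip().lower()]
    except KeyError:
        raise ParseError(f"unknown sign token {token!r}") from None


@dataclass(frozen=True, order=True)
class SignedInteraction:
    """A directed regulatory edge: effector gene acts on target gene.

    Two interactions are equal only if effector, target *and* sign agree;
    an activating and an inhibiting edge on the same gene pair are distinct
    interactions throughout.
    """

    effector: str
    target: str
    sign: str

    def __post_init__(self) -> None:
        if self.sign not in SIGNS:
            raise ValueError(f"sign must be one of {SIGNS}, got {self.sign!r}")

    @property
    def pair(self) -> tuple[str, str]:
        return (self.effector, self.target)

    def opposite(self) -> "SignedInteraction":
        other = INHIBITING if self.sign == ACTIVATING else ACTIVATING
        return SignedInteraction(self.effector, self.target, other)

    def __str__(self) -> str:
        return f"{self.effector}->{self.target}({self.sign})"


@dataclass(frozen=True)
class Network:
    """One predicted network: an edge set plus an optional fit score.

    ``score`` is a goodness-of-fit to the underlying data where *lower is
    better* (e.g. an RMSD between simulated and reference trajectories).
    """

    network_id: str
    interactions: frozenset[SignedInteraction]
    score: float | None = None

    def __post_init__(self) -> None:
        if self.score is not None and self.score < 0:
            raise ValueError("network score must be non-negative")

    def __contains__(self, interaction: SignedInteraction) -> bool:
        return interaction in self.interactions

    def genes(self) -> frozenset[str]:
        out: set[str] = set()
        for i in self.interactions:
            out.add(i.effector)
            out.add(i.target)
        return frozenset(out)

    def double_signed_pairs(self) -> frozenset[tuple[str, str]]:
        """Gene pairs carrying both an activating and an inhibiting edge."""
        return frozenset(
            i.pair for i in self.interactions if i.opposite() in self.interactions
        )


@dataclass(frozen=True)
class NetworkCollection:
    """An ordered list of predicted networks over a common gene universe."""

    networks: tuple[Network, ...]
    gene_universe: frozenset[str]

    def __post_init__(self) -> None:
        if not self.networks:
            raise ValueError("a collection must contain at least one network")
        ids = [n.network_id for n in self.networks]
        if len(set(ids)) != len(ids):
            raise ValueError("network_id values must be unique")
        seen = set().union(*(n.genes() for n in self.networks))
        if not seen <= self.gene_universe:
            raise ValueError(
                f"genes {sorted(seen - self.gene_universe)} missing from gene_universe"
            )

    @classmethod
    def from_networks(
        cls, networks: Iterable[Network], extra_genes: Iterable[str] = ()
    ) -> "NetworkCollection":
        nets = tuple(networks)
        genes = set(extra_genes)
        for n in nets:
            genes |= n.genes()
        return cls(networks=nets, gene_universe=frozenset(genes))

    def __len__(self) -> int:
        return len(self.networks)

    def __iter__(self) -> Iterator[Network]:
        return iter(self.networks)

    def get(self, network_id: str) -> Network:
        for n in self.networks:
            if n.network_id == network_id:
                return n
        raise KeyError(network_id)

    def subset(self, network_ids: Iterable[str]) -> "NetworkCollection":
        """Restrict to the given networks, preserving order and universe."""
        wanted = set(network_ids)
        kept = tuple(n for n in self.networks if n.network_id in wanted)
        if not kept:
            raise ValueError("subset would be empty")
        return NetworkCollection(networks=kept, gene_universe=self.gene_universe)


@dataclass(frozen=True)
class Ensemble:
    """A voted consensus: one confidence weight per signed interaction.

    Interactions absent from ``weights`` have weight 0.  ``n_networks``
    records how many networks were voted over.
    """

    weights: Mapping[SignedInteraction, float]
    n_networks: int

    def __post_init__(self) -> None:
        if self.n_networks < 1:
            raise ValueError("n_networks must be positive")
        for i, w in self.weights.items():
            if not 0.0 <= w <= 1.0 or math.isnan(w):
                raise ValueError(f"weight of {i} out of [0,1]: {w}")

    def weight(self, interaction: SignedInteraction) -> float:
        return self.weights.get(interaction, 0.0)

    def __len__(self) -> int:
        return len(self.weights)


@dataclass(frozen=True)
class CutoffConfig:
    """Cutoffs steering extraction.

    hc_cutoff
        an edge with relative frequency strictly above this is a
        high-confidence interaction (default 0.8).
    nc_cutoff
        strictly below this it is a high-confidence non-interaction
        (default 0.1); in between it is low-confidence.
    joint_cutoff
        minimum evidence frequency a dependency relation must exceed
        (joint frequency for co-occurrence, exclusive frequencies for
        mutual exclusion; default 0.1).
    score_cutoff
        threshold the AND/EX score must exceed (default 0.7); must be
        above 0.5 so the two relations can never both qualify.
    """

    hc_cutoff: float = 0.8
    nc_cutoff: float = 0.1
    joint_cutoff: float = 0.1
    score_cutoff: float = 0.7

    def __post_init__(self) -> None:
        if not 0.0 < self.hc_cutoff <= 1.0:
            raise ValueError("hc_cutoff must be in (0, 1]")
        if not 0.0 <= self.nc_cutoff < 1.0:
            raise ValueError("nc_cutoff must be in [0, 1)")
        if self.nc_cutoff >= self.hc_cutoff:
            raise ValueError("nc_cutoff must be below hc_cutoff")
        if not 0.0 <= self.joint_cutoff <= 1.0:
            raise ValueError("joint_cutoff must be in [0, 1]")
        if not 0.5 < self.score_cutoff <= 1.0:
            raise ValueError("score_cutoff must be in (0.5, 1]")
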