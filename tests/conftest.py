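from __future__ import annotations

from dataclasses import dataclass

import pytest

from charnets import (
    CutoffConfig,
    SyntheticSpec,
    extract_characteristic_sets,
    generate_collection,
    vote_groups,
)
from helpers import make_collection


@pytest.fixture(scope="session")
def default_cutoffs() -> CutoffConfig:
    return CutoffConfig()


@pytest.fixture()
def two_set_collection():
    """8-network toy collection with two competing 2-edge sets and a backbone.

    Networks n0–n3 realise set {a1, a2}; n4–n7 realise set {b1, b2};
    all carry the backbone edge hb.  Frequencies: backbone 1.0, each set
    member 0.5, joint within a set 0.5, joint across sets 0.
    """
    hb = ("X", "Y", "+")
    a1, a2 = ("A", "Y", "+"), ("B", "Y", "-")
    b1, b2 = ("C", "Y", "+"), ("D", "Y", "-")
    spec = {}
    for i in range(4):
        spec[f"n{i}"] = [hb, a1, a2]
    for i in range(4, 8):
        spec[f"n{i}"] = [hb, b1, b2]
    return make_collection(spec)


@dataclass(frozen=True)
class SyntheticRun:
    """One generated collection with its planted truth and pipeline output."""

    seed: int
    collection: object
    truth: object
    result: object
    grouping: object
    group_ensembles: dict
    full_ensemble: object


def _run_seed(seed: int) -> SyntheticRun:
    collection, truth = generate_collection(SyntheticSpec(seed=seed))
    result = extract_characteristic_sets(collection)
    grouping, per_group, full = vote_groups(collection, result)
    return SyntheticRun(
        seed=seed,
        collection=collection,
        truth=truth,
        result=result,
        grouping=grouping,
        group_ensembles=per_group,
        full_ensemble=full,
    )


@pytest.fixture(scope="session")
def synthetic_runs() -> list[SyntheticRun]:
    """50 independently seeded default synthetic collections, fully processed.

    Shared across the stochastic property tests: generation and
    extraction dominate their cost, the per-test measurements are cheap.
    """
    return [_run_seed(seed) for seed in range(50)]
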