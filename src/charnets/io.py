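"""Reading and writing collections, references, ensembles and reports.

File dialect: UTF-8 tab-separated values, comment lines start with ``#``.
A collection file has columns [network_id, effector, target, sign] with an
optional fifth per-network score column; a reference file drops the
network_id column; an ensemble file has [effector, target, sign, weight].
Signs are written as ``+``/``-``; ``activating``/``inhibiting`` and
``1``/``-1`` are accepted on read.  An optional directive line
``#genes: A,B,C`` declares genes that never appear in any edge, which
matters for candidate-universe denominators in evaluation.
"""

from __future__ import annotations

import json
import warnings
from pathlib import Path
from typing import TextIO

from .model import (
    Ensemble,
    Network,
    NetworkCollection,
    ParseError,
    SignedInteraction,
    parse_sign,
)
from .frequencies import FrequencyTable, InteractionClassification
from .dependencies import CharacteristicSetSystem, PairRelation
from .grouping import GroupingResult, signature_name


def _edge_json(i: SignedInteraction) -> list[str]:
    return [i.effector, i.target, i.sign]


def _iter_rows(handle: TextIO):
    """Yield (line_number, fields, raw_line) for data rows; capture directives."""
    declared_genes: set[str] = set()
    rows = []
    for lineno, raw in enumerate(handle, start=1):
        line = raw.rstrip("\n")
        stripped = line.strip()
        if not stripped:
            continue
        if stripped.startswith("#"):
            body = stripped.lstrip("#").strip()
            if body.lower().startswith("genes:"):
                declared_genes.update(
                    g.strip() for g in body[len("genes:"):].split(",") if g.strip()
                )
            continue
        rows.append((lineno, line.split("\t")))
    return rows, declared_genes


def _check_edge(
    effector: str,
    target: str,
    sign_token: str,
    lineno: int,
    allow_self_loops: bool,
) -> SignedInteraction:
    if not effector or not target:
        raise ParseError(f"line {lineno}: empty gene identifier")
    if effector == target and not allow_self_loops:
        raise ParseError(
            f"line {lineno}: self-loop {effector}->{target} (pass allow_self_loops to permit)"
        )
    try:
        sign = parse_sign(sign_token)
    except ParseError as exc:
        raise ParseError(f"line {lineno}: {exc}") from None
    return SignedInteraction(effector, target, sign)


def read_network_collection(
    path: str | Path,
    *,
    allow_self_loops: bool = False,
    strict_signs: bool = True,
) -> NetworkCollection:
    """Parse a collection TSV into a NetworkCollection.

    Duplicate identical rows are deduplicated with a warning.  In strict
    mode (default) a network carrying both signs on one gene pair is
    rejected, since the dynamical models these collections come from
    admit a single regulatory role per edge; lenient mode keeps both as
    distinct interactions.
    """
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        rows, declared_genes = _iter_rows(handle)
    if not rows:
        raise ParseError(f"{path}: no data rows")

    edges: dict[str, set[SignedInteraction]] = {}
    scores: dict[str, float] = {}
    order: list[str] = []
    for lineno, fields in rows:
        if len(fields) not in (4, 5):
            raise ParseError(
                f"line {lineno}: expected 4 or 5 tab-separated columns, got {len(fields)}"
            )
        network_id, effector, target, sign_token = (f.strip() for f in fields[:4])
        if not network_id:
            raise ParseError(f"line {lineno}: empty network_id")
        interaction = _check_edge(effector, target, sign_token, lineno, allow_self_loops)
        if network_id not in edges:
            edges[network_id] = set()
            order.append(network_id)
        if interaction in edges[network_id]:
            warnings.warn(
                f"{path}:{lineno}: duplicate row for {network_id} {interaction}; deduplicated",
                stacklevel=2,
            )
        if strict_signs and interaction.opposite() in edges[network_id]:
            raise ParseError(
                f"line {lineno}: both signs on {effector}->{target} in network "
                f"{network_id} (strict mode)"
            )
        edges[network_id].add(interaction)
        if len(fields) == 5:
            try:
                score = float(fields[4])
            except ValueError:
                raise ParseError(f"line {lineno}: malformed score {fields[4]!r}") from None
            if network_id in scores and scores[network_id] != score:
                raise ParseError(
                    f"line {lineno}: inconsistent score for network {network_id}"
                )
            scores[network_id] = score

    networks = tuple(
        Network(
            network_id=nid,
            interactions=frozenset(edges[nid]),
            score=scores.get(nid),
        )
        for nid in order
    )
    return NetworkCollection.from_networks(networks, extra_genes=declared_genes)


def read_reference(
    path: str | Path, *, allow_self_loops: bool = False, strict_signs: bool = True
) -> Network:
    """Parse a single-network reference TSV ([effector, target, sign])."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        rows, _ = _iter_rows(handle)
    if not rows:
        raise ParseError(f"{path}: no data rows")
    edges: set[SignedInteraction] = set()
    for lineno, fields in rows:
        if len(fields) != 3:
            raise ParseError(
                f"line {lineno}: expected 3 tab-separated columns, got {len(fields)}"
            )
        interaction = _check_edge(*(f.strip() for f in fields), lineno, allow_self_loops)
        if interaction in edges:
            warnings.warn(f"{path}:{lineno}: duplicate reference row; deduplicated", stacklevel=2)
        if strict_signs and interaction.opposite() in edges:
            raise ParseError(
                f"line {lineno}: both signs on {interaction.effector}->{interaction.target} "
                "in reference (strict mode)"
            )
        edges.add(interaction)
    return Network(network_id="reference", interactions=frozenset(edges))


def write_network_collection(collection: NetworkCollection, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# network_id\teffector\ttarget\tsign\tscore\n")
        handle.write("#genes: " + ",".join(sorted(collection.gene_universe)) + "\n")
        for network in collection:
            for i in sorted(network.interactions):
                row = [network.network_id, i.effector, i.target, i.sign]
                if network.score is not None:
                    row.append(repr(network.score))
                handle.write("\t".join(row) + "\n")


def write_reference(reference: Network, path: str | Path) -> None:
    path = Path(path)
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# effector\ttarget\tsign\n")
        for i in sorted(reference.interactions):
            handle.write(f"{i.effector}\t{i.target}\t{i.sign}\n")


def write_ensemble(ensemble: Ensemble, path: str | Path) -> None:
    """Write an ensemble TSV sorted by descending weight, then lexicographically."""
    path = Path(path)
    ordered = sorted(
        ensemble.weights.items(), key=lambda kv: (-kv[1], kv[0])
    )
    with path.open("w", encoding="utf-8") as handle:
        handle.write("# effector\ttarget\tsign\tweight\n")
        for i, w in ordered:
            handle.write(f"{i.effector}\t{i.target}\t{i.sign}\t{w:.6f}\n")


def read_ensemble(path: str | Path, n_networks: int = 1) -> Ensemble:
    """Parse an ensemble TSV ([effector, target, sign, weight])."""
    path = Path(path)
    with path.open(encoding="utf-8") as handle:
        rows, _ = _iter_rows(handle)
    weights: dict[SignedInteraction, float] = {}
    for lineno, fields in rows:
        if len(fields) != 4:
            raise ParseError(
                f"line {lineno}: expected 4 tab-separated columns, got {len(fields)}"
            )
        effector, target, sign_token, weight_token = (f.strip() for f in fields)
        interaction = _check_edge(effector, target, sign_token, lineno, True)
        try:
            weight = float(weight_token)
        except ValueError:
            raise ParseError(f"line {lineno}: malformed weight {weight_token!r}") from None
        weights[interaction] = weight
    return Ensemble(weights=weights, n_networks=n_networks)


def extraction_report(
    system: CharacteristicSetSystem,
    grouping: GroupingResult | None = None,
    *,
    cutoffs=None,
    frequencies: FrequencyTable | None = None,
    classification: InteractionClassification | None = None,
    relations: list[PairRelation] | None = None,
) -> dict:
    """Assemble the machine-readable extraction report as a JSON-able dict."""
    report: dict = {
        "cutoffs": (
            {
                "hc_cutoff": cutoffs.hc_cutoff,
                "nc_cutoff": cutoffs.nc_cutoff,
                "joint_cutoff": cutoffs.joint_cutoff,
                "score_cutoff": cutoffs.score_cutoff,
            }
            if cutoffs is not None
            else None
        ),
        "interaction_classes": None,
        "characteristic_sets": [],
        "competitions": sorted(list(p) for p in system.competitions),
        "conflicts": sorted(list(p) for p in system.conflicts),
        "manual_resolution_required": not system.conflict_free,
        "groups": {},
        "excluded_networks": [],
    }
    if classification is not None:
        from .frequencies import Tier

        report["interaction_classes"] = {
            tier.value: [
                _edge_json(i)
                + ([frequencies.frequency(i)] if frequencies is not None else [])
                for i in classification.of_tier(tier)
            ]
            for tier in (Tier.HIGH, Tier.LOW, Tier.NON)
        }

    by_member: dict[SignedInteraction, str] = {}
    for cset in system.sets:
        for m in cset.members:
            by_member[m] = cset.set_id
    pair_scores: dict[str, list[dict]] = {s.set_id: [] for s in system.sets}
    if relations is not None:
        for rel in relations:
            a, b = rel.pair
            sid_a, sid_b = by_member.get(a), by_member.get(b)
            if sid_a is not None and sid_a == sid_b:
                pair_scores[sid_a].append(
                    {
                        "pair": [_edge_json(a), _edge_json(b)],
                        "and_score": rel.and_score,
                        "ex_score": rel.ex_score,
                        "relation": rel.relation.value,
                    }
                )
    for cset in system.sets:
        report["characteristic_sets"].append(
            {
                "id": cset.set_id,
                "members": [_edge_json(m) for m in cset.sorted_members()],
                "support": cset.support,
                "pairwise_scores": pair_scores[cset.set_id],
            }
        )

    if grouping is not None:
        report["groups"] = {
            signature_name(g.signature): list(g.member_ids) for g in grouping.groups
        }
        report["excluded_networks"] = list(grouping.excluded)
        report["violations"] = list(grouping.violations)
    return report


def write_extraction_report(
    system: CharacteristicSetSystem,
    grouping: GroupingResult | None,
    path: str | Path,
    **context,
) -> None:
    path = Path(path)
    report = extraction_report(system, grouping, **context)
    with path.open("w", encoding="utf-8") as handle:
        json.dump(report, handle, indent=2, sort_keys=False)
        handle.write("\n")
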