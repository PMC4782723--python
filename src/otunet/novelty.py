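"""Novelty classification of environmental amplicons within OTUs.

OTUs are first classified by composition: *mixed* (environmental and
reference members), *ref_only*, or *env_only*. Inside OTUs that carry an
internal edge topology (network and swarm approaches), every environmental
amplicon is then assigned the shortest-path distance — in edges — to its
nearest reference member, via a multi-source breadth-first search started
from all reference members at once.

Environmental amplicons at distance 1 sit within one clustering step of a
reference and are *covered* by the reference set; finite distances >= 2
mark *novel variants* reachable only through intermediate environmental
amplicons; infinite distance (no reference in the OTU) marks *novel*
diversity. Greedy OTUs carry no topology, so only the composition rule
applies there: env_only members are novel, everything else covered.

A best-hit identity against the reference set (above a floor, 0.70 by
default) is recorded for amplicons in env_only OTUs — optionally for all —
so that the misclassification audit can test whether "novel" amplicons are
in fact highly similar to some reference.
"""

from __future__ import annotations

import math
from collections import deque
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

from .amplicon_io import Amplicon, ENVIRONMENTAL, REFERENCE
from .alignment import DEFAULT_SCORING, ScoringParams, best_hit
from .clustering import GREEDY, OTU, ClusteringResult

__all__ = [
    "MIXED",
    "REF_ONLY",
    "ENV_ONLY",
    "COVERED",
    "NOVEL_VARIANT",
    "NOVEL",
    "NoveltyRecord",
    "classify_otus",
    "shortest_path_to_reference",
    "classify_novelty",
    "novelty_report",
    "write_novelty_table",
]

MIXED = "mixed"
REF_ONLY = "ref_only"
ENV_ONLY = "env_only"

COVERED = "covered"
NOVEL_VARIANT = "novel_variant"
NOVEL = "novel"

INF = math.inf


@dataclass(frozen=True, slots=True)
class NoveltyRecord:
    """Per-environmental-amplicon novelty assessment.

    ``path_distance`` is a positive integer, ``math.inf`` (no reference
    reachable) or ``None`` for approaches without internal topology
    (greedy), where ``novelty_class`` derives from the OTU class alone.
    """

    amplicon_id: str
    otu_id: str
    otu_class: str
    path_distance: float | int | None
    best_hit_identity: float | None
    novelty_class: str


def classify_otus(
    result: ClusteringResult, amplicons: Sequence[Amplicon]
) -> dict[str, str]:
    """Map each otu_id to mixed / ref_only / env_only by member origins."""
    origin = {a.id: a.origin for a in amplicons}
    out: dict[str, str] = {}
    for otu in result.otus:
        has_env = has_ref = False
        for m in otu.member_ids:
            try:
                o = origin[m]
            except KeyError:
                raise KeyError(
                    f"OTU {otu.otu_id}: member {m!r} not found among amplicons"
                ) from None
            has_env |= o == ENVIRONMENTAL
            has_ref |= o == REFERENCE
        out[otu.otu_id] = MIXED if (has_env and has_ref) else (
            REF_ONLY if has_ref else ENV_ONLY
        )
    return out


def shortest_path_to_reference(
    otu: OTU, origins: Mapping[str, str]
) -> dict[str, float | int]:
    """Hop count from each environmental member to its nearest reference.

    Runs a breadth-first search over the OTU's internal edges seeded with
    all reference members simultaneously. Environmental members that no
    reference can reach map to ``math.inf``.
    """
    if otu.approach == GREEDY:
        raise ValueError(
            "greedy OTUs carry no internal topology; shortest paths are undefined"
        )
    if not otu.internal_edges and len(otu) > 1:
        raise ValueError(
            f"OTU {otu.otu_id} has {len(otu)} members but no internal edges; "
            "this approach carries no topology"
        )
    adj: dict[str, list[str]] = {m: [] for m in otu.member_ids}
    for a, b in otu.internal_edges:
        adj[a].append(b)
        adj[b].append(a)
    dist: dict[str, int] = {}
    queue: deque[str] = deque()
    for m in otu.member_ids:
        if origins[m] == REFERENCE:
            dist[m] = 0
            queue.append(m)
    while queue:
        node = queue.popleft()
        for nb in adj[node]:
            if nb not in dist:
                dist[nb] = dist[node] + 1
                queue.append(nb)
    return {
        m: dist.get(m, INF)
        for m in otu.member_ids
        if origins[m] == ENVIRONMENTAL
    }


def classify_novelty(otu_class: str, path_distance: float | int) -> str:
    """Distance 1 -> covered; finite >= 2 -> novel_variant; infinite -> novel."""
    if otu_class == ENV_ONLY and path_distance != INF:
        raise ValueError("env_only OTUs must have infinite reference distance")
    if path_distance == INF:
        return NOVEL
    if path_distance == 1:
        return COVERED
    if path_distance >= 2:
        return NOVEL_VARIANT
    raise ValueError(f"invalid path distance {path_distance!r}")


def novelty_report(
    result: ClusteringResult,
    amplicons: Sequence[Amplicon],
    references: Sequence[Amplicon],
    floor: float = 0.70,
    best_hits_for: str = "env_only",
    scoring: ScoringParams = DEFAULT_SCORING,
) -> list[NoveltyRecord]:
    """One :class:`NoveltyRecord` per retained environmental amplicon.

    *best_hits_for* is ``"env_only"`` (default: audit only the amplicons
    claimed as novel) or ``"all"``. For the greedy approach path distances
    are not applicable (``None``) and novelty derives from the OTU class:
    env_only members are novel, all others covered.
    """
    if not references:
        raise ValueError("novelty_report: reference list is empty")
    if best_hits_for not in ("env_only", "all"):
        raise ValueError("best_hits_for must be 'env_only' or 'all'")
    by_id = {a.id: a for a in amplicons}
    origins = {a.id: a.origin for a in amplicons}
    otu_classes = classify_otus(result, amplicons)
    records: list[NoveltyRecord] = []
    for otu in result.otus:
        oclass = otu_classes[otu.otu_id]
        if result.approach == GREEDY:
            distances = {
                m: None
                for m in otu.member_ids
                if origins[m] == ENVIRONMENTAL
            }
        else:
            distances = shortest_path_to_reference(otu, origins)
        for m in sorted(distances):
            dist = distances[m]
            if result.approach == GREEDY:
                nclass = NOVEL if oclass == ENV_ONLY else COVERED
            else:
                nclass = classify_novelty(oclass, dist)
            ident: float | None = None
            if best_hits_for == "all" or oclass == ENV_ONLY:
                hit = best_hit(by_id[m], references, floor=floor, scoring=scoring)
                ident = None if hit is None else hit[1]
            records.append(
                NoveltyRecord(
                    amplicon_id=m,
                    otu_id=otu.otu_id,
                    otu_class=oclass,
                    path_distance=dist,
                    best_hit_identity=ident,
                    novelty_class=nclass,
                )
            )
    records.sort(key=lambda r: r.amplicon_id)
    return records


def _fmt_distance(d: float | int | None) -> str:
    if d is None:
        return "NA"
    if d == INF:
        return "inf"
    return str(int(d))


def write_novelty_table(
    records: Sequence[NoveltyRecord], approach: str, path: str | Path
) -> None:
    """Write the novelty TSV with ``inf`` and ``NA`` sentinels."""
    with open(path, "w") as fh:
        fh.write(
            "approach\tamplicon_id\totu_id\totu_class\tpath_distance\t"
            "best_hit_identity\tnovelty_class\n"
        )
        for r in records:
            ident = "NA" if r.best_hit_identity is None else f"{r.best_hit_identity:.6f}"
            fh.write(
                f"{approach}\t{r.amplicon_id}\t{r.otu_id}\t{r.otu_class}\t"
                f"{_fmt_distance(r.path_distance)}\t{ident}\t{r.novelty_class}\n"
            )
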