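"""Three de-novo OTU clustering approaches and the small-OTU filter.

The three approaches differ in how far an OTU may extend from its seed:

* **greedy** — centroid clustering with a global identity threshold t.
  Amplicons are processed by decreasing abundance; each joins the existing
  centroid of maximal identity if that identity is >= t, otherwise it
  founds a new OTU. Every member is within t of its centroid (the "radius
  cap"), so clusters can never grow beyond 2*(1-t) diameter — the source
  of over-splitting relative to the network approach.
* **network** — connected components of the all-vs-all similarity graph at
  threshold t. Components grow transitively, so their radius is unbounded.
* **swarm** — iterative single linkage with a small *local* threshold d
  (maximum edit distance between directly linked amplicons), abundance-
  aware chain breaking, and optional "fastidious" grafting of low-abundance
  OTUs onto heavy ones within 2d.

Network and swarm OTUs retain their internal edge topology, which the
novelty analysis later exploits with shortest-path searches; greedy OTUs
have no internal topology beyond the star around their centroid and are
therefore excluded from path-based analyses.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass, field, replace
from pathlib import Path
from typing import Mapping, Sequence

import networkx as nx

from .amplicon_io import Amplicon, AmpliconError
from .alignment import (
    DEFAULT_SCORING,
    ScoringParams,
    _identity_band,
    edit_distance,
    pairwise_identity,
)

__all__ = [
    "OTU",
    "ClusteringResult",
    "greedy_centroid_cluster",
    "network_components",
    "swarm_cluster",
    "filter_small_otus",
    "write_membership",
]

GREEDY = "greedy"
NETWORK = "network"
SWARM = "swarm"
APPROACHES = (GREEDY, NETWORK, SWARM)


@dataclass(frozen=True, slots=True)
class OTU:
    """A cluster of amplicon ids produced by one approach.

    ``internal_edges`` (network and swarm only) holds unordered member id
    pairs as sorted tuples and makes the member set connected; greedy OTUs
    carry no topology and an empty edge set.
    """

    otu_id: str
    approach: str
    member_ids: frozenset[str]
    seed_id: str | None = None
    internal_edges: frozenset[tuple[str, str]] = frozenset()

    def __post_init__(self) -> None:
        if not self.member_ids:
            raise ValueError(f"OTU {self.otu_id}: empty member set")
        if self.seed_id is not None and self.seed_id not in self.member_ids:
            raise ValueError(f"OTU {self.otu_id}: seed not among members")
        for a, b in self.internal_edges:
            if a not in self.member_ids or b not in self.member_ids:
                raise ValueError(f"OTU {self.otu_id}: edge ({a},{b}) leaves the OTU")

    def __len__(self) -> int:
        return len(self.member_ids)


@dataclass(frozen=True, slots=True)
class ClusteringResult:
    """OTUs of one approach plus the exact parameters used."""

    approach: str
    parameters: Mapping[str, object]
    otus: tuple[OTU, ...]
    removed_ids: frozenset[str] = frozenset()

    def retained_ids(self) -> frozenset[str]:
        return frozenset(m for otu in self.otus for m in otu.member_ids)

    def membership(self) -> dict[str, str]:
        """Map amplicon id -> otu id (amplicons removed by filtering absent)."""
        out: dict[str, str] = {}
        for otu in self.otus:
            for m in otu.member_ids:
                if m in out:
                    raise ValueError(f"amplicon {m} appears in two OTUs")
                out[m] = otu.otu_id
        return out


def _abundance_order(amplicons: Sequence[Amplicon]) -> list[Amplicon]:
    return sorted(amplicons, key=lambda a: (-a.abundance, a.id))


def _check_unique_ids(amplicons: Sequence[Amplicon]) -> None:
    ids = [a.id for a in amplicons]
    if len(set(ids)) != len(ids):
        raise AmpliconError("duplicate amplicon ids in input")


def _edge(a: str, b: str) -> tuple[str, str]:
    return (a, b) if a < b else (b, a)


def greedy_centroid_cluster(
    amplicons: Sequence[Amplicon],
    t: float,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> ClusteringResult:
    """Greedy centroid clustering at global identity threshold *t*.

    Amplicons are processed in decreasing-abundance order (ties by id).
    Each amplicon joins the centroid with the highest identity when that
    identity is >= t (ties resolved in favour of the earliest-created
    centroid); otherwise it becomes the centroid of a new OTU. Centroids
    are consequently pairwise below t.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold t must be in (0, 1], got {t}")
    _check_unique_ids(amplicons)
    ordered = _abundance_order(amplicons)
    centroids: list[Amplicon] = []
    members: list[list[str]] = []
    for amp in ordered:
        best_idx = -1
        best_ident = -1.0
        for idx, cen in enumerate(centroids):
            band = _identity_band(len(amp), len(cen), t)
            if edit_distance(amp.sequence, cen.sequence, max_d=band) is None:
                continue
            ident = pairwise_identity(amp.sequence, cen.sequence, scoring)
            if ident >= t and ident > best_ident:
                best_idx, best_ident = idx, ident
        if best_idx >= 0:
            members[best_idx].append(amp.id)
        else:
            centroids.append(amp)
            members.append([amp.id])
    otus = tuple(
        OTU(
            otu_id=f"greedy_{i:05d}",
            approach=GREEDY,
            member_ids=frozenset(ids),
            seed_id=centroids[i].id,
        )
        for i, ids in enumerate(members)
    )
    return ClusteringResult(
        approach=GREEDY, parameters={"t": t}, otus=otus
    )


def network_components(graph: nx.Graph) -> ClusteringResult:
    """One OTU per connected component of a similarity graph.

    Isolated nodes become singleton OTUs (typically removed later by
    :func:`filter_small_otus`). Components are numbered by their
    lexicographically smallest member id, making the result independent of
    node insertion order.
    """
    components = sorted(nx.connected_components(graph), key=min)
    otus = []
    for i, comp in enumerate(components):
        sub = graph.subgraph(comp)
        otus.append(
            OTU(
                otu_id=f"network_{i:05d}",
                approach=NETWORK,
                member_ids=frozenset(comp),
                internal_edges=frozenset(_edge(u, v) for u, v in sub.edges()),
            )
        )
    return ClusteringResult(
        approach=NETWORK,
        parameters={"t": graph.graph.get("threshold")},
        otus=tuple(otus),
    )


def _distance_neighbors(
    amplicons: Sequence[Amplicon], d: int
) -> dict[str, set[str]]:
    """All unordered pairs at edit distance <= d, as an adjacency map."""
    nbrs: dict[str, set[str]] = {a.id: set() for a in amplicons}
    for x, y in itertools.combinations(amplicons, 2):
        if abs(len(x) - len(y)) > d:
            continue
        if edit_distance(x.sequence, y.sequence, max_d=d) is not None:
            nbrs[x.id].add(y.id)
            nbrs[y.id].add(x.id)
    return nbrs


def swarm_cluster(
    amplicons: Sequence[Amplicon],
    d: int = 1,
    breaking: bool = True,
    fastidious: bool = True,
    boundary: int = 3,
) -> ClusteringResult:
    """Iterative single-linkage clustering with local threshold *d*.

    Repeatedly seeds an OTU with the most abundant pooled amplicon and
    grows it in generations: every amplicon added in one generation (a
    *subseed*) captures the pooled amplicons within edit distance d. With
    *breaking* on, a subseed may only capture amplicons of abundance less
    than or equal to its own — abundance must be non-increasing along
    capture chains — except for the seed's own first-generation captures,
    which are unrestricted. This interrupts single-linkage chains between
    adjacent abundance peaks.

    With *fastidious* on, each light OTU (total read abundance < *boundary*)
    is grafted afterwards onto the heavy OTU (total abundance >= *boundary*)
    minimising the cross-OTU member edit distance, provided that minimum is
    <= 2d; ties prefer the heaviest OTU, then id order. The minimal-distance
    pair is recorded as an internal edge.

    Internal edges comprise the full distance-<= d graph restricted to the
    members plus graft edges, so the recorded topology is independent of
    capture order.
    """
    if d < 1:
        raise ValueError(f"d must be >= 1, got {d}")
    if boundary < 1:
        raise ValueError(f"boundary must be >= 1, got {boundary}")
    _check_unique_ids(amplicons)
    ordered = _abundance_order(amplicons)
    by_id = {a.id: a for a in ordered}
    rank = {a.id: i for i, a in enumerate(ordered)}
    nbrs = _distance_neighbors(ordered, d)

    pooled = set(by_id)
    clusters: list[list[str]] = []
    for amp in ordered:
        if amp.id not in pooled:
            continue
        pooled.discard(amp.id)
        members = [amp.id]
        generation = [amp.id]
        first = True
        while generation:
            nxt: list[str] = []
            for sub in sorted(generation, key=rank.get):
                sub_ab = by_id[sub].abundance
                for cand in sorted(nbrs[sub], key=rank.get):
                    if cand not in pooled:
                        continue
                    if breaking and not first and by_id[cand].abundance > sub_ab:
                        continue
                    pooled.discard(cand)
                    members.append(cand)
                    nxt.append(cand)
            generation = nxt
            first = False
        clusters.append(members)

    graft_edges: dict[int, set[tuple[str, str]]] = {i: set() for i in range(len(clusters))}
    merged_into: dict[int, int] = {}
    if fastidious:
        totals = [sum(by_id[m].abundance for m in c) for c in clusters]
        heavy = [i for i, tot in enumerate(totals) if tot >= boundary]
        light = [i for i, tot in enumerate(totals) if tot < boundary]
        for li in sorted(light, key=lambda i: (-totals[i], i)):
            best: tuple[int, tuple[str, str]] | None = None
            best_key: tuple[int, int, int] | None = None
            for hi in heavy:
                for lm in clusters[li]:
                    for hm in clusters[hi]:
                        dist = edit_distance(
                            by_id[lm].sequence, by_id[hm].sequence, max_d=2 * d
                        )
                        if dist is None:
                            continue
                        key = (dist, -totals[hi], hi)
                        pair = _edge(lm, hm)
                        if best_key is None or key < best_key or (
                            key == best_key and pair < best[1]
                        ):
                            best_key, best = key, (hi, pair)
            if best is not None and best_key[0] <= 2 * d:
                hi, pair = best
                merged_into[li] = hi
                clusters[hi] = clusters[hi] + clusters[li]
                graft_edges[hi].add(pair)

    otus = []
    counter = 0
    for i, members in enumerate(clusters):
        if i in merged_into:
            continue
        member_set = frozenset(members)
        edges = set(graft_edges[i])
        mem_sorted = sorted(member_set)
        for a, b in itertools.combinations(mem_sorted, 2):
            if b in nbrs[a]:
                edges.add(_edge(a, b))
        otus.append(
            OTU(
                otu_id=f"swarm_{counter:05d}",
                approach=SWARM,
                member_ids=member_set,
                seed_id=members[0],
                internal_edges=frozenset(edges),
            )
        )
        counter += 1
    return ClusteringResult(
        approach=SWARM,
        parameters={
            "d": d,
            "breaking": breaking,
            "fastidious": fastidious,
            "boundary": boundary,
        },
        otus=tuple(otus),
    )


def filter_small_otus(
    result: ClusteringResult, min_amplicons: int = 3
) -> ClusteringResult:
    """Drop OTUs with fewer than *min_amplicons* members.

    The default of 3 removes singleton and doubleton OTUs, the usual
    guard against spurious diversity from residual sequencing noise.
    Removed amplicon ids are recorded on the result.
    """
    if min_amplicons < 1:
        raise ValueError(f"min_amplicons must be >= 1, got {min_amplicons}")
    kept = tuple(o for o in result.otus if len(o) >= min_amplicons)
    removed = frozenset(
        m for o in result.otus if len(o) < min_amplicons for m in o.member_ids
    )
    params = dict(result.parameters)
    params["min_otu_size"] = min_amplicons
    return ClusteringResult(
        approach=result.approach,
        parameters=params,
        otus=kept,
        removed_ids=result.removed_ids | removed,
    )


def write_membership(
    result: ClusteringResult,
    amplicons: Sequence[Amplicon],
    path: str | Path,
) -> None:
    """Write membership TSV: otu_id, approach, member_id, abundance, origin, is_seed."""
    by_id = {a.id: a for a in amplicons}
    with open(path, "w") as fh:
        fh.write("otu_id\tapproach\tmember_id\tabundance\torigin\tis_seed\n")
        for otu in result.otus:
            for m in sorted(otu.member_ids):
                amp = by_id[m]
                seed = "1" if m == otu.seed_id else "0"
                fh.write(
                    f"{otu.otu_id}\t{result.approach}\t{m}\t"
                    f"{amp.abundance}\t{amp.origin}\t{seed}\n"
                )
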