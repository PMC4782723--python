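"""Global pairwise alignment, identity, edit distance and similarity graphs.

Identity between two amplicons is defined over an optimal end-to-end
(global) alignment as ``matches / columns`` where *columns* is the total
alignment length, terminal gap columns included — the strictest of the
common identity conventions. All downstream thresholds (the 97% clustering
threshold, the 70% best-hit floor) refer to this definition.

The alignment itself is a standard Needleman–Wunsch/Gotoh global alignment
with affine gap costs, delegated to :class:`Bio.Align.PairwiseAligner`.
A gap of length ``k`` costs ``|open| + (k - 1) * |extend|``. Edit
(Levenshtein) distances are computed with edlib, optionally banded, and
also serve as an exact prefilter when building all-vs-all similarity
graphs: identity >= t implies edit distance <= (1 - t) * (len_a + len_b),
so pairs failing that band can be skipped without aligning them.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from functools import lru_cache
from pathlib import Path
from typing import Iterable, Sequence

import edlib
import networkx as nx
from Bio import Align

from .amplicon_io import Amplicon, AmpliconError

__all__ = [
    "ScoringParams",
    "DEFAULT_SCORING",
    "PairwiseAlignment",
    "global_align",
    "identity",
    "pairwise_identity",
    "edit_distance",
    "build_similarity_graph",
    "best_hit",
    "write_edge_list",
]


@dataclass(frozen=True, slots=True)
class ScoringParams:
    """Affine-gap scoring for global DNA alignment.

    Defaults mimic the usearch/vsearch family (match +2, mismatch -4,
    gap open -20, gap extension -2). *gap_open* is the score of the first
    base of a gap; each further base adds *gap_extend*, so a length-k gap
    scores ``gap_open + (k - 1) * gap_extend``. Terminal gaps are scored
    the same as internal ones.
    """

    match: float = 2.0
    mismatch: float = -4.0
    gap_open: float = -20.0
    gap_extend: float = -2.0


DEFAULT_SCORING = ScoringParams()


@dataclass(frozen=True, slots=True)
class PairwiseAlignment:
    """A global alignment of two sequences with per-column bookkeeping."""

    aligned_a: str
    aligned_b: str
    score: float
    columns: int
    matches: int

    def __post_init__(self) -> None:
        if len(self.aligned_a) != len(self.aligned_b) or len(self.aligned_a) != self.columns:
            raise ValueError("aligned rows must both have length == columns")


@lru_cache(maxsize=8)
def _make_aligner(scoring: ScoringParams) -> Align.PairwiseAligner:
    aligner = Align.PairwiseAligner()
    aligner.mode = "global"
    aligner.match_score = scoring.match
    aligner.mismatch_score = scoring.mismatch
    aligner.open_gap_score = scoring.gap_open
    aligner.extend_gap_score = scoring.gap_extend
    return aligner


def global_align(
    a: str, b: str, scoring: ScoringParams = DEFAULT_SCORING
) -> PairwiseAlignment:
    """Optimal global alignment of two DNA sequences.

    Among co-optimal alignments the aligner's first traceback is taken,
    which is deterministic for a given pair, so identities are reproducible.
    """
    if not a or not b:
        raise ValueError("global_align: sequences must be non-empty")
    aligner = _make_aligner(scoring)
    aln = aligner.align(a, b)[0]
    row_a, row_b = aln[0], aln[1]
    matches = sum(x == y for x, y in zip(row_a, row_b))
    return PairwiseAlignment(
        aligned_a=row_a,
        aligned_b=row_b,
        score=float(aln.score),
        columns=aln.length,
        matches=matches,
    )


def identity(alignment: PairwiseAlignment) -> float:
    """All-columns identity: matches / total columns, terminal gaps counted."""
    if alignment.columns == 0:
        raise ValueError("identity: alignment has zero columns")
    return alignment.matches / alignment.columns


def pairwise_identity(
    a: str, b: str, scoring: ScoringParams = DEFAULT_SCORING
) -> float:
    """Convenience: all-columns identity of the optimal global alignment."""
    return identity(global_align(a, b, scoring))


def edit_distance(a: str, b: str, max_d: int | None = None) -> int | None:
    """Levenshtein distance between two sequences.

    With *max_d* given, a banded computation is used and ``None`` is
    returned whenever the true distance exceeds *max_d*.
    """
    if not a or not b:
        raise ValueError("edit_distance: sequences must be non-empty")
    k = -1 if max_d is None else int(max_d)
    d = edlib.align(a, b, mode="NW", task="distance", k=k)["editDistance"]
    return None if d < 0 else d


def _identity_band(len_a: int, len_b: int, t: float) -> int:
    # identity >= t forces columns - matches <= (1-t)*columns and the
    # non-match columns form an edit script, so dist <= (1-t)*(len_a+len_b).
    return int((1.0 - t) * (len_a + len_b))


def build_similarity_graph(
    amplicons: Sequence[Amplicon],
    t: float,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> nx.Graph:
    """All-vs-all similarity graph: edges are pairs with identity >= t.

    Every amplicon becomes a node (isolated nodes included); each edge
    carries the all-columns identity as attribute ``identity``. An exact
    banded edit-distance prefilter skips pairs that cannot reach t, which
    keeps the O(n^2) construction tractable at moderate n.
    """
    if not 0.0 < t <= 1.0:
        raise ValueError(f"threshold t must be in (0, 1], got {t}")
    ids = [a.id for a in amplicons]
    if len(set(ids)) != len(ids):
        raise AmpliconError("build_similarity_graph: duplicate amplicon ids")
    graph = nx.Graph(threshold=t)
    for amp in amplicons:
        graph.add_node(amp.id, abundance=amp.abundance, origin=amp.origin)
    for x, y in itertools.combinations(amplicons, 2):
        band = _identity_band(len(x), len(y), t)
        if edit_distance(x.sequence, y.sequence, max_d=band) is None:
            continue
        ident = pairwise_identity(x.sequence, y.sequence, scoring)
        if ident >= t:
            graph.add_edge(x.id, y.id, identity=ident)
    return graph


def best_hit(
    query: Amplicon,
    references: Sequence[Amplicon],
    floor: float = 0.70,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[str, float] | None:
    """Reference with the highest global identity to *query*.

    Returns ``(reference_id, identity)`` if the maximum identity is >=
    *floor*, else ``None``. Ties go to the lexicographically smallest
    reference id (references are scanned in id order and only a strictly
    greater identity displaces the incumbent).
    """
    if not references:
        raise ValueError("best_hit: reference list is empty")
    if not 0.0 <= floor <= 1.0:
        raise ValueError(f"best_hit: floor must be in [0, 1], got {floor}")
    best_id: str | None = None
    best_ident = -1.0
    for ref in sorted(references, key=lambda r: r.id):
        ident = pairwise_identity(query.sequence, ref.sequence, scoring)
        if ident > best_ident:
            best_id, best_ident = ref.id, ident
    assert best_id is not None
    if best_ident >= floor:
        return best_id, best_ident
    return None


def write_edge_list(graph: nx.Graph, path: str | Path) -> None:
    """Write edges as ``id_a<TAB>id_b<TAB>identity`` (6 decimals, a < b)."""
    lines = []
    for u, v, data in graph.edges(data=True):
        a, b = sorted((u, v))
        lines.append(f"{a}\t{b}\t{data['identity']:.6f}")
    with open(path, "w") as fh:
        fh.write("id_a\tid_b\tidentity\n")
        for line in sorted(lines):
            fh.write(line + "\n")
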