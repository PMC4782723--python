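"""Independent brute-force oracles used to validate the implementation.

Everything here is deliberately written against the mathematical
definitions (full dynamic programming matrices, exhaustive enumeration,
matrix transitive closure) with no imports from the package's alignment or
clustering internals, so agreement is evidence and not tautology.
"""

from __future__ import annotations

import itertools
from functools import lru_cache

import numpy as np


def dp_edit_distance(a: str, b: str) -> int:
    """Plain full-matrix Levenshtein distance."""
    m, n = len(a), len(b)
    prev = list(range(n + 1))
    for i in range(1, m + 1):
        cur = [i] + [0] * n
        for j in range(1, n + 1):
            cur[j] = min(
                prev[j] + 1,
                cur[j - 1] + 1,
                prev[j - 1] + (a[i - 1] != b[j - 1]),
            )
        prev = cur
    return prev[n]


def score_gapped(row_a: str, row_b: str, match, mismatch, gap_open, gap_extend) -> float:
    """Score a gapped alignment; a gap run of length k costs open + (k-1)*extend."""
    score = 0.0
    prev_gap = None  # which row held a gap in the previous column
    for x, y in zip(row_a, row_b):
        if x == "-" and y == "-":
            raise ValueError("column with gaps in both rows")
        if x == "-":
            score += gap_extend if prev_gap == "a" else gap_open
            prev_gap = "a"
        elif y == "-":
            score += gap_extend if prev_gap == "b" else gap_open
            prev_gap = "b"
        else:
            score += match if x == y else mismatch
            prev_gap = None
    return score


def enumerate_alignments(a: str, b: str):
    """Yield every global alignment of a and b as (row_a, row_b)."""
    if not a and not b:
        yield "", ""
        return
    if a and b:
        for ra, rb in enumerate_alignments(a[1:], b[1:]):
            yield a[0] + ra, b[0] + rb
    if a:
        for ra, rb in enumerate_alignments(a[1:], b):
            yield a[0] + ra, "-" + rb
    if b:
        for ra, rb in enumerate_alignments(a, b[1:]):
            yield "-" + ra, b[0] + rb


def exhaustive_best_score(a, b, match, mismatch, gap_open, gap_extend) -> float:
    """Max score over every enumerated global alignment (tiny inputs only)."""
    return max(
        score_gapped(ra, rb, match, mismatch, gap_open, gap_extend)
        for ra, rb in enumerate_alignments(a, b)
    )


def gotoh_best_score(a, b, match, mismatch, gap_open, gap_extend) -> float:
    """Memoized affine-gap recursion; independent of the package aligner."""

    @lru_cache(maxsize=None)
    def f(i: int, j: int, state: int) -> float:
        # state: 0 = previous column aligned, 1 = gap in b, 2 = gap in a
        if i == len(a) and j == len(b):
            return 0.0
        best = -np.inf
        if i < len(a) and j < len(b):
            s = match if a[i] == b[j] else mismatch
            best = max(best, s + f(i + 1, j + 1, 0))
        if i < len(a):
            g = gap_extend if state == 1 else gap_open
            best = max(best, g + f(i + 1, j, 1))
        if j < len(b):
            g = gap_extend if state == 2 else gap_open
            best = max(best, g + f(i, j + 1, 2))
        return best

    out = f(0, 0, 0)
    f.cache_clear()
    return out


def closure_components(n_nodes: int, edges) -> list[frozenset[int]]:
    """Connected components via boolean transitive closure of the adjacency matrix."""
    reach = np.eye(n_nodes, dtype=bool)
    for u, v in edges:
        reach[u, v] = reach[v, u] = True
    while True:
        nxt = reach | (reach @ reach)
        if (nxt == reach).all():
            break
        reach = nxt
    seen: set[int] = set()
    comps = []
    for i in range(n_nodes):
        if i in seen:
            continue
        comp = frozenset(np.flatnonzero(reach[i]).tolist())
        seen |= comp
        comps.append(comp)
    return comps


def floyd_warshall_ref_distances(n_nodes: int, edges, ref_nodes) -> dict[int, float]:
    """Per-node minimum hop count to any reference node, via Floyd-Warshall."""
    from scipy.sparse.csgraph import floyd_warshall
    from scipy.sparse import csr_matrix

    rows, cols = [], []
    for u, v in edges:
        rows += [u, v]
        cols += [v, u]
    mat = csr_matrix(
        (np.ones(len(rows)), (rows, cols)), shape=(n_nodes, n_nodes)
    )
    dist = floyd_warshall(mat, unweighted=True, directed=False)
    refs = sorted(ref_nodes)
    out = {}
    for i in range(n_nodes):
        out[i] = min((dist[i, r] for r in refs), default=np.inf)
    return out


def mutate(seq: str, n_events: int, rng: np.random.Generator) -> str:
    """n random single-base substitutions/indels (for test data generation)."""
    bases = "ACGT"
    for _ in range(n_events):
        kind = rng.integers(3)
        pos = int(rng.integers(len(seq)))
        if kind == 0 and len(seq) > 10:
            seq = seq[:pos] + seq[pos + 1 :]
        elif kind == 1:
            seq = seq[:pos] + bases[rng.integers(4)] + seq[pos:]
        else:
            repl = [c for c in bases if c != seq[pos]]
            seq = seq[:pos] + repl[rng.integers(3)] + seq[pos + 1 :]
    return seq


def random_dna(rng: np.random.Generator, length: int) -> str:
    return "".join("ACGT"[i] for i in rng.integers(0, 4, size=length))
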