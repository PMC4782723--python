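"""Cross-approach comparison of clustering results.

Summarises, for each approach, how OTUs and amplicons distribute over the
three composition classes; intersects the three approaches' novel-amplicon
sets into the seven Venn regions; audits each novel set for amplicons whose
best-hit identity to the references is at or above the clustering threshold
(misclassifications — amplicons called novel despite a near-identical
reference); and tabulates the divergence profile of novel amplicons.

For the network approach the audit count is structurally zero: an edge
exists exactly when identity >= t, so any environmental amplicon with a
>= t best hit is adjacent to a reference and its component can never be
env_only. Greedy and swarm carry no such guarantee — the greedy radius cap
and swarm's small local threshold both strand high-identity amplicons in
env_only OTUs.
"""

from __future__ import annotations

import itertools
from dataclasses import dataclass
from pathlib import Path
from typing import Mapping, Sequence

import pandas as pd

from .amplicon_io import Amplicon, ENVIRONMENTAL, REFERENCE
from .alignment import DEFAULT_SCORING, ScoringParams, best_hit
from .clustering import ClusteringResult
from .novelty import (
    ENV_ONLY,
    MIXED,
    REF_ONLY,
    NoveltyRecord,
    classify_otus,
)

__all__ = [
    "ComparisonSummary",
    "novel_amplicon_sets",
    "overlap_counts",
    "misclassification_audit",
    "summarize",
    "divergence_profile",
    "write_summary",
    "write_venn_counts",
    "plot_divergence",
    "plot_path_histogram",
]

#: Venn region keys, as frozensets of approach names.
VENN_REGIONS = (
    ("a",), ("b",), ("c",), ("a", "b"), ("a", "c"), ("b", "c"), ("a", "b", "c"),
)


@dataclass(frozen=True)
class ComparisonSummary:
    """Per-approach composition counts plus Venn regions and audit counts.

    ``per_approach`` maps approach -> dict with keys: total_otus,
    mixed_otus, mixed_env_amplicons, mixed_ref_amplicons, ref_only_otus,
    ref_only_ref_amplicons, env_only_otus, env_only_env_amplicons.
    ``venn`` maps a frozenset of approach names to a region count.
    """

    per_approach: Mapping[str, Mapping[str, int]]
    venn: Mapping[frozenset[str], int]
    misclassified: Mapping[str, int]


def novel_amplicon_sets(
    reports: Mapping[str, Sequence[NoveltyRecord]],
) -> dict[str, set[str]]:
    """Environmental amplicons in env_only OTUs, per approach."""
    return {
        approach: {r.amplicon_id for r in records if r.otu_class == ENV_ONLY}
        for approach, records in reports.items()
    }


def overlap_counts(
    sets: Mapping[str, set[str]],
) -> dict[frozenset[str], int]:
    """The seven Venn region cardinalities of three labelled sets.

    Keys are frozensets of approach names; the value for ``{a}`` is the
    count of elements in set *a* only, for ``{a, b}`` in *a* and *b* but
    not the third, and so on. Regions partition the union of the sets.
    """
    if len(sets) != 3:
        raise ValueError(f"overlap_counts expects exactly 3 sets, got {len(sets)}")
    names = sorted(sets)
    universe = set().union(*sets.values())
    counts: dict[frozenset[str], int] = {}
    for r in range(1, 4):
        for combo in itertools.combinations(names, r):
            counts[frozenset(combo)] = 0
    for el in universe:
        pattern = frozenset(n for n in names if el in sets[n])
        counts[pattern] += 1
    return counts


def misclassification_audit(
    novel_set: set[str],
    amplicons: Sequence[Amplicon],
    references: Sequence[Amplicon],
    t: float,
    strict: bool = False,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> tuple[int, list[str]]:
    """Count novel-set amplicons whose best-hit identity reaches *t*.

    These are amplicons classified as novel despite being as similar to a
    reference as the clustering threshold demands — misclassifications by
    the definition of coverage. With *strict* the comparison is ``> t``
    instead of the default ``>= t``.
    """
    if not references:
        raise ValueError("misclassification_audit: reference list is empty")
    by_id = {a.id: a for a in amplicons}
    flagged: list[str] = []
    for amp_id in sorted(novel_set):
        hit = best_hit(by_id[amp_id], references, floor=0.0, scoring=scoring)
        ident = hit[1]
        if (ident > t) if strict else (ident >= t):
            flagged.append(amp_id)
    return len(flagged), flagged


def summarize(
    results: Mapping[str, ClusteringResult],
    reports: Mapping[str, Sequence[NoveltyRecord]],
    amplicons: Sequence[Amplicon],
    references: Sequence[Amplicon] | None = None,
    t: float | None = None,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> ComparisonSummary:
    """Cross-approach summary of OTU and amplicon composition counts.

    When *references* and *t* are given, the misclassification audit is
    run on each approach's novel set; otherwise audit counts are omitted.
    All approaches must have clustered the same amplicon universe.
    """
    universes = {
        ap: res.retained_ids() | res.removed_ids for ap, res in results.items()
    }
    if len({frozenset(u) for u in universes.values()}) > 1:
        raise ValueError("summarize: approaches were run on different amplicon sets")

    origin = {a.id: a.origin for a in amplicons}
    per_approach: dict[str, dict[str, int]] = {}
    for ap, res in results.items():
        classes = classify_otus(res, amplicons)
        counts = {
            "total_otus": len(res.otus),
            "mixed_otus": 0,
            "mixed_env_amplicons": 0,
            "mixed_ref_amplicons": 0,
            "ref_only_otus": 0,
            "ref_only_ref_amplicons": 0,
            "env_only_otus": 0,
            "env_only_env_amplicons": 0,
        }
        for otu in res.otus:
            n_env = sum(1 for m in otu.member_ids if origin[m] == ENVIRONMENTAL)
            n_ref = len(otu) - n_env
            cls = classes[otu.otu_id]
            if cls == MIXED:
                counts["mixed_otus"] += 1
                counts["mixed_env_amplicons"] += n_env
                counts["mixed_ref_amplicons"] += n_ref
            elif cls == REF_ONLY:
                counts["ref_only_otus"] += 1
                counts["ref_only_ref_amplicons"] += n_ref
            else:
                counts["env_only_otus"] += 1
                counts["env_only_env_amplicons"] += n_env
        per_approach[ap] = counts

    sets = novel_amplicon_sets(reports)
    venn = overlap_counts(sets) if len(sets) == 3 else {}
    misclassified: dict[str, int] = {}
    if references is not None and t is not None:
        for ap, novel in sets.items():
            misclassified[ap], _ = misclassification_audit(
                novel, amplicons, references, t, scoring=scoring
            )
    return ComparisonSummary(
        per_approach=per_approach, venn=venn, misclassified=misclassified
    )


def divergence_profile(
    novel_set: set[str],
    amplicons: Sequence[Amplicon],
    references: Sequence[Amplicon],
    floor: float = 0.70,
    scoring: ScoringParams = DEFAULT_SCORING,
) -> pd.DataFrame:
    """Best-hit divergence table for a set of novel amplicons.

    One row per amplicon: id, abundance, best-hit identity (NaN when the
    best hit falls below *floor*, flagged in the ``below_floor`` column).
    """
    by_id = {a.id: a for a in amplicons}
    rows = []
    for amp_id in sorted(novel_set):
        hit = best_hit(by_id[amp_id], references, floor=floor, scoring=scoring)
        rows.append(
            {
                "amplicon_id": amp_id,
                "abundance": by_id[amp_id].abundance,
                "best_hit_identity": float("nan") if hit is None else hit[1],
                "below_floor": hit is None,
            }
        )
    return pd.DataFrame(
        rows,
        columns=["amplicon_id", "abundance", "best_hit_identity", "below_floor"],
    )


def write_summary(summary: ComparisonSummary, path: str | Path) -> None:
    """Serialise the per-approach composition counts as a TSV table."""
    approaches = sorted(summary.per_approach)
    rows = [
        "total_otus",
        "mixed_otus",
        "mixed_env_amplicons",
        "mixed_ref_amplicons",
        "ref_only_otus",
        "ref_only_ref_amplicons",
        "env_only_otus",
        "env_only_env_amplicons",
    ]
    with open(path, "w") as fh:
        fh.write("metric\t" + "\t".join(approaches) + "\n")
        for row in rows:
            vals = "\t".join(str(summary.per_approach[ap][row]) for ap in approaches)
            fh.write(f"{row}\t{vals}\n")
        if summary.misclassified:
            vals = "\t".join(
                str(summary.misclassified.get(ap, "")) for ap in approaches
            )
            fh.write(f"misclassified_novel\t{vals}\n")


def write_venn_counts(
    venn: Mapping[frozenset[str], int], path: str | Path
) -> None:
    """Write Venn region counts as ``region<TAB>count`` (region = a&b&c syntax)."""
    with open(path, "w") as fh:
        fh.write("region\tcount\n")
        for region in sorted(venn, key=lambda r: (len(r), sorted(r))):
            fh.write("&".join(sorted(region)) + f"\t{venn[region]}\n")


def plot_divergence(profile: pd.DataFrame, path: str | Path, title: str = "") -> None:
    """Scatter of best-hit identity against (log) abundance for novel amplicons."""
    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    fig, ax = plt.subplots(figsize=(6, 4))
    sub = profile.dropna(subset=["best_hit_identity"])
    ax.scatter(sub["abundance"], 100 * sub["best_hit_identity"], s=12, alpha=0.6)
    ax.set_xscale("log")
    ax.set_xlabel("amplicon abundance")
    ax.set_ylabel("best-hit identity to references (%)")
    ax.axhline(97, color="red", lw=0.8, ls="--")
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)


def plot_path_histogram(
    distances: Sequence[float | int], path: str | Path, title: str = ""
) -> None:
    """Histogram of shortest-path distances, with an explicit infinity bar."""
    import math

    import matplotlib

    matplotlib.use("Agg")
    import matplotlib.pyplot as plt

    finite = [int(d) for d in distances if d != math.inf]
    n_inf = sum(1 for d in distances if d == math.inf)
    top = max(finite, default=1)
    fig, ax = plt.subplots(figsize=(6, 4))
    bins = list(range(1, top + 2))
    counts = [finite.count(b) for b in bins[:-1]]
    ax.bar(bins[:-1], counts, color="steelblue", label="finite")
    ax.bar([top + 1], [n_inf], color="grey", label="infinite")
    ax.set_xticks(bins[:-1] + [top + 1])
    ax.set_xticklabels([str(b) for b in bins[:-1]] + ["inf"])
    ax.set_xlabel("edges to nearest reference")
    ax.set_ylabel("environmental amplicons")
    ax.legend()
    if title:
        ax.set_title(title)
    fig.tight_layout()
    fig.savefig(path, dpi=150)
    plt.close(fig)
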