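"""Synthetic amplicon communities with known ground truth.

The generator emulates the structure a novelty analysis of marker-gene
amplicons (e.g., 18S V4, ~380 bp) has to cope with:

* a set of *reference* sequences, mutually diverged "species" standing in
  for a curated reference database;
* per reference, a *known cloud* of environmental amplicons: a founder a
  small number of substitutions away from its reference plus chains of
  single-event mutants (substitutions and occasional 1-bp indels) with a
  heavy-tailed (Zipf) abundance profile, the founder most abundant;
* optional *stepping-stone chains*: cloud members placed so that they are
  within the clustering threshold of their reference but beyond it from
  the cloud founder. These connect through the reference in a similarity
  network, yet a radius-capped greedy clusterer strands them in their own
  purely environmental OTU — the constructed misclassification scenario;
* *novel lineages*: founders evolved from a random reference at a
  divergence drawn well above the species threshold, each with a small
  cloud of its own. The generator verifies (by banded edit distance) that
  no novel amplicon can form a threshold edge to any reference or any
  known-cloud amplicon, so "novel lineage" is a structural guarantee, not
  a label of intent.

Truth records store each environmental amplicon's true minimum divergence
to the reference set, recomputed exhaustively from the sequences with an
edit-distance routine independent of the alignment stack used by the
pipeline. ``truth_label`` is ``novel_lineage`` exactly when that minimum
divergence exceeds the novelty margin (1 - t of the planned clustering
run), and ``known_variant`` otherwise.
"""

from __future__ import annotations

import math
from dataclasses import dataclass
from pathlib import Path
from typing import Sequence

import edlib
import numpy as np
import pandas as pd

from .amplicon_io import Amplicon, ENVIRONMENTAL, REFERENCE, write_fasta

__all__ = [
    "SyntheticTruth",
    "SyntheticDataError",
    "generate_references",
    "generate_community",
    "stepping_stones_feasible",
    "write_dataset",
    "read_truth",
]

_BASES = "ACGT"

KNOWN_VARIANT = "known_variant"
NOVEL_LINEAGE = "novel_lineage"


class SyntheticDataError(RuntimeError):
    """Raised when divergence constraints cannot be satisfied."""


@dataclass(frozen=True, slots=True)
class SyntheticTruth:
    """Ground truth for one generated environmental amplicon."""

    amplicon_id: str
    lineage: str
    nearest_ref_id: str
    true_divergence: float
    truth_label: str


def _norm_dist(a: str, b: str) -> float:
    d = edlib.align(a, b, mode="NW", task="distance")["editDistance"]
    return d / max(len(a), len(b))


def _exceeds_band(a: str, b: str, band: int) -> bool:
    """True when edit distance > band (so identity >= t is impossible)."""
    return (
        edlib.align(a, b, mode="NW", task="distance", k=band)["editDistance"] < 0
    )


def _random_seq(rng: np.random.Generator, length: int) -> str:
    return "".join(rng.choice(list(_BASES), size=length))


def _substitute(
    seq: str, n: int, rng: np.random.Generator, used: set[int]
) -> tuple[str, set[int]]:
    """Apply n substitutions at fresh positions (disjoint from *used*)."""
    free = [i for i in range(len(seq)) if i not in used]
    if n > len(free):
        raise SyntheticDataError("not enough free positions for substitutions")
    positions = set(rng.choice(free, size=n, replace=False).tolist()) if n else set()
    chars = list(seq)
    for pos in positions:
        choices = [b for b in _BASES if b != chars[pos]]
        chars[pos] = choices[rng.integers(len(choices))]
    return "".join(chars), positions


def _single_event(
    seq: str, rng: np.random.Generator, indel_fraction: float
) -> str:
    """One mutation event: a substitution, or (with prob indel_fraction) a 1-bp indel."""
    if rng.random() < indel_fraction and len(seq) > 50:
        pos = int(rng.integers(len(seq)))
        if rng.random() < 0.5:
            return seq[:pos] + seq[pos + 1 :]  # deletion
        base = _BASES[rng.integers(4)]
        return seq[:pos] + base + seq[pos:]  # insertion
    pos = int(rng.integers(len(seq)))
    choices = [b for b in _BASES if b != seq[pos]]
    return seq[:pos] + choices[rng.integers(len(choices))] + seq[pos + 1 :]


def generate_references(
    n_ref: int = 20,
    length: int = 380,
    min_divergence: float = 0.10,
    seed: int = 0,
    attempt_budget: int | None = None,
) -> list[Amplicon]:
    """Random reference "species", each pair at normalized edit distance
    >= *min_divergence* (rejection sampling; deterministic under *seed*).
    Raises :class:`SyntheticDataError` when *attempt_budget* draws (default
    200 per reference) do not suffice."""
    if n_ref < 1:
        raise ValueError("n_ref must be >= 1")
    if length < 50:
        raise ValueError("length must be >= 50")
    if not 0.0 < min_divergence < 0.5:
        raise ValueError("min_divergence must be in (0, 0.5)")
    rng = np.random.default_rng(seed)
    refs: list[str] = []
    budget = 200 * n_ref if attempt_budget is None else attempt_budget
    while len(refs) < n_ref:
        if budget <= 0:
            raise SyntheticDataError(
                "could not satisfy min_divergence; lower n_ref or min_divergence"
            )
        budget -= 1
        cand = _random_seq(rng, length)
        if all(_norm_dist(cand, r) >= min_divergence for r in refs):
            refs.append(cand)
    return [
        Amplicon(
            id=f"ref_{i:03d}",
            sequence=seq,
            abundance=1,
            origin=REFERENCE,
            taxonomy=f"lineage_{i:03d}",
        )
        for i, seq in enumerate(refs)
    ]


def stepping_stones_feasible(
    length: int, threshold: float, cloud_divergence: float, cloud_size: int
) -> bool:
    """Whether a known cloud can host a stepping-stone chain spanning the
    clustering radius: needs room below the threshold (>= 4 mismatch
    columns), actual cloud divergence, and at least founder + 4 stones +
    one satellite."""
    margin = math.floor((1.0 - threshold) * length)
    return margin >= 4 and cloud_divergence > 0 and cloud_size >= 6


def generate_community(
    references: Sequence[Amplicon],
    cloud_size: int = 12,
    cloud_divergence: float = 0.01,
    novel_lineages: int = 5,
    novel_divergence_range: tuple[float, float] = (0.05, 0.15),
    abundance_exponent: float = 1.5,
    indel_fraction: float = 0.1,
    novel_cloud_size: int = 6,
    stepping_stones: bool = True,
    threshold: float = 0.97,
    seed: int = 0,
) -> tuple[list[Amplicon], list[SyntheticTruth]]:
    """Generate an environmental amplicon set with per-amplicon ground truth.

    See the module docstring for the community structure. *threshold* is
    the clustering threshold the dataset is calibrated against: stepping
    stones are sized to straddle its radius, and the novelty margin for
    truth labels is ``1 - threshold``. *novel_divergence_range* must lie
    strictly above that margin.

    Returns the environmental amplicons (dereplication is left to the
    pipeline; with positive cloud divergence duplicates are vanishingly
    rare) and one truth record per amplicon.
    """
    if not references:
        raise ValueError("references must be non-empty")
    if cloud_size < 1:
        raise ValueError("cloud_size must be >= 1")
    lo, hi = novel_divergence_range
    margin_frac = 1.0 - threshold
    if novel_lineages > 0 and not (margin_frac < lo < hi):
        raise SyntheticDataError(
            f"novel_divergence_range {novel_divergence_range} must lie strictly "
            f"above the novelty margin {margin_frac:.3f}"
        )
    rng = np.random.default_rng(seed)
    env: list[Amplicon] = []
    truths_pending: list[tuple[str, str]] = []  # (amplicon_id, lineage)

    def _zipf_abundances(n: int) -> list[int]:
        draws = sorted(
            (int(x) for x in rng.zipf(abundance_exponent, size=n)), reverse=True
        )
        return draws

    # --- known clouds ------------------------------------------------------
    for ref in references:
        L = len(ref)
        margin = math.floor(margin_frac * L)
        stones = stepping_stones and stepping_stones_feasible(
            L, threshold, cloud_divergence, cloud_size
        )
        used: set[int] = set()
        founder_subs = int(rng.binomial(L, cloud_divergence))
        if stones:
            q = margin - 2  # stones' distance budget from the reference
            founder_subs = min(max(founder_subs, margin + 1 - q), margin - 1)
        founder_seq, pos = _substitute(ref.sequence, founder_subs, rng, used)
        used |= pos

        seqs: list[str] = [founder_seq]
        n_stones = 4 if stones else 0
        # a reference-proximal "anchor" (ref + 1 substitution) and its own
        # satellite give the reference a direct d=1 neighbourhood, as real
        # communities have; they need two slots and positive divergence
        anchors = cloud_divergence > 0 and cloud_size >= n_stones + 4
        n_sats = max(cloud_size - 1 - n_stones - (2 if anchors else 0), 0)
        # satellite chains of single-event steps off the founder; each chain
        # stays within the greedy radius of the founder
        chain_cap = max(margin - founder_subs, 1)
        current = founder_seq
        steps = 0
        for _ in range(n_sats):
            if cloud_divergence == 0:
                seqs.append(founder_seq)  # noise-free cloud: exact copies
                continue
            if steps >= chain_cap:
                current, steps = founder_seq, 0
            current = _single_event(current, rng, indel_fraction)
            steps += 1
            seqs.append(current)
        if anchors:
            anchor_seq, pos = _substitute(ref.sequence, 1, rng, used)
            used |= pos
            anchor_sat, pos = _substitute(anchor_seq, 1, rng, used)
            used |= pos
            seqs.extend([anchor_seq, anchor_sat])
        if stones:
            # S1 bridges reference and founder; M is within the threshold of
            # the reference but beyond the greedy radius of the founder;
            # M2/M3 are satellites of M so the stranded OTU survives the
            # small-OTU filter.
            q1 = min(q - 1, margin - founder_subs)
            q2 = q - q1
            s1_seq, pos = _substitute(ref.sequence, q1, rng, used)
            used |= pos
            m_seq, pos = _substitute(s1_seq, q2, rng, used)
            used |= pos
            m2_seq, pos = _substitute(m_seq, 1, rng, used)
            used |= pos
            m3_seq, pos = _substitute(m2_seq, 1, rng, used)
            used |= pos
            seqs.extend([s1_seq, m_seq, m2_seq, m3_seq])

        abundances = _zipf_abundances(len(seqs))
        for k, (seq, ab) in enumerate(zip(seqs, abundances)):
            amp_id = f"env{ref.id.removeprefix('ref_')}_{k:02d}"
            env.append(
                Amplicon(id=amp_id, sequence=seq, abundance=ab, origin=ENVIRONMENTAL)
            )
            truths_pending.append((amp_id, ref.id))

    # --- novel lineages ----------------------------------------------------
    known_seqs = [a.sequence for a in env] + [r.sequence for r in references]
    for j in range(novel_lineages):
        source = references[j % len(references)]
        L = len(source)
        for attempt in range(100):
            n_sub = int(round(rng.uniform(lo, hi) * L))
            founder_seq, _ = _substitute(source.sequence, n_sub, rng, set())
            chain = [founder_seq]
            current = founder_seq
            for _ in range(max(novel_cloud_size - 1, 0)):
                current, _ = _substitute(current, 1, rng, set())
                chain.append(current)
            # structural guarantee: no member may reach threshold identity
            # with any reference or known-cloud amplicon
            ok = True
            for seq in chain:
                for other in known_seqs:
                    band = int(margin_frac * (len(seq) + len(other)))
                    if not _exceeds_band(seq, other, band):
                        ok = False
                        break
                if not ok:
                    break
            if ok:
                break
        else:
            raise SyntheticDataError(
                f"novel lineage {j}: could not place a founder beyond the "
                "novelty margin from all known sequences"
            )
        abundances = _zipf_abundances(len(chain))
        for k, (seq, ab) in enumerate(zip(chain, abundances)):
            amp_id = f"nov{j:02d}_{k:02d}"
            env.append(
                Amplicon(id=amp_id, sequence=seq, abundance=ab, origin=ENVIRONMENTAL)
            )
            truths_pending.append((amp_id, f"novel_{j:02d}"))

    # --- truth records (recomputed exhaustively from the sequences) --------
    by_id = {a.id: a for a in env}
    truths: list[SyntheticTruth] = []
    for amp_id, lineage in truths_pending:
        seq = by_id[amp_id].sequence
        best_ref, best_div = None, math.inf
        for ref in sorted(references, key=lambda r: r.id):
            div = _norm_dist(seq, ref.sequence)
            if div < best_div:
                best_ref, best_div = ref.id, div
        truths.append(
            SyntheticTruth(
                amplicon_id=amp_id,
                lineage=lineage,
                nearest_ref_id=best_ref,
                true_divergence=best_div,
                truth_label=NOVEL_LINEAGE if best_div > margin_frac else KNOWN_VARIANT,
            )
        )
    return env, truths


def write_dataset(
    outdir: str | Path,
    references: Sequence[Amplicon],
    env: Sequence[Amplicon],
    truths: Sequence[SyntheticTruth],
    abundance_dialect: str = "size",
) -> dict[str, Path]:
    """Write ref/env FASTA files and the truth TSV; returns the paths."""
    outdir = Path(outdir)
    outdir.mkdir(parents=True, exist_ok=True)
    paths = {
        "ref_fasta": outdir / "references.fasta",
        "env_fasta": outdir / "environment.fasta",
        "truth_tsv": outdir / "truth.tsv",
    }
    write_fasta(references, paths["ref_fasta"], abundance_dialect)
    write_fasta(env, paths["env_fasta"], abundance_dialect)
    with open(paths["truth_tsv"], "w") as fh:
        fh.write("amplicon_id\tlineage\tnearest_ref_id\ttrue_divergence\ttruth_label\n")
        for t in truths:
            fh.write(
                f"{t.amplicon_id}\t{t.lineage}\t{t.nearest_ref_id}\t"
                f"{t.true_divergence:.6f}\t{t.truth_label}\n"
            )
    return paths


def read_truth(path: str | Path) -> list[SyntheticTruth]:
    """Read a truth TSV written by :func:`write_dataset`."""
    df = pd.read_csv(path, sep="\t")
    return [
        SyntheticTruth(
            amplicon_id=str(r.amplicon_id),
            lineage=str(r.lineage),
            nearest_ref_id=str(r.nearest_ref_id),
            true_divergence=float(r.true_divergence),
            truth_label=str(r.truth_label),
        )
        for r in df.itertuples(index=False)
    ]
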