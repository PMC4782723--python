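"""Reading, writing, labelling and dereplicating amplicon FASTA files.

An *amplicon* is a dereplicated sequencing read: a unique sequence together
with an abundance (the number of strictly identical reads observed).
Abundance annotations in FASTA headers come in two common dialects, the
``;size=N`` suffix used by the usearch/vsearch family and a trailing ``_N``
used by swarm-style tools; both are supported, plus ``none`` for files
without annotations.

Amplicons carry an *origin* label distinguishing environmental reads from
taxonomically identified reference sequences; the two sets are dereplicated
separately and only combined for clustering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from pathlib import Path
from typing import Iterable, Sequence

import pandas as pd
from Bio import SeqIO

__all__ = [
    "Amplicon",
    "AmpliconError",
    "ENVIRONMENTAL",
    "REFERENCE",
    "DIALECTS",
    "read_fasta",
    "write_fasta",
    "dereplicate",
    "amplicon_table",
]

ENVIRONMENTAL = "environmental"
REFERENCE = "reference"
_ORIGINS = frozenset({ENVIRONMENTAL, REFERENCE})

#: Supported abundance header dialects.
DIALECTS = ("size", "underscore", "none")

_DIALECT_ALIASES = {
    "size": "size",
    ";size=": "size",
    "underscore": "underscore",
    "_": "underscore",
    "none": "none",
}

_VALID_CHARS = frozenset("ACGTN")
_SIZE_RE = re.compile(r";size=(\d+);?$")
_UNDERSCORE_RE = re.compile(r"_(\d+)$")


class AmpliconError(ValueError):
    """Raised for malformed amplicon records or inconsistent datasets."""


@dataclass(frozen=True, slots=True)
class Amplicon:
    """One dereplicated sequence with its read count and origin label.

    Parameters
    ----------
    id : str
        Identifier, unique within a dataset.
    sequence : str
        Uppercase DNA over ``{A, C, G, T, N}``; no gaps or whitespace.
    abundance : int
        Number of identical reads collapsed into this amplicon (>= 1).
    origin : str
        Either ``"environmental"`` or ``"reference"``.
    taxonomy : str or None
        Free-text taxonomy annotation (reference sequences only, optional).
    """

    id: str
    sequence: str
    abundance: int = 1
    origin: str = ENVIRONMENTAL
    taxonomy: str | None = None

    def __post_init__(self) -> None:
        if not self.id:
            raise AmpliconError("amplicon id must be non-empty")
        if not self.sequence:
            raise AmpliconError(f"amplicon {self.id!r}: sequence is empty")
        bad = set(self.sequence) - _VALID_CHARS
        if bad:
            raise AmpliconError(
                f"amplicon {self.id!r}: invalid characters {sorted(bad)!r} "
                "(sequences must be uppercase DNA over A/C/G/T/N)"
            )
        if self.abundance < 1:
            raise AmpliconError(
                f"amplicon {self.id!r}: abundance must be >= 1, got {self.abundance}"
            )
        if self.origin not in _ORIGINS:
            raise AmpliconError(
                f"amplicon {self.id!r}: origin must be one of {sorted(_ORIGINS)}"
            )

    def __len__(self) -> int:
        return len(self.sequence)


def _normalize_dialect(dialect: str) -> str:
    try:
        return _DIALECT_ALIASES[dialect]
    except KeyError:
        raise AmpliconError(
            f"unknown abundance dialect {dialect!r}; expected one of {DIALECTS}"
        ) from None


def _parse_header(label: str, dialect: str) -> tuple[str, int]:
    """Split a FASTA id token into (amplicon id, abundance) per dialect."""
    if dialect == "size":
        m = _SIZE_RE.search(label)
        if m is None:
            raise AmpliconError(
                f"record {label!r}: no ';size=N' abundance annotation found"
            )
        return label[: m.start()], int(m.group(1))
    if dialect == "underscore":
        m = _UNDERSCORE_RE.search(label)
        if m is None:
            raise AmpliconError(
                f"record {label!r}: no trailing '_N' abundance annotation found"
            )
        return label[: m.start()], int(m.group(1))
    return label, 1


def read_fasta(
    path: str | Path,
    origin: str = ENVIRONMENTAL,
    abundance_dialect: str = "size",
) -> list[Amplicon]:
    """Read a FASTA file into a list of :class:`Amplicon`.

    The abundance is parsed from each header's first whitespace-delimited
    token according to *abundance_dialect*; any remaining description text
    is stored as the taxonomy string. Sequences are uppercased. Duplicate
    ids raise :class:`AmpliconError`.
    """
    dialect = _normalize_dialect(abundance_dialect)
    path = Path(path)
    text_head = path.read_text()[:1].lstrip()
    if text_head and not text_head.startswith(">"):
        raise AmpliconError(f"{path}: not FASTA-formatted (does not start with '>')")

    amplicons: list[Amplicon] = []
    seen: set[str] = set()
    for record in SeqIO.parse(str(path), "fasta"):
        amp_id, abundance = _parse_header(record.id, dialect)
        if not amp_id:
            raise AmpliconError(f"{path}: record {record.id!r} has an empty id")
        if amp_id in seen:
            raise AmpliconError(f"{path}: duplicate amplicon id {amp_id!r}")
        seen.add(amp_id)
        rest = record.description[len(record.id) :].strip()
        try:
            amplicons.append(
                Amplicon(
                    id=amp_id,
                    sequence=str(record.seq).upper(),
                    abundance=abundance,
                    origin=origin,
                    taxonomy=rest or None,
                )
            )
        except AmpliconError as exc:
            raise AmpliconError(f"{path}: {exc}") from exc
    return amplicons


def _format_header(amp: Amplicon, dialect: str) -> str:
    if dialect == "size":
        head = f"{amp.id};size={amp.abundance}"
    elif dialect == "underscore":
        head = f"{amp.id}_{amp.abundance}"
    else:
        head = amp.id
    if amp.taxonomy:
        head = f"{head} {amp.taxonomy}"
    return head


def write_fasta(
    amplicons: Sequence[Amplicon],
    path: str | Path,
    abundance_dialect: str = "size",
) -> None:
    """Write amplicons as single-line-sequence FASTA.

    The output round-trips exactly: reading it back with the same dialect
    reproduces every (id, sequence, abundance) triple, and a second
    write is byte-identical.
    """
    dialect = _normalize_dialect(abundance_dialect)
    with open(path, "w") as fh:
        for amp in amplicons:
            fh.write(f">{_format_header(amp, dialect)}\n{amp.sequence}\n")


def dereplicate(amplicons: Iterable[Amplicon]) -> list[Amplicon]:
    """Merge strictly identical sequences, summing abundances.

    The merged amplicon takes the id of its most abundant member (ties
    broken by the lexicographically smallest id), so the result is fully
    deterministic. Output is sorted by decreasing abundance, then id.
    All inputs must share one origin label: environmental and reference
    sets are dereplicated separately.
    """
    groups: dict[str, list[Amplicon]] = {}
    origins: set[str] = set()
    for amp in amplicons:
        origins.add(amp.origin)
        groups.setdefault(amp.sequence, []).append(amp)
    if len(origins) > 1:
        raise AmpliconError(
            "dereplicate: mixed origin labels; dereplicate environmental and "
            "reference sets separately"
        )
    merged: list[Amplicon] = []
    for seq, members in groups.items():
        total = sum(m.abundance for m in members)
        head = min(members, key=lambda m: (-m.abundance, m.id))
        merged.append(
            Amplicon(
                id=head.id,
                sequence=seq,
                abundance=total,
                origin=head.origin,
                taxonomy=head.taxonomy,
            )
        )
    merged.sort(key=lambda m: (-m.abundance, m.id))
    return merged


def amplicon_table(amplicons: Sequence[Amplicon]) -> pd.DataFrame:
    """Tabulate (id, abundance, origin, length) for inspection or TSV export."""
    return pd.DataFrame(
        {
            "id": [a.id for a in amplicons],
            "abundance": [a.abundance for a in amplicons],
            "origin": [a.origin for a in amplicons],
            "length": [len(a) for a in amplicons],
        }
    )
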