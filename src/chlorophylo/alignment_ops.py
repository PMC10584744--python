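"""Alignment containers, gap trimming, and supermatrix construction.

The trimming rule removes columns that are mostly gaps while guaranteeing
that a floor fraction of the original alignment length is retained;
supermatrices concatenate per-marker alignments for a shared taxon set in
any marker arrangement, carrying a contiguous partition scheme (0-based
half-open internally, 1-based inclusive in exported partition files).
"""

from __future__ import annotations

import itertools
import math
from dataclasses import dataclass

from Bio import SeqIO


@dataclass
class Alignment:
    """Columnar multiple alignment: ordered mapping label -> residue string."""

    rows: dict[str, str]
    marker: str = ""

    def __post_init__(self) -> None:
        if self.rows:
            lengths = {len(v) for v in self.rows.values()}
            if len(lengths) != 1:
                raise ValueError(f"rows have unequal lengths: {sorted(lengths)}")

    @property
    def n_columns(self) -> int:
        return len(next(iter(self.rows.values()))) if self.rows else 0

    @property
    def n_rows(self) -> int:
        return len(self.rows)

    def column(self, j: int) -> str:
        return "".join(row[j] for row in self.rows.values())

    def take_columns(self, cols: list[int]) -> "Alignment":
        return Alignment(rows={k: "".join(v[j] for j in cols)
                               for k, v in self.rows.items()},
                         marker=self.marker)


@dataclass
class PartitionScheme:
    """Ordered contiguous column intervals, one per marker, with models."""

    parts: list[tuple[str, int, int, object]]  # (marker, start, end, model) half-open

    def __post_init__(self) -> None:
        pos = 0
        for marker, start, end, _model in self.parts:
            if start != pos or end <= start:
                raise ValueError("partitions must be contiguous, ascending, non-empty")
            pos = end

    @property
    def n_columns(self) -> int:
        return self.parts[-1][2] if self.parts else 0

    def to_raxml(self, model_name: str = "GTR+G") -> str:
        """RAxML-style partition lines, 1-based inclusive coordinates."""
        return "\n".join(f"{model_name}, {m} = {s + 1}-{e}"
                         for m, s, e, _ in self.parts)


@dataclass
class Supermatrix:
    """Concatenated alignment over a shared taxon set with its partitions."""

    alignment: Alignment
    scheme: PartitionScheme
    arrangement: tuple[str, ...]

    def partition_slice(self, marker: str) -> Alignment:
        for m, s, e, _ in self.scheme.parts:
            if m == marker:
                return Alignment(rows={k: v[s:e] for k, v in self.alignment.rows.items()},
                                 marker=marker)
        raise KeyError(marker)


def read_fasta_alignment(path: str, marker: str = "") -> Alignment:
    rows = {rec.id: str(rec.seq).upper() for rec in SeqIO.parse(path, "fasta")}
    if not rows:
        raise ValueError(f"no records in {path}")
    return Alignment(rows=rows, marker=marker)


def write_fasta_alignment(aln: Alignment, path: str) -> None:
    with open(path, "w") as fh:
        for label, seq in aln.rows.items():
            fh.write(f">{label}\n{seq}\n")


def write_phylip(aln: Alignment, path: str) -> None:
    """Relaxed PHYLIP (label, two spaces, sequence)."""
    with open(path, "w") as fh:
        fh.write(f" {aln.n_rows} {aln.n_columns}\n")
        for label, seq in aln.rows.items():
            fh.write(f"{label}  {seq}\n")


def gap_fractions(aln: Alignment) -> list[float]:
    n = aln.n_rows
    counts = [0] * aln.n_columns
    for seq in aln.rows.values():
        for j, c in enumerate(seq):
            if c == "-":
                counts[j] += 1
    return [c / n for c in counts]


def trim_gappy_columns(aln: Alignment, gap_threshold: float = 0.70,
                       min_retained: float = 0.80):
    """Drop columns with gap fraction strictly above ``gap_threshold``.

    Candidates are removed in descending gap-fraction order (ties broken
    leftmost-first) but never below a retained-length floor of
    ``ceil(min_retained * original_length)`` columns.  Returns the trimmed
    alignment and the original indices of removed columns (ascending).
    """
    if not (0 < gap_threshold < 1) or not (0 < min_retained <= 1):
        raise ValueError("thresholds must lie in (0,1) / (0,1]")
    if aln.n_rows == 0 or aln.n_columns == 0:
        raise ValueError("empty alignment")
    fractions = gap_fractions(aln)
    n = aln.n_columns
    floor = math.ceil(min_retained * n)
    candidates = sorted((j for j, f in enumerate(fractions) if f > gap_threshold),
                        key=lambda j: (-fractions[j], j))
    removed: list[int] = []
    remaining = n
    for j in candidates:
        if remaining - 1 < floor:
            break
        removed.append(j)
        remaining -= 1
    removed_set = set(removed)
    kept = [j for j in range(n) if j not in removed_set]
    return aln.take_columns(kept), sorted(removed)


def all_arrangements(markers: list[str]) -> list[tuple[str, ...]]:
    """Every ordering of the marker list, lexicographically sorted."""
    if not markers:
        raise ValueError("need at least one marker")
    return sorted(itertools.permutations(markers))


def concatenate(alignments: dict[str, Alignment], taxa: list[str],
                arrangement: tuple[str, ...],
                models: dict[str, object] | None = None) -> Supermatrix:
    """Concatenate per-marker alignments for ``taxa`` in the given order.

    Every taxon must have exactly one row in every marker alignment
    (representative selection happens upstream); a missing row is an error
    naming the taxon and marker.
    """
    for marker in arrangement:
        aln = alignments[marker]
        for t in taxa:
            if t not in aln.rows:
                raise ValueError(f"taxon {t!r} missing from marker {marker!r}")
    rows = {t: "".join(alignments[m].rows[t] for m in arrangement) for t in taxa}
    parts = []
    pos = 0
    for m in arrangement:
        ln = alignments[m].n_columns
        parts.append((m, pos, pos + ln, (models or {}).get(m)))
        pos += ln
    return Supermatrix(alignment=Alignment(rows=rows, marker="+".join(arrangement)),
                       scheme=PartitionScheme(parts=parts),
                       arrangement=tuple(arrangement))
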