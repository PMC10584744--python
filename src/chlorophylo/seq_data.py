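"""Multi-marker sequence collections with taxonomy metadata.

A marker dataset bundles nucleotide sequences for several DNA-barcode
markers (18S rRNA, the ITS region, chloroplast rbcL, ...) together with a
taxonomy sidecar (accession, species, genus, marker).  Sequences arrive as
per-marker FASTA files; metadata travels in a tab-separated table rather
than being parsed out of FASTA headers, because GenBank header formats are
not consistent enough to rely on.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass, field

import pandas as pd
from Bio import SeqIO

logger = logging.getLogger(__name__)

IUPAC_NT = set("ACGTURYSWKMBDHVN-")

#: default outfmt-6-style column names for similarity hit tables
HIT_COLUMNS = {"query": "query", "subject": "subject", "evalue": "evalue",
               "pident": "pident", "qcovs": "qcovs"}


@dataclass(frozen=True)
class MarkerSequence:
    """One nucleotide sequence with its taxonomy and marker labels."""

    accession: str
    species: str
    genus: str
    marker: str
    residues: str

    def __post_init__(self) -> None:
        if not self.residues:
            raise ValueError(f"{self.accession}: empty residue string")
        bad = set(self.residues.upper()) - IUPAC_NT
        if bad:
            raise ValueError(f"{self.accession}: non-nucleotide characters {sorted(bad)}")
        if self.species.split()[0] != self.genus:
            raise ValueError(
                f"{self.accession}: genus {self.genus!r} is not the first token "
                f"of species {self.species!r}")


@dataclass
class HitRecord:
    """A similarity-search hit (query vs subject) used for quality filtering."""

    query: str
    subject: str
    e_value: float
    identity_pct: float
    coverage_pct: float

    def __post_init__(self) -> None:
        if self.e_value < 0:
            raise ValueError("e_value must be non-negative")
        for name in ("identity_pct", "coverage_pct"):
            v = getattr(self, name)
            if not 0 <= v <= 100:
                raise ValueError(f"{name}={v} outside [0, 100]")


@dataclass
class MarkerDataset:
    """A curated multi-marker collection with declared outgroup species."""

    sequences: list[MarkerSequence]
    markers: list[str]
    outgroup_species: set[str] = field(default_factory=set)

    def __post_init__(self) -> None:
        seen: set[tuple[str, str]] = set()
        for s in self.sequences:
            key = (s.accession, s.marker)
            if key in seen:
                raise ValueError(f"duplicate (accession, marker) pair {key}")
            seen.add(key)
            if s.marker not in self.markers:
                raise ValueError(f"{s.accession}: marker {s.marker!r} not in {self.markers}")

    def by_marker(self, marker: str) -> list[MarkerSequence]:
        return [s for s in self.sequences if s.marker == marker]

    def species(self, include_outgroup: bool = True) -> set[str]:
        out = {s.species for s in self.sequences}
        if not include_outgroup:
            out -= self.outgroup_species
        return out


def read_dataset(fasta_paths: dict[str, str], metadata_path: str,
                 outgroup_species: set[str] | None = None) -> MarkerDataset:
    """Read per-marker FASTA files against a metadata sidecar TSV.

    ``fasta_paths`` maps marker label -> FASTA path.  The metadata TSV needs
    columns accession, species, genus, marker.  FASTA records whose id is
    absent from the metadata (for their marker) are skipped with a logged
    count; metadata rows whose genus disagrees with the species binomial are
    a hard error.
    """
    meta = pd.read_csv(metadata_path, sep="\t", dtype=str)
    required = {"accession", "species", "genus", "marker"}
    missing = required - set(meta.columns)
    if missing:
        raise ValueError(f"metadata missing columns: {sorted(missing)}")
    bad = meta[meta["species"].str.split().str[0] != meta["genus"]]
    if len(bad):
        rows = bad[["accession", "species", "genus"]].to_dict("records")
        raise ValueError(f"metadata rows where genus != first species token: {rows}")
    lookup = {(r.accession, r.marker): r for r in meta.itertuples()}

    sequences: list[MarkerSequence] = []
    n_skipped = 0
    for marker, path in fasta_paths.items():
        for rec in SeqIO.parse(path, "fasta"):
            row = lookup.get((rec.id, marker))
            if row is None:
                n_skipped += 1
                logger.warning("record %s (%s) absent from metadata; skipped", rec.id, marker)
                continue
            sequences.append(MarkerSequence(
                accession=rec.id, species=row.species, genus=row.genus,
                marker=marker, residues=str(rec.seq).upper()))
    if n_skipped:
        logger.info("skipped %d FASTA records without metadata", n_skipped)
    ds = MarkerDataset(sequences=sequences, markers=list(fasta_paths),
                       outgroup_species=set(outgroup_species or ()))
    ds.n_skipped = n_skipped  # type: ignore[attr-defined]
    return ds


def read_hit_table(path: str, columns: dict[str, str] | None = None) -> list[HitRecord]:
    """Read a tab-separated similarity hit table (outfmt-6-style names)."""
    cols = dict(HIT_COLUMNS)
    if columns:
        cols.update(columns)
    tab = pd.read_csv(path, sep="\t")
    return [HitRecord(query=str(r[cols["query"]]), subject=str(r[cols["subject"]]),
                      e_value=float(r[cols["evalue"]]), identity_pct=float(r[cols["pident"]]),
                      coverage_pct=float(r[cols["qcovs"]]))
            for _, r in tab.iterrows()]


def filter_by_hits(dataset: MarkerDataset, hits: list[HitRecord],
                   e_max: float = 1e-15, id_min_pct: float = 40.0,
                   cov_min_pct: float = 40.0) -> MarkerDataset:
    """Keep sequences with at least one passing similarity hit.

    A hit passes if e_value <= e_max, identity strictly > id_min_pct and
    query coverage strictly > cov_min_pct.  Identity/coverage comparisons
    are strict because the quality rule is stated as "> 40%"; the e-value
    is a cutoff and compares non-strictly.  Sequences with no hit at all
    fail the filter.
    """
    passing = {h.query for h in hits
               if h.e_value <= e_max and h.identity_pct > id_min_pct
               and h.coverage_pct > cov_min_pct}
    kept = [s for s in dataset.sequences if s.accession in passing]
    removed = [s.accession for s in dataset.sequences if s.accession not in passing]
    if removed:
        logger.info("filter_by_hits removed %d sequences: %s", len(removed), removed)
    return MarkerDataset(sequences=kept, markers=list(dataset.markers),
                         outgroup_species=set(dataset.outgroup_species))


def _canonical(residues: str) -> str:
    return residues.upper().strip("-")


def remove_redundant(dataset: MarkerDataset) -> MarkerDataset:
    """Collapse exact duplicate sequences within each (species, marker) group.

    Identity is exact string equality after uppercasing and stripping
    terminal gaps; the surviving accession is the lexicographically smallest.
    Identical strings in *different* species are both kept.
    """
    best: dict[tuple[str, str, str], MarkerSequence] = {}
    for s in dataset.sequences:
        key = (s.species, s.marker, _canonical(s.residues))
        cur = best.get(key)
        if cur is None or s.accession < cur.accession:
            best[key] = s
    survivors = {(s.accession, s.marker) for s in best.values()}
    kept = [s for s in dataset.sequences if (s.accession, s.marker) in survivors]
    n_removed = len(dataset.sequences) - len(kept)
    if n_removed:
        logger.info("remove_redundant collapsed %d duplicate sequences", n_removed)
    ds = MarkerDataset(sequences=kept, markers=list(dataset.markers),
                       outgroup_species=set(dataset.outgroup_species))
    ds.n_removed = n_removed  # type: ignore[attr-defined]
    return ds


def shared_species(dataset: MarkerDataset, required_markers: list[str]) -> set[str]:
    """Ingroup species with at least one sequence for every required marker."""
    if not required_markers:
        raise ValueError("required_markers must be non-empty")
    unknown = set(required_markers) - set(dataset.markers)
    if unknown:
        raise ValueError(f"markers not in dataset: {sorted(unknown)}")
    have: dict[str, set[str]] = {}
    for s in dataset.sequences:
        have.setdefault(s.species, set()).add(s.marker)
    return {sp for sp, mk in have.items()
            if set(required_markers) <= mk and sp not in dataset.outgroup_species}


def dataset_summary(dataset: MarkerDataset) -> dict:
    """Counts of sequences, species and genera; outgroup tallied separately."""
    ingroup = [s for s in dataset.sequences if s.species not in dataset.outgroup_species]
    outgroup = [s for s in dataset.sequences if s.species in dataset.outgroup_species]
    per_marker = {m: sum(1 for s in ingroup if s.marker == m) for m in dataset.markers}
    return {
        "n_sequences": len(ingroup),
        "n_species": len({s.species for s in ingroup}),
        "n_genera": len({s.genus for s in ingroup}),
        "per_marker": per_marker,
        "n_outgroup_sequences": len(outgroup),
        "n_outgroup_species": len({s.species for s in outgroup}),
    }
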