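"""Sequence records, FASTA input/output, and taxonomy hit tables.

FASTA headers carry pipe-delimited metadata: ``id|marker|sample|forest|habitat``,
with trailing fields optional.  Readers validate rather than coerce: unknown
residue characters, duplicate identifiers and malformed files are errors.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass, field
from pathlib import Path

from Bio import SeqIO

from ecmcomm.config import HABITATS
from ecmcomm.errors import EmptyInputError, FormatError, ValidationError

MARKERS = ("ITS", "LSU")

# IUPAC nucleotide one-letter codes (consensus sequences may carry ambiguity
# codes) plus N and the gap character.
_ALPHABET = frozenset("ACGTUNRYSWKMBDHV-")


@dataclass
class SequenceRecord:
    """A single sequenced root tip (or reference sequence) with metadata."""

    id: str
    marker: str | None = None
    residues: str = ""
    sample_id: str | None = None
    forest_id: str | None = None
    habitat: str | None = None

    def __post_init__(self) -> None:
        self.id = self.id.strip()
        if not self.id:
            raise ValidationError("sequence id must be non-empty")
        self.residues = self.residues.strip().upper()
        if not self.residues:
            raise ValidationError(f"sequence {self.id!r}: residues must be non-empty")
        bad = set(self.residues) - _ALPHABET
        if bad:
            raise ValidationError(
                f"sequence {self.id!r}: invalid residue characters {sorted(bad)}"
            )
        if self.marker is not None and self.marker not in MARKERS:
            raise ValidationError(
                f"sequence {self.id!r}: marker must be one of {MARKERS}, got {self.marker!r}"
            )
        if self.habitat is not None and self.habitat not in HABITATS:
            raise ValidationError(
                f"sequence {self.id!r}: habitat must be one of {HABITATS}, got {self.habitat!r}"
            )

    @property
    def header(self) -> str:
        fields = [self.id, self.marker or "", self.sample_id or "",
                  self.forest_id or "", self.habitat or ""]
        while len(fields) > 1 and fields[-1] == "":
            fields.pop()
        return "|".join(fields)


def _record_from_header(header: str, residues: str) -> SequenceRecord:
    parts = [p.strip() for p in header.split("|")]
    parts += [""] * (5 - len(parts))
    rid, marker, sample, forest, habitat = parts[:5]
    return SequenceRecord(
        id=rid,
        marker=marker or None,
        residues=residues,
        sample_id=sample or None,
        forest_id=forest or None,
        habitat=habitat or None,
    )


def read_fasta(path: str | Path) -> list[SequenceRecord]:
    """Read a FASTA file into :class:`SequenceRecord` objects.

    Raises :class:`FormatError` on malformed input (naming the offending
    line) and :class:`EmptyInputError` on an empty file.
    """
    path = Path(path)
    text = path.read_text()
    if not text.strip():
        raise EmptyInputError(f"{path}: empty FASTA file")
    for lineno, line in enumerate(text.splitlines(), start=1):
        if line.strip():
            if not line.startswith(">"):
                raise FormatError(
                    f"{path}: line {lineno}: expected FASTA header starting with '>'"
                )
            break
    records: list[SequenceRecord] = []
    seen: set[str] = set()
    for bio_rec in SeqIO.parse(str(path), "fasta"):
        rec = _record_from_header(bio_rec.description, str(bio_rec.seq))
        if rec.id in seen:
            raise FormatError(f"{path}: duplicate sequence id {rec.id!r}")
        seen.add(rec.id)
        records.append(rec)
    if not records:
        raise FormatError(f"{path}: no FASTA records parsed")
    return records


def write_fasta(records: list[SequenceRecord], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        for rec in records:
            fh.write(f">{rec.header}\n{rec.residues}\n")


@dataclass
class TaxonomyHits:
    """Rank-ordered genus hits for one query sequence (best hit first)."""

    query_id: str
    hits: list[str] = field(default_factory=list)


def read_taxonomy_hits(path: str | Path) -> list[TaxonomyHits]:
    """Read a TSV hit table with columns ``query`` and ``genus``.

    Row order within a query defines hit rank.  Query order follows first
    appearance in the file.
    """
    path = Path(path)
    by_query: dict[str, TaxonomyHits] = {}
    with path.open() as fh:
        reader = csv.reader(fh, delimiter="\t")
        header = next(reader, None)
        if header is None:
            raise EmptyInputError(f"{path}: empty hit table")
        cols = [c.strip().lower() for c in header]
        try:
            qi, gi = cols.index("query"), cols.index("genus")
        except ValueError as exc:
            raise FormatError(
                f"{path}: hit table must have 'query' and 'genus' columns"
            ) from exc
        for lineno, row in enumerate(reader, start=2):
            if not row or not any(cell.strip() for cell in row):
                continue
            if len(row) <= max(qi, gi):
                raise FormatError(f"{path}: line {lineno}: too few columns")
            query = row[qi].strip()
            genus = row[gi].strip()
            if not query:
                raise FormatError(f"{path}: line {lineno}: empty query id")
            by_query.setdefault(query, TaxonomyHits(query)).hits.append(genus)
    return list(by_query.values())


def write_taxonomy_hits(hits: list[TaxonomyHits], path: str | Path) -> None:
    path = Path(path)
    with path.open("w") as fh:
        fh.write("query\tgenus\n")
        for th in hits:
            for genus in th.hits:
                fh.write(f"{th.query_id}\t{genus}\n")
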