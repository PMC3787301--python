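"""Data model and readers/writers for the flat-file formats the pipeline touches.

The pipeline exchanges four kinds of files: FASTA (protein or nucleotide),
the 12-column tab-separated hit table (the classic tabular output of pairwise
search engines: qseqid, sseqid, pident, length, mismatch, gapopen, qstart,
qend, sstart, send, evalue, bitscore), a 2-column subject-to-phylum taxonomy
TSV, and assorted small TSVs handled by the downstream modules.

Parsing is strict: sequences with characters outside the declared alphabet,
malformed headers and rows with the wrong field count raise ``ParseError``
naming the offending line or row — silent masking of upstream corruption is
never done.
"""

from __future__ import annotations

import logging
from dataclasses import dataclass
from pathlib import Path

logger = logging.getLogger(__name__)

#: 20 canonical amino acids plus X (unknown residue).
PROTEIN_ALPHABET = frozenset("ACDEFGHIKLMNPQRSTVWYX")
#: IUPAC nucleotide codes (uppercase).
DNA_ALPHABET = frozenset("ACGTUNRYSWKMBDHV")


class ParseError(ValueError):
    """Raised for malformed input files; the message names the line or row."""


@dataclass
class ProteinRecord:
    """One sequence record: a predicted protein, or a nucleotide scaffold.

    Coordinates, when present, are 1-based inclusive on the scaffold.
    """

    id: str
    genome_id: str
    sequence: str
    description: str = ""
    scaffold_id: str | None = None
    start: int | None = None
    end: int | None = None
    strand: str | None = None

    def __post_init__(self) -> None:
        if not self.sequence:
            raise ValueError(f"record {self.id!r}: empty sequence")
        if self.start is not None and self.end is not None and self.end < self.start:
            raise ValueError(f"record {self.id!r}: end < start")
        if self.strand not in (None, "+", "-"):
            raise ValueError(f"record {self.id!r}: bad strand {self.strand!r}")

    def __len__(self) -> int:
        return len(self.sequence)


@dataclass
class SimilarityHit:
    """One query-subject alignment result (one 12-field tabular row)."""

    query_id: str
    subject_id: str
    pident: float
    length: int
    mismatch: int
    gapopen: int
    qstart: int
    qend: int
    sstart: int
    send: int
    evalue: float
    bitscore: float

    def __post_init__(self) -> None:
        if not (0.0 <= self.pident <= 100.0):
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: pident {self.pident}")
        if self.length < 1:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: length {self.length}")
        if self.evalue < 0:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: negative e-value")
        if self.qend < self.qstart or self.send < self.sstart:
            raise ValueError(f"hit {self.query_id}->{self.subject_id}: inverted coordinates")


def read_fasta(
    path: str | Path,
    genome_id: str | None = None,
    moltype: str = "protein",
) -> list[ProteinRecord]:
    """Read a FASTA file into :class:`ProteinRecord` objects.

    The token before the first whitespace in each header is the record id;
    the remainder is stored as ``description``.  Sequences are uppercased and
    validated against the protein or nucleotide alphabet (``moltype`` is
    ``"protein"`` or ``"dna"``).  ``genome_id`` defaults to the file stem.
    An empty file yields an empty list with a warning.
    """
    path = Path(path)
    if genome_id is None:
        genome_id = path.stem
    alphabet = PROTEIN_ALPHABET if moltype == "protein" else DNA_ALPHABET
    records: list[ProteinRecord] = []
    header: str | None = None
    header_line = 0
    chunks: list[str] = []
    seen: set[str] = set()

    def flush() -> None:
        assert header is not None
        seq = "".join(chunks).upper()
        if not seq:
            raise ParseError(f"{path}: empty sequence for header at line {header_line}")
        bad = set(seq) - alphabet
        if bad:
            raise ParseError(
                f"{path}: record starting at line {header_line} contains "
                f"characters outside the {moltype} alphabet: {sorted(bad)}"
            )
        token, _, desc = header.partition(" ")
        if not token:
            raise ParseError(f"{path}: empty header at line {header_line}")
        if token in seen:
            raise ParseError(f"{path}: duplicate record id {token!r} at line {header_line}")
        seen.add(token)
        records.append(ProteinRecord(id=token, genome_id=genome_id, sequence=seq, description=desc.strip()))

    with open(path) as fh:
        for lineno, raw in enumerate(fh, start=1):
            line = raw.strip()
            if not line:
                continue
            if line.startswith(">"):
                if header is not None:
                    flush()
                header = line[1:].strip()
                header_line = lineno
                chunks = []
            else:
                if header is None:
                    raise ParseError(f"{path}: sequence data before first header at line {lineno}")
                chunks.append(line)
        if header is not None:
            flush()
    if not records:
        logger.warning("%s: empty FASTA file", path)
    return records


def write_fasta(records: list[ProteinRecord], path: str | Path, width: int = 60) -> None:
    with open(path, "w") as fh:
        for rec in records:
            head = rec.id if not rec.description else f"{rec.id} {rec.description}"
            fh.write(f">{head}\n")
            for i in range(0, len(rec.sequence), width):
                fh.write(rec.sequence[i : i + width] + "\n")


_HIT_FIELDS = (
    "qseqid sseqid pident length mismatch gapopen qstart qend sstart send evalue bitscore"
).split()


def read_hit_table(path: str | Path) -> list[SimilarityHit]:
    """Read a 12-column tabular hit file, preserving row order."""
    hits: list[SimilarityHit] = []
    with open(path) as fh:
        for row_idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 12:
                raise ParseError(f"{path}: row {row_idx}: expected 12 fields, got {len(parts)}")
            try:
                hits.append(
                    SimilarityHit(
                        query_id=parts[0],
                        subject_id=parts[1],
                        pident=float(parts[2]),
                        length=int(parts[3]),
                        mismatch=int(parts[4]),
                        gapopen=int(parts[5]),
                        qstart=int(parts[6]),
                        qend=int(parts[7]),
                        sstart=int(parts[8]),
                        send=int(parts[9]),
                        evalue=float(parts[10]),
                        bitscore=float(parts[11]),
                    )
                )
            except ValueError as exc:
                raise ParseError(f"{path}: row {row_idx}: {exc}") from exc
    return hits


def format_hit(hit: SimilarityHit) -> str:
    """Render one hit as a 12-field row: pident/bitscore to 1 decimal,
    e-value in scientific notation."""
    evalue = "0.0e+00" if hit.evalue == 0 else f"{hit.evalue:.1e}"
    return "\t".join(
        [
            hit.query_id,
            hit.subject_id,
            f"{hit.pident:.1f}",
            str(hit.length),
            str(hit.mismatch),
            str(hit.gapopen),
            str(hit.qstart),
            str(hit.qend),
            str(hit.sstart),
            str(hit.send),
            evalue,
            f"{hit.bitscore:.1f}",
        ]
    )


def write_hit_table(hits: list[SimilarityHit], path: str | Path) -> None:
    with open(path, "w") as fh:
        for hit in hits:
            fh.write(format_hit(hit) + "\n")


def load_taxonomy_map(path: str | Path) -> dict[str, str]:
    """Load the 2-column subject-id -> phylum TSV into a dict.

    Duplicate subject ids are rejected; an empty file yields an empty map
    with a warning.
    """
    mapping: dict[str, str] = {}
    with open(path) as fh:
        for row_idx, raw in enumerate(fh):
            line = raw.rstrip("\n")
            if not line:
                continue
            parts = line.split("\t")
            if len(parts) != 2:
                raise ParseError(f"{path}: row {row_idx}: expected 2 fields, got {len(parts)}")
            subject, phylum = parts
            if not phylum:
                raise ParseError(f"{path}: row {row_idx}: empty phylum name")
            if subject in mapping:
                raise ParseError(f"{path}: duplicate subject id {subject!r}")
            mapping[subject] = phylum
    if not mapping:
        logger.warning("%s: empty taxonomy map", path)
    return mapping


def write_taxonomy_map(mapping: dict[str, str], path: str | Path) -> None:
    with open(path, "w") as fh:
        for subject in sorted(mapping):
            fh.write(f"{subject}\t{mapping[subject]}\n")
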