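"""Protein FASTA input and match report output (TSV and GFF3).

GFF3 is used for protein features because its coordinates are 1-based
inclusive, matching residue-numbering conventions; no BED writer is
provided (BED's half-open 0-based coordinates would force a double
conversion).
"""

from __future__ import annotations

import sys
import warnings
from dataclasses import dataclass
from typing import IO, Iterable, Sequence

from Bio import SeqIO
from Bio.Seq import Seq
from Bio.SeqRecord import SeqRecord

from .pattern import MotifMatch


class FastaFormatError(ValueError):
    """Raised when FASTA input is structurally invalid."""


@dataclass(frozen=True)
class SequenceRecord:
    """One FASTA record: id, free-text description, uppercased residues."""

    id: str
    description: str
    residues: str


def read_fasta(source: IO[str]) -> list[SequenceRecord]:
    """Parse multi-record protein FASTA from a text stream.

    Wrapped sequence lines are joined, whitespace stripped, residues
    uppercased, input order preserved.  An empty stream yields an empty
    list; sequence content before the first header is a format error.
    An empty record (header with no residues) is tolerated with a warning.
    """
    first = source.read(1)
    if not first:
        return []
    if first != ">":
        raise FastaFormatError("sequence content before first FASTA header")
    source.seek(0)

    records = []
    for rec in SeqIO.parse(source, "fasta"):
        residues = str(rec.seq).replace(" ", "").upper()
        if not residues:
            warnings.warn(f"FASTA record {rec.id!r} has no residues", stacklevel=2)
        description = rec.description
        if description.startswith(rec.id):
            description = description[len(rec.id) :].strip()
        records.append(
            SequenceRecord(id=rec.id, description=description, residues=residues)
        )
    return records


def write_fasta(records: Iterable[SequenceRecord], dest: IO[str]) -> None:
    """Write records as FASTA; round-trips ids and residues exactly."""
    bio_records = [
        SeqRecord(Seq(r.residues), id=r.id, description=r.description)
        for r in records
    ]
    SeqIO.write(bio_records, dest, "fasta")


_TSV_COLUMNS = (
    "sequence_id",
    "core_start",
    "core_end",
    "core_peptide",
    "ext_start",
    "ext_end",
    "ext_peptide",
    "annotations",
)


def _sorted(matches: Sequence[MotifMatch]) -> list[MotifMatch]:
    # Stable: preserves input (sequence) order, then sorts by core_start.
    order: dict[str, int] = {}
    for m in matches:
        order.setdefault(m.sequence_id, len(order))
    return sorted(matches, key=lambda m: (order[m.sequence_id], m.core_start))


def _format_annotations(annotations: dict) -> str:
    parts = []
    for key in sorted(annotations):
        value = annotations[key]
        if isinstance(value, tuple):
            value = "".join(str(v) for v in value)
        parts.append(f"{key}={value}")
    return ";".join(parts)


def write_matches(matches: Sequence[MotifMatch], format: str = "tsv") -> str:
    """Render matches as ``tsv`` or ``gff3`` text.

    TSV carries one row per match with core and extended coordinates
    (1-based inclusive) and flattened annotations.  GFF3 emits one
    ``polypeptide_motif`` feature per match spanning the extended region,
    score and strand ``.``, with the core peptide and context flag in the
    attributes column.  Ordering is deterministic: input sequence order,
    then core start.
    """
    if format == "tsv":
        lines = ["\t".join(_TSV_COLUMNS)]
        for m in _sorted(matches):
            lines.append(
                "\t".join(
                    str(v)
                    for v in (
                        m.sequence_id,
                        m.core_start,
                        m.core_end,
                        m.core_peptide,
                        m.ext_start,
                        m.ext_end,
                        m.ext_peptide,
                        _format_annotations(m.annotations),
                    )
                )
            )
        return "\n".join(lines) + "\n"
    if format == "gff3":
        lines = ["##gff-version 3"]
        for m in _sorted(matches):
            full = m.annotations.get("full_context")
            attrs = [
                f"core_peptide={m.core_peptide}",
                f"core_start={m.core_start}",
                f"core_end={m.core_end}",
            ]
            if full is not None:
                attrs.append(f"full_context={str(full).lower()}")
            lines.append(
                "\t".join(
                    (
                        m.sequence_id,
                        "taadscan",
                        "polypeptide_motif",
                        str(m.ext_start),
                        str(m.ext_end),
                        ".",
                        ".",
                        ".",
                        ";".join(attrs),
                    )
                )
            )
        return "\n".join(lines) + "\n"
    raise ValueError(f"unknown output format: {format!r} (expected 'tsv' or 'gff3')")


def log(message: str, quiet: bool = False) -> None:
    """Diagnostics go to standard error so stdout stays machine-readable."""
    if not quiet:
        print(message, file=sys.stderr)
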