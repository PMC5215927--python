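"""Curated registry of printed peptides, constructs and family members,
plus a seeded synthetic-sequence generator for testing.

The registry ships as three documented plain-text TSV files under
``taadscan/data/``.  Loading is schema-validated, and every peptide
fixture is re-scanned against its recorded core-match count, so a
corrupted data file fails loudly rather than silently.

The synthetic generator draws i.i.d. residues from a background model and
can implant a motif verbatim at a chosen offset — the standard recipe for
recall/background testing of short-linear-motif scanners.
"""

from __future__ import annotations

import csv
from dataclasses import dataclass
from importlib import resources
from typing import Sequence

import numpy as np

from .io import SequenceRecord
from .pattern import STANDARD_RESIDUES
from .taad import RESIDUE_ORDER, BackgroundModel, default_pattern
from . import pattern as _pattern

ACTIVITY_CLASSES = ("strong", "weak/basal", "inactive", "not_reported")

#: Length of full-length Gal4 (residues), the upper bound for construct spans.
GAL4_LENGTH = 881


class RegistryIntegrityError(ValueError):
    """Raised when a packaged registry file fails schema or self-validation."""


@dataclass(frozen=True)
class ConstructRecord:
    """One reporter construct: Gal4 span, optional artifact peptide, activity.

    ``alt_gal4_start``/``alt_gal4_end`` hold a second printed span where the
    source text is internally inconsistent; the canonical span is stored in
    ``gal4_start``/``gal4_end`` and ``coordinate_discrepancy`` is True.
    """

    name: str
    gal4_start: int | None
    gal4_end: int | None
    artificial_peptide: str | None
    ha_tag: bool
    reported_activity_class: str
    alt_gal4_start: int | None = None
    alt_gal4_end: int | None = None
    note: str = ""

    @property
    def coordinate_discrepancy(self) -> bool:
        return self.alt_gal4_start is not None or self.alt_gal4_end is not None


@dataclass(frozen=True)
class PeptideFixture:
    """A printed peptide with its expected 9aaTAD core-match count."""

    name: str
    residues: str
    provenance: str
    expected_core_matches: int


@dataclass(frozen=True)
class FamilyMember:
    """One 9aaTAD-family transcription factor, named exactly as printed."""

    name: str


@dataclass(frozen=True)
class Registry:
    constructs: tuple[ConstructRecord, ...]
    peptides: tuple[PeptideFixture, ...]
    family: tuple[FamilyMember, ...]


def _read_tsv(filename: str) -> list[dict]:
    text = (resources.files("taadscan") / "data" / filename).read_text()
    lines = [ln for ln in text.splitlines() if ln and not ln.startswith("#")]
    return list(csv.DictReader(lines, delimiter="\t"))


def _opt_int(value: str, where: str) -> int | None:
    if value == "NA":
        return None
    try:
        return int(value)
    except ValueError:
        raise RegistryIntegrityError(f"{where}: expected integer or NA, got {value!r}")


def _load_constructs() -> tuple[ConstructRecord, ...]:
    records = []
    seen: set[str] = set()
    for row in _read_tsv("constructs.tsv"):
        name = row["name"]
        if name in seen:
            raise RegistryIntegrityError(f"duplicate construct name {name!r}")
        seen.add(name)
        if row["activity_class"] not in ACTIVITY_CLASSES:
            raise RegistryIntegrityError(
                f"construct {name!r}: unknown activity class {row['activity_class']!r}"
            )
        start = _opt_int(row["gal4_start"], f"construct {name!r}")
        end = _opt_int(row["gal4_end"], f"construct {name!r}")
        if (start is None) != (end is None):
            raise RegistryIntegrityError(f"construct {name!r}: half-open Gal4 span")
        if start is not None and not (1 <= start <= end <= GAL4_LENGTH):
            raise RegistryIntegrityError(
                f"construct {name!r}: span {start}-{end} outside 1-{GAL4_LENGTH}"
            )
        peptide = None if row["artificial_peptide"] == "NA" else row["artificial_peptide"]
        if peptide is not None and (set(peptide) - STANDARD_RESIDUES):
            raise RegistryIntegrityError(
                f"construct {name!r}: peptide has non-standard residues"
            )
        records.append(
            ConstructRecord(
                name=name,
                gal4_start=start,
                gal4_end=end,
                artificial_peptide=peptide,
                ha_tag=row["ha_tag"] == "true",
                reported_activity_class=row["activity_class"],
                alt_gal4_start=_opt_int(row["alt_gal4_start"], f"construct {name!r}"),
                alt_gal4_end=_opt_int(row["alt_gal4_end"], f"construct {name!r}"),
                note=row["note"],
            )
        )
    return tuple(records)


def _load_peptides(validate: bool) -> tuple[PeptideFixture, ...]:
    fixtures = []
    pattern = default_pattern()
    for row in _read_tsv("peptides.tsv"):
        name = row["name"]
        residues = row["residues"]
        if set(residues) - STANDARD_RESIDUES:
            raise RegistryIntegrityError(
                f"peptide {name!r}: non-standard residues in {residues!r}"
            )
        expected = int(row["expected_core_matches"])
        if validate:
            found = len(_pattern.scan(residues, pattern))
            if found != expected:
                raise RegistryIntegrityError(
                    f"peptide {name!r}: registry records {expected} core "
                    f"match(es) but scanning finds {found}"
                )
        fixtures.append(
            PeptideFixture(
                name=name,
                residues=residues,
                provenance=row["provenance"],
                expected_core_matches=expected,
            )
        )
    return tuple(fixtures)


def _load_family() -> tuple[FamilyMember, ...]:
    seen: set[str] = set()
    members = []
    for row in _read_tsv("family.tsv"):
        name = row["name"].strip()
        if not name:
            raise RegistryIntegrityError("empty family-member name")
        if name not in seen:  # printed list repeats VP16 and EBNA2
            seen.add(name)
            members.append(FamilyMember(name=name))
    return tuple(members)


def load_registry(validate: bool = True) -> Registry:
    """Load the packaged registry of constructs, peptides and family members.

    With ``validate=True`` (default) every peptide fixture is re-scanned
    with the default pattern and checked against its recorded core-match
    count; a mismatch raises :class:`RegistryIntegrityError`.
    The family list is deduplicated, preserving printed order.
    """
    return Registry(
        constructs=_load_constructs(),
        peptides=_load_peptides(validate),
        family=_load_family(),
    )


def generate_synthetic(
    n_sequences: int,
    length: int,
    implant: tuple[str, int] | None = None,
    model: BackgroundModel | None = None,
    seed: int = 0,
) -> list[SequenceRecord]:
    """Generate random protein sequences, optionally with an implanted motif.

    Residues are drawn i.i.d. from `model` (uniform by default).  `implant`
    is a ``(peptide, offset)`` pair with a 1-based offset; the peptide is
    written verbatim over the background at that position in every
    sequence.  Deterministic for a fixed seed.

    Raises
    ------
    ValueError
        If the implant does not fit inside the sequence.
    """
    if n_sequences < 0 or length < 0:
        raise ValueError("n_sequences and length must be non-negative")
    if model is None:
        model = BackgroundModel.uniform()
    if implant is not None:
        peptide, offset = implant
        if offset < 1 or offset + len(peptide) - 1 > length:
            raise ValueError(
                f"implant {peptide!r} at offset {offset} does not fit in "
                f"length {length}"
            )
        if set(peptide.upper()) - STANDARD_RESIDUES:
            raise ValueError("implant contains non-standard residues")
    rng = np.random.default_rng(seed)
    freqs = model.as_array()
    records = []
    for i in range(n_sequences):
        draws = rng.choice(20, size=length, p=freqs)
        residues = "".join(RESIDUE_ORDER[j] for j in draws)
        if implant is not None:
            peptide, offset = implant
            residues = (
                residues[: offset - 1]
                + peptide.upper()
                + residues[offset - 1 + len(peptide) :]
            )
        records.append(
            SequenceRecord(id=f"synthetic_{i + 1}", description="", residues=residues)
        )
    return records
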