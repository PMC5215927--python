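"""Degenerate protein-pattern engine in Swissprot/PROSITE bracket syntax.

A pattern is an ordered list of single-residue constraints.  ``[XYZ]`` is an
*inclusion* group (the aligned residue must be one of X, Y, Z) and ``{XYZ}``
is an *exclusion* group (the aligned residue must not be any of X, Y, Z).
Groups may be separated by whitespace, by PROSITE-style hyphens, or both.

Only the 20 standard one-letter residue codes participate in constraints.
Ambiguity and non-standard codes (X, B, Z, J, U, O and the stop ``*``)
satisfy no constraint of either kind, so a window containing one never
matches — the conservative choice for motif prediction.

Coordinates are 0-based half-open internally; every user-facing offset in
this module's API is 1-based inclusive, the convention of protein residue
numbering.
"""

from __future__ import annotations

import re
from dataclasses import dataclass, field
from typing import Iterator

STANDARD_RESIDUES: frozenset[str] = frozenset("ACDEFGHIKLMNPQRSTVWY")

_GROUP_RE = re.compile(r"\[([^\[\]{}]*)\]|\{([^\[\]{}]*)\}")
_SEPARATOR_RE = re.compile(r"[\s\-]*")


class PatternSyntaxError(ValueError):
    """Raised when pattern text cannot be parsed into constraint groups."""


@dataclass(frozen=True)
class PatternPosition:
    """One per-position residue constraint.

    Parameters
    ----------
    index
        Ordinal position within the pattern, 1-based.
    kind
        ``"inclusion"`` (residue must be in `residues`) or ``"exclusion"``
        (residue must not be in `residues`).
    residues
        Non-empty set of standard one-letter codes.
    """

    index: int
    kind: str
    residues: frozenset[str]

    def __post_init__(self) -> None:
        if self.kind not in ("inclusion", "exclusion"):
            raise ValueError(f"unknown constraint kind: {self.kind!r}")
        if not self.residues:
            raise ValueError(f"position {self.index}: empty residue set")
        bad = set(self.residues) - STANDARD_RESIDUES
        if bad:
            raise ValueError(
                f"position {self.index}: non-standard residue code(s) "
                f"{''.join(sorted(bad))!r}"
            )

    def satisfied_by(self, residue: str) -> bool:
        """True iff `residue` (one uppercase letter) meets this constraint.

        Non-standard codes satisfy neither inclusion nor exclusion.
        """
        if residue not in STANDARD_RESIDUES:
            return False
        if self.kind == "inclusion":
            return residue in self.residues
        return residue not in self.residues

    def allowed_residues(self) -> frozenset[str]:
        """The set of standard residues that satisfy this position."""
        if self.kind == "inclusion":
            return self.residues
        return STANDARD_RESIDUES - self.residues

    def to_text(self) -> str:
        inner = "".join(sorted(self.residues))
        return f"[{inner}]" if self.kind == "inclusion" else f"{{{inner}}}"


@dataclass(frozen=True)
class CompiledPattern:
    """An executable degenerate pattern: ordered constraints plus source text."""

    positions: tuple[PatternPosition, ...]
    source_text: str

    def __post_init__(self) -> None:
        if not self.positions:
            raise ValueError("pattern must have at least one position")

    def __len__(self) -> int:
        return len(self.positions)

    def __iter__(self) -> Iterator[PatternPosition]:
        return iter(self.positions)

    def serialize(self) -> str:
        """Canonical space-separated text; reparsing it reproduces the pattern."""
        return " ".join(p.to_text() for p in self.positions)


@dataclass(frozen=True)
class MatchVerdict:
    """Outcome of testing one window: matched, or first failing position.

    ``matched`` is True iff ``failed_position`` is None.  ``failed_residue``
    is the residue that violated the constraint, for diagnostics.
    """

    matched: bool
    failed_position: int | None = None
    failed_residue: str | None = None


@dataclass(frozen=True)
class MotifMatch:
    """A core pattern hit on a sequence; coordinates 1-based inclusive.

    Extension fields are filled by the 9aaTAD layer; at the engine level
    they equal the core coordinates.
    """

    sequence_id: str
    core_start: int
    core_end: int
    core_peptide: str
    ext_start: int
    ext_end: int
    ext_peptide: str
    annotations: dict = field(default_factory=dict)


def parse_pattern(text: str) -> CompiledPattern:
    """Parse Swissprot-syntax pattern text into a :class:`CompiledPattern`.

    Accepts whitespace and/or hyphens between groups.  Residue letters are
    uppercased; duplicates within a group collapse.  Full PROSITE syntax
    (``x`` wildcards, repetition counts, ``<``/``>`` anchors) is not
    supported and is rejected with a clear error.

    Raises
    ------
    PatternSyntaxError
        On empty input, unbalanced brackets, an empty group, or a character
        outside the 20 standard codes inside a group.
    """
    if not text or not text.strip():
        raise PatternSyntaxError("empty pattern text")

    positions: list[PatternPosition] = []
    pos = 0
    while pos < len(text):
        sep = _SEPARATOR_RE.match(text, pos)
        pos = sep.end()
        if pos >= len(text):
            break
        m = _GROUP_RE.match(text, pos)
        if m is None:
            snippet = text[pos : pos + 20]
            raise PatternSyntaxError(
                f"expected a bracket group at {snippet!r} "
                "(unbalanced bracket or unsupported syntax?)"
            )
        inner = m.group(1) if m.group(1) is not None else m.group(2)
        kind = "inclusion" if m.group(1) is not None else "exclusion"
        if not inner:
            raise PatternSyntaxError(f"empty group {m.group(0)!r}")
        letters = frozenset(inner.upper())
        bad = letters - STANDARD_RESIDUES
        if bad:
            raise PatternSyntaxError(
                f"group {m.group(0)!r} contains non-standard code(s) "
                f"{''.join(sorted(bad))!r}"
            )
        positions.append(
            PatternPosition(index=len(positions) + 1, kind=kind, residues=letters)
        )
        pos = m.end()

    if not positions:
        raise PatternSyntaxError(f"no bracket groups found in {text!r}")
    return CompiledPattern(positions=tuple(positions), source_text=text)


def match_at(sequence: str, offset: int, pattern: CompiledPattern) -> MatchVerdict:
    """Test the pattern against `sequence` starting at 1-based `offset`.

    The sequence is uppercased before comparison, so soft-masked lowercase
    input behaves like uppercase.  Returns a verdict carrying the first
    unsatisfied position when the window does not match.

    Raises
    ------
    IndexError
        If the window would extend past either end of the sequence.
    """
    if offset < 1:
        raise IndexError(f"offset must be >= 1, got {offset}")
    end = offset + len(pattern) - 1
    if end > len(sequence):
        raise IndexError(
            f"window {offset}..{end} extends past sequence end ({len(sequence)})"
        )
    window = sequence[offset - 1 : end].upper()
    for position, residue in zip(pattern.positions, window):
        if not position.satisfied_by(residue):
            return MatchVerdict(
                matched=False,
                failed_position=position.index,
                failed_residue=residue,
            )
    return MatchVerdict(matched=True)


def scan(
    sequence: str, pattern: CompiledPattern, sequence_id: str = ""
) -> list[MotifMatch]:
    """Slide the pattern over `sequence` and return every matching window.

    All overlapping matches are reported, in ascending offset order; no
    merging happens at this layer.  A sequence shorter than the pattern
    yields an empty list.
    """
    k = len(pattern)
    matches: list[MotifMatch] = []
    seq = sequence.upper()
    for start0 in range(len(seq) - k + 1):
        verdict = match_at(seq, start0 + 1, pattern)
        if verdict.matched:
            peptide = seq[start0 : start0 + k]
            matches.append(
                MotifMatch(
                    sequence_id=sequence_id,
                    core_start=start0 + 1,
                    core_end=start0 + k,
                    core_peptide=peptide,
                    ext_start=start0 + 1,
                    ext_end=start0 + k,
                    ext_peptide=peptide,
                )
            )
    return matches
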