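"""Shared test helpers: an independent brute-force motif oracle.

The oracle deliberately shares no code with the package's pattern engine:
constraints are plain (kind, set) tuples and matching is a naive
per-window loop, so agreement between the two is a real cross-check.
"""

from __future__ import annotations

import pytest

STANDARD = set("ACDEFGHIKLMNPQRSTVWY")

# The 9aaTAD consensus written out by hand as (kind, residue-set) pairs.
TAAD_CONSTRAINTS = [
    ("in", set("MDENQSTYG")),
    ("out", set("KRHCGP")),
    ("in", set("ILVFWM")),
    ("out", set("KRHCGP")),
    ("out", set("CGP")),
    ("out", set("CGP")),
    ("in", set("ILVFWM")),
    ("out", set("CGP")),
    ("out", set("CGP")),
]


def oracle_window_ok(window: str, constraints=None) -> bool:
    """Naive constraint check of one window; non-standard codes never pass."""
    constraints = TAAD_CONSTRAINTS if constraints is None else constraints
    if len(window) != len(constraints):
        return False
    for residue, (kind, residues) in zip(window.upper(), constraints):
        if residue not in STANDARD:
            return False
        if kind == "in" and residue not in residues:
            return False
        if kind == "out" and residue in residues:
            return False
    return True


def oracle_scan(sequence: str, constraints=None) -> list[int]:
    """All 1-based offsets where the naive check matches."""
    constraints = TAAD_CONSTRAINTS if constraints is None else constraints
    k = len(constraints)
    return [
        o + 1
        for o in range(len(sequence) - k + 1)
        if oracle_window_ok(sequence[o : o + k], constraints)
    ]


@pytest.fixture(scope="session")
def taad_pattern():
    from taadscan import default_pattern

    return default_pattern()
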