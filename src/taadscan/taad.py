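"""9aaTAD layer: default pattern, context extension, background statistics.

The nine-amino-acid transactivation domain (9aaTAD) is a short activation
motif built from two hydrophobic clusters (pattern positions 3 and 7)
interspersed by hydrophilic residues; it is recognized by transcriptional
coactivators.  The degenerate consensus, in Swissprot syntax:

    [MDENQSTYG] {KRHCGP} [ILVFWM] {KRHCGP} {CGP} {CGP} [ILVFWM] {CGP} {CGP}

Activity can be enhanced by adjacent residues — up to four on the N-terminal
side and one on the C-terminal side — so the maximal-activity region is up
to 14 residues long.  ``scan_9aatad`` reports both the 9-residue core and
this extended region, clipped at sequence ends.

A further published refinement layer (criteria RC1–12) is cited in the
literature but not specified here; it is exposed only as a plug-in hook
(`RefinementCriterion`) and defaults to no filtering.
"""

from __future__ import annotations

import math
from dataclasses import dataclass, replace
from typing import Callable, Iterable, Mapping, Sequence

import numpy as np

from .pattern import (
    STANDARD_RESIDUES,
    CompiledPattern,
    MotifMatch,
    parse_pattern,
    scan,
)

#: The degenerate 9aaTAD consensus, Swissprot syntax.
DEFAULT_PATTERN_TEXT = (
    "[MDENQSTYG] {KRHCGP} [ILVFWM] {KRHCGP} {CGP} {CGP} [ILVFWM] {CGP} {CGP}"
)

#: Canonical residue ordering used by background models.
RESIDUE_ORDER: str = "ACDEFGHIKLMNPQRSTVWY"

_DEFAULT_PATTERN: CompiledPattern | None = None


def default_pattern() -> CompiledPattern:
    """The compiled 9-position 9aaTAD pattern (cached, immutable)."""
    global _DEFAULT_PATTERN
    if _DEFAULT_PATTERN is None:
        _DEFAULT_PATTERN = parse_pattern(DEFAULT_PATTERN_TEXT)
    return _DEFAULT_PATTERN


@dataclass(frozen=True)
class ExtensionPolicy:
    """How far to extend a core match toward the maximal-activity region.

    Defaults (4 upstream, 1 downstream) give the 14-residue region; both
    counts clip at sequence ends, and the match records whether the full
    context was available.
    """

    upstream: int = 4
    downstream: int = 1
    clip_at_ends: bool = True

    def __post_init__(self) -> None:
        if self.upstream < 0 or self.downstream < 0:
            raise ValueError("extension counts must be non-negative")


@dataclass(frozen=True)
class RefinementCriterion:
    """Plug-in hook for post-scan filtering of candidate matches.

    `apply` maps (match, sequence) to (passed, reason).  Criteria must be
    pure functions of their inputs.  No criteria ship with the package;
    the published RC1-12 set is defined elsewhere and deliberately not
    guessed at here.
    """

    name: str
    apply: Callable[[MotifMatch, str], tuple[bool, str]]


@dataclass(frozen=True)
class BackgroundModel:
    """Per-residue frequency model over the 20 standard codes.

    kind is ``"uniform"`` or ``"composition"``; frequencies must be
    non-negative and sum to 1 (tolerance 1e-9).
    """

    kind: str
    frequencies: Mapping[str, float]

    def __post_init__(self) -> None:
        if self.kind not in ("uniform", "composition"):
            raise ValueError(f"unknown background model kind: {self.kind!r}")
        keys = set(self.frequencies)
        if keys != set(STANDARD_RESIDUES):
            raise ValueError("frequencies must cover exactly the 20 standard codes")
        vals = np.array([self.frequencies[r] for r in RESIDUE_ORDER], dtype=float)
        if (vals < 0).any():
            raise ValueError("frequencies must be non-negative")
        if abs(vals.sum() - 1.0) > 1e-9:
            raise ValueError(f"frequencies sum to {vals.sum()!r}, expected 1")

    @classmethod
    def uniform(cls) -> "BackgroundModel":
        """Equal mass 1/20 on every standard residue."""
        return cls("uniform", {r: 1.0 / 20.0 for r in RESIDUE_ORDER})

    @classmethod
    def from_sequences(cls, sequences: Iterable[str]) -> "BackgroundModel":
        """Composition model estimated from observed residue counts.

        Non-standard codes are ignored.  Falls back to uniform frequencies
        when no standard residues are observed.
        """
        counts = {r: 0 for r in RESIDUE_ORDER}
        for seq in sequences:
            for residue in seq.upper():
                if residue in counts:
                    counts[residue] += 1
        total = sum(counts.values())
        if total == 0:
            return cls("composition", {r: 1.0 / 20.0 for r in RESIDUE_ORDER})
        return cls("composition", {r: counts[r] / total for r in RESIDUE_ORDER})

    def as_array(self) -> np.ndarray:
        """Frequencies as a vector in :data:`RESIDUE_ORDER`."""
        return np.array([self.frequencies[r] for r in RESIDUE_ORDER], dtype=float)


def extend_match(match: MotifMatch, sequence: str, policy: ExtensionPolicy) -> MotifMatch:
    """Fill in the extended-region fields of a core match.

    The extension is clipped at sequence ends; annotation
    ``full_context`` records whether the complete upstream+downstream
    context existed.
    """
    ext_start = max(1, match.core_start - policy.upstream)
    ext_end = min(len(sequence), match.core_end + policy.downstream)
    full = (
        match.core_start - ext_start == policy.upstream
        and ext_end - match.core_end == policy.downstream
    )
    annotations = dict(match.annotations)
    annotations["full_context"] = full
    return replace(
        match,
        ext_start=ext_start,
        ext_end=ext_end,
        ext_peptide=sequence[ext_start - 1 : ext_end].upper(),
        annotations=annotations,
    )


def _annotate(match: MotifMatch) -> MotifMatch:
    core = match.core_peptide
    annotations = dict(match.annotations)
    annotations["acidic_count"] = sum(core.count(r) for r in "DE")
    if len(core) >= 7:  # custom patterns may be shorter than the 9-mer
        annotations["hydrophobic_cluster"] = (core[2], core[6])
    return replace(match, annotations=annotations)


def scan_9aatad(
    sequence: str,
    policy: ExtensionPolicy | None = None,
    criteria: Sequence[RefinementCriterion] = (),
    sequence_id: str = "",
    pattern: CompiledPattern | None = None,
) -> list[MotifMatch]:
    """Scan a protein sequence for 9aaTAD motifs.

    Core matches come from the sliding-window engine with the default
    pattern (or an explicit `pattern`); each is extended per `policy`,
    annotated (acidic D/E count in the core; the residues at the two
    hydrophobic cluster positions 3 and 7), then filtered through
    `criteria` in order.  With the default empty criteria list the cores
    equal the raw engine output exactly.
    """
    if policy is None:
        policy = ExtensionPolicy()
    if pattern is None:
        pattern = default_pattern()
    seq = sequence.upper()
    matches = []
    for match in scan(seq, pattern, sequence_id=sequence_id):
        match = extend_match(_annotate(match), seq, policy)
        if all(criterion.apply(match, seq)[0] for criterion in criteria):
            matches.append(match)
    return matches


def window_match_probability(
    model: BackgroundModel, pattern: CompiledPattern | None = None
) -> float:
    """Probability that one window of i.i.d. residues matches the pattern.

    Closed form: the product over positions of the total frequency of
    satisfying residues.  For the uniform model and the default 9aaTAD
    pattern this is (9·14·6·14·17·17·6·17·17)/20^9 ≈ 1.04e-2.
    """
    if pattern is None:
        pattern = default_pattern()
    prob = 1.0
    for position in pattern:
        # fsum keeps the all-residues case at exactly 1.0
        prob *= math.fsum(model.frequencies[r] for r in position.allowed_residues())
    return prob


def empirical_match_rate(
    model: BackgroundModel,
    pattern: CompiledPattern | None = None,
    n_windows: int = 100_000,
    seed: int = 0,
) -> float:
    """Monte-Carlo estimate of the per-window match probability.

    Draws `n_windows` independent windows of i.i.d. residues from `model`
    and returns the fraction matching `pattern`.  Deterministic for a
    fixed seed.  Implemented as a vectorized per-position boolean lookup.
    """
    if n_windows < 1:
        raise ValueError("n_windows must be >= 1")
    if pattern is None:
        pattern = default_pattern()
    rng = np.random.default_rng(seed)
    k = len(pattern)
    draws = rng.choice(20, size=(n_windows, k), p=model.as_array())
    ok = np.ones(n_windows, dtype=bool)
    for j, position in enumerate(pattern):
        allowed = np.array(
            [RESIDUE_ORDER[i] in position.allowed_residues() for i in range(20)]
        )
        ok &= allowed[draws[:, j]]
    return float(ok.mean())
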