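# Methods

## The motif model

A 9aaTAD is modelled as a nine-position degenerate pattern in
Swissprot/PROSITE bracket syntax.  Each position is a single-residue
constraint — an inclusion set (`[MDENQSTYG]`: the residue must be one of
these) or an exclusion set (`{KRHCGP}`: the residue must not be).  The
default pattern is

```
[MDENQSTYG] {KRHCGP} [ILVFWM] {KRHCGP} {CGP} {CGP} [ILVFWM] {CGP} {CGP}
```

Positions 3 and 7 carry the two hydrophobic clusters that define the
motif family; the remaining positions mostly forbid helix-breaking or
positively charged residues.  Matching is position-independent: a window
matches iff every aligned residue satisfies its constraint.  There is no
scoring, hydropathy scale or weighting — the model is a hard pattern, and
the implementation reports per-position diagnostics (the first failing
position and the offending residue) rather than a score.

Assumptions and conventions:

- Only the 20 standard residue codes participate in constraints.
  Ambiguity and non-standard codes (X, B, Z, J, U, O, `*`) satisfy
  neither constraint kind, so any window containing one never matches.
  This is the conservative choice for a prediction tool: a match is only
  claimed when every residue is known.
- Input is uppercased before matching; soft-masked lowercase FASTA
  behaves identically to uppercase (protein FASTA case carries no
  standard meaning).
- Pattern text accepts spaces and/or PROSITE-style hyphens between
  groups.  Full PROSITE syntax (wildcards `x`, repetition counts,
  `<`/`>` anchors) is out of scope and rejected with a clear error.
- Coordinates are 0-based half-open internally and 1-based inclusive at
  every API/report surface, matching residue-numbering conventions.
- All overlapping matches are reported; merging or ranking is left to
  downstream layers.

## Context extension

Activation by a 9aaTAD can be enhanced by adjacent residues — up to four
on the N-terminal side and one on the C-terminal side — giving a
maximal-activity region of up to 9 + 4 + 1 = 14 residues.  The
`ExtensionPolicy` (defaults `upstream=4`, `downstream=1`) implements
exactly this arithmetic, clipping at sequence ends; each match records
whether the full context was available (`full_context` annotation).  The
extension is reported even when clipped because adjacent residues enhance
but are not required for function.

Matches are annotated with the count of acidic residues (D/E) in the
core — relevant to the historical "acidic activator" interpretation the
motif model replaces — and the residues at the two hydrophobic cluster
positions.  No hydropathy scale is applied, since the motif definition
names none.

A plug-in hook (`RefinementCriterion`) allows callers to filter candidate
matches with their own criteria.  A published set of twelve refinement
criteria exists for this motif family but is specified elsewhere; its
content is deliberately not guessed at, so the default criteria list is
empty and the scanner's output equals the raw pattern scan.

## Background statistics

For a background model with per-residue frequencies *f*, the probability
that one window of i.i.d. residues matches the pattern is the product
over positions of the total frequency of that position's satisfying set:

P(match) = Π_j Σ_{r ∈ allowed(j)} f_r

For the uniform model (f_r = 1/20) and the default pattern this is
(9·14·6·14·17·17·6·17·17)/20⁹ ≈ 1.036 × 10⁻², about one window per
hundred — the motif is deliberately permissive.  The closed form was
verified against exhaustive enumeration on a reduced four-letter-alphabet
analogue (all 4⁴ windows counted explicitly) and against Monte-Carlo
sampling: at 10⁵ windows per seed, the empirical rate stays within three
binomial standard errors of the closed form for all twenty fixed seeds
tested (observed worst deviation ≈ 1.6 SE).

Two background models ship: `uniform` (default; the simplest defensible
null) and `composition`, which estimates frequencies from user-supplied
sequences — appropriate when the scanned proteome has a skewed
composition.  The composition model falls back to uniform when no
standard residues are observed.

## Synthetic data

`generate_synthetic` draws sequences of i.i.d. residues from a background
model with `numpy.random.default_rng(seed)` and can implant a peptide
verbatim at a chosen offset.  It emulates exactly what the match-rate
algebra assumes — independent residues at a chosen composition — which is
what makes it the right instrument for calibration tests (implant recall,
background rate vs the closed form, oracle equivalence).  It does *not*
emulate real protein features: local composition bias, repeats, domain
structure, disorder or homology.  Passing tests therefore demonstrate
that the scanner and statistics are internally correct, not that the
background rate of real proteomes equals the uniform-model value — for
real data, use the composition model and treat matches as candidates for
experimental follow-up.

Test problem sizes — 1,000 random sequences of length 20–200 for oracle
equivalence, 20 × 10⁵ windows for the Monte-Carlo band — were chosen to
make the binomial bands tight while keeping the default suite fast.

## Fixture registry

The packaged registry (plain-text TSVs under `taadscan/data/`) curates
the peptides, reporter constructs and family members used to validate
the scanner.  Decisions taken in curation:

- Typographic spaces inside printed peptides are layout, not sequence,
  and were removed (e.g. `RVWN HYRDV` → `RVWNHYRDV`).
- Where a construct's Gal4 span is printed inconsistently in different
  passages (G49, G50, G81: start 766 vs 776), both values are stored;
  the earlier printed value is canonical and a discrepancy flag is set.
  The registry preserves; it does not adjudicate.
- Construct H577 spans 857–871 (15 residues) while the maximal-activity
  rule gives 14; the construct is stored as printed, and the 9+4+1
  arithmetic is what the tool implements — the rule, not a construct
  label, defines the extension operation.
- Constructs whose spans or appended peptides were never printed (H45,
  H46, G44, G46, G48) carry absent fields rather than guesses.
- `reported_activity_class` is qualitative (strong / weak-basal /
  inactive / not_reported): numeric activities exist only as figure
  graphics and were not read off.
- Every peptide fixture stores its expected core-match count, computed
  with an independent brute-force oracle; `load_registry()` re-scans all
  of them on load and raises on any mismatch, so a corrupted data file
  cannot load silently.
- The family list is transcribed in printed order with its two printed
  duplicates (VP16, EBNA2) retained in the file and collapsed at load
  time: 48 printed entries, 46 unique members.

## Reporter normalization

Replicate activities are normalized jointly: every replicate is
multiplied by `100 / mean(reference replicates)` and means and sample
standard deviations (n−1 denominator, standard for triplicate biological
assays) are computed on the rescaled values.  Only the reference *mean*
is pinned at exactly 100%; its SD scales like any other construct's.
The procedure is scale-equivariant and idempotent, both enforced by
tests.  Whether to normalize per experiment before averaging is an open
design choice in such assays; this implementation normalizes replicates
jointly by the reference mean, which keeps the two properties above
exact.  A construct with a single replicate reports SD = NaN (the n−1
estimator is undefined) rather than a fabricated 0.

Classification bands (defaults: mean < 10% → inactive, 10–50% → basal,
≥ 50% → strong; half-open, lower-inclusive) are pragmatic reporting
conventions exposed as configuration, not measured quantities.

## Numerical choices and edge cases

- Per-position frequency sums use compensated summation (`math.fsum`) so
  an all-residues position contributes exactly 1.0.
- Monte-Carlo sampling is a vectorized per-position boolean lookup;
  deterministic for a fixed seed.
- A sequence shorter than the pattern scans to an empty list, not an
  error; an out-of-range `match_at` window raises.
- Empty FASTA records are tolerated with a warning; sequence content
  before the first header is an error.
- GFF3 output uses `polypeptide_motif` features over the *extended*
  region with 1-based inclusive coordinates; no BED writer exists, since
  BED's 0-based half-open convention would force a double coordinate
  conversion for protein features.

## Known limitations

- The hard pattern has no notion of match strength; two matches are not
  comparable beyond their annotations.
- Without the (externally defined) refinement criteria, roughly 1% of
  random windows match; on real proteins the scanner is a candidate
  generator, not a classifier.
- The registry contains only peptides and construct metadata that were
  printed as text; full-length Gal4 and family-member sequences are not
  bundled and must be supplied by the user.
- Nucleotide input, six-frame translation and compressed streams are out
  of scope.
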