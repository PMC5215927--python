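# taadscan

Scanning protein sequences for the **nine-amino-acid transactivation
domain (9aaTAD)** — a short linear motif through which transcription
factors such as Gal4, p53, MLL and VP16 recruit coactivators.  The motif
is a tandem of two hydrophobic clusters interspersed by hydrophilic
residues; in Gal4 it sits inside the region bound by the inhibitor Gal80,
so the same nine residues explain both activation and repression.

The toolkit is for molecular biologists and sequence analysts who want
to (i) find candidate 9aaTADs in their own protein FASTA, (ii) reason
about how often so degenerate a pattern matches by chance, (iii) check
whether a suspicious activity in a reporter construct could be an
*artificial* activation domain created at a cloning junction, and
(iv) normalize replicate reporter-assay measurements the standard way.

## The pattern

The 9aaTAD consensus, in Swissprot/PROSITE syntax (`[...]` = allowed
residues, `{...}` = forbidden residues, one group per position):

```
[MDENQSTYG] {KRHCGP} [ILVFWM] {KRHCGP} {CGP} {CGP} [ILVFWM] {CGP} {CGP}
```

Positions 3 and 7 are the two hydrophobic clusters.  A core match can be
extended by up to four residues on the N-terminal side and one on the
C-terminal side — the ≤14-residue region needed for maximal activation.
Under a uniform residue model the per-window match probability has the
closed form

```
P(match) = (9·14·6·14·17·17·6·17·17) / 20^9 ≈ 1.04 × 10⁻²
```

(the numerators are the sizes of each position's allowed set), i.e. about
one window in a hundred — the pattern is a *screen*, not a verdict, which
is why a refinement-criteria plug-in hook exists (`RefinementCriterion`);
the published RC1–12 criteria themselves are defined elsewhere and are
deliberately not bundled.

## Worked example

```python
>>> from taadscan import scan_9aatad
>>> (m,) = scan_9aatad("GMFNTTTMDDVYNYLFDDEDT")   # Gal80-binding peptide
>>> m.core_peptide, m.core_start, m.core_end
('DDVYNYLFD', 9, 17)
>>> m.ext_start, m.ext_end, m.ext_peptide
(5, 18, 'TTTMDDVYNYLFDD')
```

The 21-residue Gal80-binding peptide of Gal4 contains exactly one core,
`DDVYNYLFD` at peptide residues 9–17, and the default extension yields
the 14-residue maximal-activity
region `TTTMDDVYNYLFDD`.  The same call on the cloning-artifact peptides
`RVWNHYRDV`, `GIPDHYRDV` and `PEFRRVWNHYRDV` returns no matches — they are
not 9aaTAD-family activation domains — while the DNA-binding-domain/AD-III
junction `LLTGLFVQDWTDQ` contains the artificial core `GLFVQDWTD` spanning
the fusion boundary.

From a shell:

```
taadscan scan --fasta proteins.fa --format gff3 --out hits.gff3
taadscan fixtures --list
taadscan background --mc 100000 --seed 1
taadscan normalize --table activities.tsv --reference HaY
```

The `fixtures` subcommand exposes a curated registry of the peptides and
reporter constructs used to validate the scanner (Gal80-binding peptides,
artifact peptides, the G/H construct series, the 46-member deduplicated
9aaTAD family list); `normalize` rescales replicate reporter activities so
a chosen reference construct's mean is exactly 100%, reporting mean ± SD
per construct.

See `examples/` for short narrative scripts covering each capability.

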