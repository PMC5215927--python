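"""Scan the Gal80-binding peptides for 9aaTAD cores.

The Gal4 region bound by its inhibitor Gal80 contains the activation
motif itself; scanning the two packaged Gal80-binding peptides (from
S.c.Gal4 and the ortholog K.l.Gal9) finds exactly one 9-residue core in
each, and the default extension (4 residues upstream, 1 downstream)
yields the 14-residue maximal-activity region.
"""

from taadscan import load_registry, scan_9aatad, write_matches

registry = load_registry()
matches = []
for name in ("gal80_binding_gal4", "gal80_binding_klgal9"):
    peptide = next(p for p in registry.peptides if p.name == name)
    matches += scan_9aatad(peptide.residues, sequence_id=peptide.name)

print(write_matches(matches, format="tsv"))
for m in matches:
    print(
        f"{m.sequence_id}: core {m.core_peptide} at {m.core_start}-{m.core_end}, "
        f"extended region {m.ext_start}-{m.ext_end} "
        f"({m.ext_end - m.ext_start + 1} residues)"
    )
# Each peptide holds one core (DDVYNYLFD / DDVYNYIFD); the 14-residue
# extended span is the region needed for maximal activation.
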