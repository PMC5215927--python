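"""Cloning artifacts: peptides that do and do not form a 9aaTAD.

Three artificial peptides carried along in historical reporter constructs
are pattern-negative — they are not 9aaTAD-family activation domains.
In contrast, fusing a Gal4 DNA-binding-domain fragment (LLTGLFVQD)
directly to four residues of the so-called AD-III region (WTDQ) creates a
motif across the junction, even though neither half matches alone: the
classic recipe for an accidental activation domain at a cloning boundary.
"""

from taadscan import scan_9aatad

negatives = ["RVWNHYRDV", "GIPDHYRDV", "PEFRRVWNHYRDV", "LLTGLFVQD", "WTDQ"]
for peptide in negatives:
    hits = scan_9aatad(peptide)
    print(f"{peptide:14s} -> {len(hits)} core match(es)")

junction = "LLTGLFVQD" + "WTDQ"
(hit,) = scan_9aatad(junction)
print(
    f"{junction:14s} -> core {hit.core_peptide} at "
    f"{hit.core_start}-{hit.core_end} (spans the fusion boundary)"
)
# The isolated halves score 0; only the fused junction contains a core.
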